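"""End-to-end run: data -> matrix -> features -> classifier -> ROC.

``run_pipeline`` is a pure function of (inputs, config, seed): given the
same configuration it produces byte-identical output files, which is why
no timestamps are written into results (provenance lives in the log as
config + input checksums).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io as eio
from .classifier import LRCModel, save_model, train
from .evaluation import AveragedROC, averaged_roc
from .genome_model import BindingSiteSet
from .pipeline import (
    LabeledInterval,
    build_test_set,
    build_training_set,
    score_test_set,
)
from .pwm import PWM, build_pwm, revcomp, save_pwm
from .synthetic import SyntheticDatasetSpec, generate

__all__ = ["RunResult", "run_pipeline", "pwm_from_sites", "evaluate_intervals"]


@dataclass
class RunResult:
    model: LRCModel
    pwm: PWM
    intervals: list[LabeledInterval]
    metrics: dict
    out_dir: Path | None


def pwm_from_sites(
    genome: dict[str, str],
    sites: BindingSiteSet,
    chromosomes: list[str] | None = None,
    background: np.ndarray | None = None,
    pseudocount: str | float = "sqrt_n",
) -> PWM:
    """Build the matrix from site sequences extracted off the genome.

    Minus-strand sites are reverse-complemented before counting; the
    zero-order background defaults to the base composition of the
    chromosomes the sites came from.
    """
    chroms = sites.chromosomes if chromosomes is None else chromosomes
    seqs: list[str] = []
    for chrom in chroms:
        seq = genome[chrom]
        for s in sites.sites_on(chrom):
            sub = seq[s.iv.start : s.iv.end]
            seqs.append(revcomp(sub) if s.strand == "-" else sub)
    if background is None:
        background = _base_composition(genome, chroms)
    return build_pwm(seqs, background=background, pseudocount_total=pseudocount)


def _base_composition(genome: dict[str, str], chroms: list[str]) -> np.ndarray:
    counts = np.zeros(4)
    for chrom in chroms:
        s = genome[chrom]
        for i, b in enumerate("ACGT"):
            counts[i] += s.count(b)
    if counts.sum() == 0:
        raise ValueError("no ACGT bases on the background chromosomes")
    return counts / counts.sum()


def evaluate_intervals(
    intervals: list[LabeledInterval], score_attr: str
) -> AveragedROC:
    """Pooled + per-chromosome ROC of one score column of the test bins."""
    per_chrom: dict[str, tuple[list[float], list[int]]] = {}
    for iv in intervals:
        s = getattr(iv, score_attr)
        if s is None:
            raise ValueError(f"interval missing {score_attr}")
        sc, lb = per_chrom.setdefault(iv.iv.chrom, ([], []))
        sc.append(float(s))
        lb.append(iv.label)
    return averaged_roc(per_chrom)


def run_pipeline(
    cfg: "eio.RunConfig", write: bool = True
) -> RunResult:
    """Execute the full prediction pipeline described by a config.

    If no input paths are configured, a synthetic dataset is generated
    (deterministically from ``cfg.seed``).  The classifier is trained on
    ``cfg.training_chromosome`` and evaluated on every other chromosome.
    """
    if cfg.fasta is not None:
        genome = eio.read_fasta(cfg.fasta)
        if cfg.sites_gff is None or cfg.tf_name is None or cfg.tracks_dir is None:
            raise ValueError(
                "external input requires fasta, sites_gff, tf_name and "
                "tracks_dir together"
            )
        sites = eio.read_gff_sites(cfg.sites_gff, cfg.tf_name)
        tracks = eio.read_tracks_dir(cfg.tracks_dir, cfg.marks)
    else:
        ds = generate(
            SyntheticDatasetSpec(
                n_chromosomes=cfg.n_chromosomes,
                chrom_length=cfg.chrom_length,
                n_sites=cfg.n_sites,
                seed=cfg.seed,
            )
        )
        genome, sites, tracks = ds.genome, ds.sites, ds.tracks

    train_chrom = cfg.training_chromosome
    if train_chrom not in genome:
        raise ValueError(f"training chromosome {train_chrom!r} not in genome")
    test_chroms = [c for c in sorted(genome) if c != train_chrom]
    if not test_chroms:
        raise ValueError("need at least one chromosome besides the training one")
    marks = list(tracks) if cfg.marks is None else cfg.marks

    pwm = pwm_from_sites(
        genome, sites.subset([train_chrom]), [train_chrom],
        pseudocount=cfg.pseudocount,
    )
    ts = build_training_set(
        sites, tracks, genome[train_chrom], train_chrom,
        mode=cfg.mode, marks=marks, flank=cfg.flank, seed=cfg.seed,
    )
    model = train(ts, l2=cfg.l2)
    intervals = build_test_set(
        genome, sites, tracks, pwm=pwm, mode=cfg.mode, marks=marks,
        bin_size=cfg.bin_size, flank=cfg.flank, chromosomes=test_chroms,
    )
    score_test_set(model, intervals, combine=cfg.combine)

    metrics = {}
    for name, attr in (
        ("pwm", "pwm_score"),
        ("lrc", "lrc_proba"),
        ("combined", "combined_score"),
    ):
        ev = evaluate_intervals(intervals, attr)
        metrics[name] = {
            "auc_pooled": ev.pooled.auc,
            "auc_macro": ev.macro_auc,
            "per_chromosome": ev.per_chromosome_auc,
            "n_pos": ev.pooled.n_pos,
            "n_neg": ev.pooled.n_neg,
        }

    out_dir: Path | None = None
    if write:
        out_dir = Path(cfg.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        eio.save_config(cfg, out_dir / "config.yaml")
        save_pwm(pwm, out_dir / "pwm.json")
        save_model(model, out_dir / "model.json")
        eio.write_scores(intervals, out_dir / "scores.tsv")
        _write_roc(intervals, out_dir)
        (out_dir / "summary.json").write_text(json.dumps(metrics, indent=1))
        # checksum the config without out_dir so reruns into different
        # directories stay comparable
        cfg_dict = dataclasses.asdict(cfg)
        cfg_dict.pop("out_dir")
        cfg_canon = json.dumps(cfg_dict, sort_keys=True).encode()
        log = {
            "package": "epimotif",
            "seed": cfg.seed,
            "config_checksum": hashlib.sha256(cfg_canon).hexdigest(),
            "input_checksums": _input_checksums(cfg),
        }
        (out_dir / "run_log.json").write_text(json.dumps(log, indent=1))
    return RunResult(
        model=model, pwm=pwm, intervals=intervals, metrics=metrics,
        out_dir=out_dir,
    )


def _input_checksums(cfg: "eio.RunConfig") -> dict[str, str]:
    out = {}
    for key in ("fasta", "sites_gff"):
        path = getattr(cfg, key)
        if path is not None:
            out[key] = eio.file_checksum(path)
    return out


def _write_roc(intervals: list[LabeledInterval], out_dir: Path) -> None:
    for name, attr in (("pwm", "pwm_score"), ("combined", "combined_score")):
        ev = evaluate_intervals(intervals, attr)
        with open(out_dir / f"roc_{name}.tsv", "w") as fh:
            fh.write("fpr\ttpr\n")
            for f, t in zip(ev.pooled.fpr, ev.pooled.tpr):
                fh.write(f"{f:.6f}\t{t:.6f}\n")
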