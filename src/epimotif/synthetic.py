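"""Self-contained synthetic datasets for the full prediction pipeline.

The generator emits a random genome with planted motif instances, the
corresponding binding-site annotations, and per-mark nucleosome-center
tracks whose spatial statistics mimic what is observed around real binding
sites: nucleosomes carrying *active* marks cluster in two Gaussian peaks
flanking each site (offsets ~ +/-mu) with a nucleosome-free exclusion zone
at the site center, on top of a sparse uniform background; *repressive*
marks are uniform background only; *moderate* marks get weak site
enrichment.  Everything is a deterministic function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_model import (
    BindingSite,
    BindingSiteSet,
    GenomicInterval,
    NucleosomeTrack,
)
from .features import position_profile
from .pwm import revcomp

__all__ = [
    "MarkSpec",
    "SyntheticDatasetSpec",
    "SyntheticDataset",
    "generate",
    "profile_roundtrip_check",
]

BASES = "ACGT"


@dataclass(frozen=True)
class MarkSpec:
    """Placement model for one histone mark's nucleosomes."""

    name: str
    mark_class: str = "active"  # active | repressive | moderate
    background_per_kb: float = 0.2
    per_site_nucleosomes: int = 8  # ignored for repressive marks

    def __post_init__(self) -> None:
        if self.mark_class not in ("active", "repressive", "moderate"):
            raise ValueError(f"unknown mark class {self.mark_class!r}")
        if self.background_per_kb < 0:
            raise ValueError("background rate must be >= 0")
        if self.per_site_nucleosomes < 0:
            raise ValueError("per-site nucleosome count must be >= 0")


def _default_marks() -> list[MarkSpec]:
    # two active marks with bimodal site enrichment over sparse background;
    # two repressive marks as dense flat background.  The repressive density
    # is set high enough that the occupancy-profile estimator resolves a
    # flat curve at desk scale (relative sampling error per offset
    # ~ 1/sqrt(n_sites * rate * footprint) ~ 5%); real data reaches the
    # same smoothness through orders of magnitude more binding sites.
    return [
        MarkSpec("H3K4me3", "active", background_per_kb=0.2),
        MarkSpec("H2A.Z", "active", background_per_kb=0.2),
        MarkSpec("H3K27me3", "repressive", background_per_kb=10.0),
        MarkSpec("H3K9me3", "repressive", background_per_kb=10.0),
    ]


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """Parameters of a synthetic study: genome, motif, marks, enrichment."""

    n_chromosomes: int = 3
    chrom_length: int = 2_000_000
    gc_content: float = 0.5
    motif_consensus: str = "GGGGCGGGGC"
    motif_mutation_rate: float = 0.1
    n_sites: int = 500  # per chromosome
    marks: tuple[MarkSpec, ...] = field(
        default_factory=lambda: tuple(_default_marks())
    )
    peak_offset: int = 150  # mu of the two flanking Gaussians, bp
    peak_sd: int = 50  # sigma, bp
    center_depletion: int = 40  # nucleosome-free zone +/-d around centers
    min_site_separation: int = 1000  # at most one site per bin-sized stretch
    # None -> one assembly-gap N-run at 60% of the chromosome, 1% long
    gap_runs: tuple[tuple[int, int], ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.chrom_length < 10_000:
            raise ValueError("need >= 1 chromosome of >= 10 kb")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0, 1)")
        if not 0 <= self.motif_mutation_rate < 1:
            raise ValueError("mutation rate must be in [0, 1)")
        if self.center_depletion > 0 and self.center_depletion >= self.peak_offset:
            raise ValueError("exclusion zone must be smaller than peak offset")
        if set(self.motif_consensus) - set(BASES):
            raise ValueError("motif consensus must be ACGT only")
        if self.gap_runs is None:
            gap_len = max(self.chrom_length // 100, 1000)
            object.__setattr__(
                self,
                "gap_runs",
                ((int(0.6 * self.chrom_length), gap_len),),
            )
        for g0, glen in self.gap_runs:
            if g0 < 0 or glen <= 0 or g0 + glen > self.chrom_length:
                raise ValueError(f"gap run ({g0}, {glen}) does not fit")


@dataclass
class SyntheticDataset:
    """In-memory generated dataset plus its ground truth."""

    spec: SyntheticDatasetSpec
    genome: dict[str, str]
    sites: BindingSiteSet
    tracks: dict[str, NucleosomeTrack]
    truth: pd.DataFrame  # chrom, start, end, strand, center, sequence


def _chrom_names(n: int) -> list[str]:
    return [f"chr{i + 1}" for i in range(n)]


def _place_sites(
    rng: np.random.Generator, length: int, n_sites: int, motif_len: int,
    gaps: tuple[tuple[int, int], ...], min_sep: int,
) -> np.ndarray:
    """Non-overlapping site start positions away from edges and gaps."""
    margin = 2_000  # room for flanking windows and profiles
    min_sep = max(min_sep, 2 * motif_len)
    gap_iv = [(g0 - margin, g0 + glen + margin) for g0, glen in gaps]
    chosen: set[int] = set()
    attempts = 0
    while len(chosen) < n_sites:
        attempts += 1
        if attempts > 200 * n_sites:
            raise ValueError(
                f"cannot place {n_sites} non-overlapping sites on a "
                f"{length} bp chromosome"
            )
        p = int(rng.integers(margin, length - margin - motif_len))
        if any(a <= p < b for a, b in gap_iv):
            continue
        if any(abs(p - q) < min_sep for q in chosen):
            continue
        chosen.add(p)
    return np.sort(np.array(sorted(chosen), dtype=np.int64))


def _mutate_motif(rng: np.random.Generator, consensus: str, rate: float) -> str:
    out = list(consensus)
    for i, b in enumerate(out):
        if rng.random() < rate:
            out[i] = rng.choice([c for c in BASES if c != b])
    return "".join(out)


def _active_centers(
    rng, site_centers: np.ndarray, spec: SyntheticDatasetSpec,
    per_site: int, background_per_kb: float, length: int,
) -> np.ndarray:
    mu, sd, d = spec.peak_offset, spec.peak_sd, spec.center_depletion
    centers: list[np.ndarray] = []
    for s in site_centers:
        offs = []
        while len(offs) < per_site:
            mag = rng.normal(mu, sd)
            if mag < d:  # rejected: inside the nucleosome-free zone
                continue
            sign = 1 if rng.random() < 0.5 else -1
            offs.append(sign * mag)
        centers.append(s + np.asarray(offs))
    bg_n = rng.poisson(background_per_kb * length / 1000.0)
    bg = rng.uniform(0, length, size=bg_n)
    # enforce the nucleosome-free zone against background nucleosomes too
    if bg.size and site_centers.size:
        idx = np.searchsorted(site_centers, bg)
        near = np.full(bg.shape, np.inf)
        left_ok = idx > 0
        near[left_ok] = np.abs(bg[left_ok] - site_centers[idx[left_ok] - 1])
        right_ok = idx < site_centers.size
        near[right_ok] = np.minimum(
            near[right_ok], np.abs(bg[right_ok] - site_centers[idx[right_ok]])
        )
        bg = bg[near >= d]
    all_c = np.concatenate([np.concatenate(centers) if centers else np.empty(0), bg])
    all_c = np.clip(np.round(all_c), 0, length - 1).astype(np.int64)
    return np.sort(all_c)


def generate(
    spec: SyntheticDatasetSpec, out_dir: str | Path | None = None
) -> SyntheticDataset:
    """Generate a dataset; optionally write it to disk.

    Files written (plain text): ``genome.fa``, ``sites.gff``, one
    ``tracks/<mark>.tsv`` per mark, and ``truth.tsv`` with the planted
    site coordinates and sequences.
    """
    rng = np.random.default_rng(spec.seed)
    chroms = _chrom_names(spec.n_chromosomes)
    motif_len = len(spec.motif_consensus)
    gc = spec.gc_content
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])

    genome: dict[str, str] = {}
    site_records: list[BindingSite] = []
    truth_rows: list[dict] = []
    site_centers_by_chrom: dict[str, np.ndarray] = {}

    for chrom in chroms:
        seq = rng.choice(list(BASES), size=spec.chrom_length, p=base_p)
        for g0, glen in spec.gap_runs:
            seq[g0 : g0 + glen] = "N"
        starts = _place_sites(
            rng, spec.chrom_length, spec.n_sites, motif_len, spec.gap_runs,
            spec.min_site_separation,
        )
        centers = []
        for p in starts:
            strand = "+" if rng.random() < 0.5 else "-"
            inst = _mutate_motif(rng, spec.motif_consensus, spec.motif_mutation_rate)
            planted = inst if strand == "+" else revcomp(inst)
            seq[p : p + motif_len] = list(planted)
            iv = GenomicInterval(chrom, int(p), int(p + motif_len))
            site = BindingSite(iv=iv, strand=strand)
            site_records.append(site)
            centers.append(site.center)
            truth_rows.append(
                {
                    "chrom": chrom,
                    "start": int(p),
                    "end": int(p + motif_len),
                    "strand": strand,
                    "center": site.center,
                    "sequence": inst,
                }
            )
        site_centers_by_chrom[chrom] = np.sort(np.array(centers, dtype=np.int64))
        genome[chrom] = "".join(seq)

    tracks: dict[str, NucleosomeTrack] = {}
    for mark in spec.marks:
        per_chrom: dict[str, np.ndarray] = {}
        for chrom in chroms:
            if mark.mark_class == "repressive":
                n = rng.poisson(mark.background_per_kb * spec.chrom_length / 1000.0)
                c = np.sort(
                    rng.integers(0, spec.chrom_length, size=n).astype(np.int64)
                )
            else:
                per_site = mark.per_site_nucleosomes
                if mark.mark_class == "moderate":
                    per_site = max(per_site // 4, 1)
                c = _active_centers(
                    rng,
                    site_centers_by_chrom[chrom],
                    spec,
                    per_site,
                    mark.background_per_kb,
                    spec.chrom_length,
                )
            per_chrom[chrom] = c
        tracks[mark.name] = NucleosomeTrack(mark.name, per_chrom)

    sites = BindingSiteSet("SYN_TF", site_records)
    truth = pd.DataFrame(truth_rows)
    ds = SyntheticDataset(
        spec=spec, genome=genome, sites=sites, tracks=tracks, truth=truth
    )
    if out_dir is not None:
        _write_dataset(ds, Path(out_dir))
    return ds


def _write_dataset(ds: SyntheticDataset, out_dir: Path) -> None:
    from . import io as eio

    out_dir.mkdir(parents=True, exist_ok=True)
    eio.write_fasta(ds.genome, out_dir / "genome.fa")
    eio.write_gff_sites(ds.sites, out_dir / "sites.gff")
    tracks_dir = out_dir / "tracks"
    tracks_dir.mkdir(exist_ok=True)
    for name, track in ds.tracks.items():
        eio.write_nucleosome_track(track, tracks_dir / f"{name}.tsv")
    ds.truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)


def without_enrichment(spec: SyntheticDatasetSpec) -> SyntheticDatasetSpec:
    """Null variant: every mark becomes uniform background (no site signal)."""
    null_marks = tuple(
        replace(
            m,
            mark_class="repressive",
            background_per_kb=max(m.background_per_kb, 1.0),
        )
        for m in spec.marks
    )
    return replace(spec, marks=null_marks)


def profile_roundtrip_check(
    ds: SyntheticDataset,
    half_window: int = 1000,
    footprint: int = 15,
    peak_tolerance: int = 20,
    flat_threshold: float = 1.5,
) -> dict[str, dict]:
    """Verify that generated tracks reproduce the intended profile shapes.

    Active marks must show two occupancy maxima within ``peak_tolerance``
    of +/-peak_offset and a central occupancy minimum at offset ~0;
    repressive marks must be flat (max/min ratio below ``flat_threshold``
    over the fully-covered offsets |offset| <= half_window).
    """
    mu = ds.spec.peak_offset
    report: dict[str, dict] = {}
    for mark in ds.spec.marks:
        prof = position_profile(
            ds.tracks[mark.name], ds.sites, half_window, footprint
        )
        off, ratio = prof.offsets, prof.ratio
        interior = np.abs(off) <= half_window
        entry: dict = {"mark_class": mark.mark_class}
        if mark.mark_class == "repressive":
            vals = ratio[interior]
            flat_ratio = float(vals.max() / vals.min()) if vals.min() > 0 else np.inf
            entry.update(flat_ratio=flat_ratio, flat=flat_ratio < flat_threshold)
        else:
            search = 3 * mu
            neg = (off >= -search) & (off <= -ds.spec.center_depletion)
            pos = (off >= ds.spec.center_depletion) & (off <= search)
            peak_neg = int(off[neg][np.argmax(ratio[neg])])
            peak_pos = int(off[pos][np.argmax(ratio[pos])])
            central = np.abs(off) <= mu
            cvals = ratio[central]
            m = cvals.min()
            plateau = off[central][cvals <= m + 1e-12]
            center_min = float(plateau.mean())
            bimodal = (
                abs(peak_neg + mu) <= peak_tolerance
                and abs(peak_pos - mu) <= peak_tolerance
                and abs(center_min) <= peak_tolerance
                and m < 0.5 * min(ratio[off == peak_neg][0], ratio[off == peak_pos][0])
            )
            entry.update(
                peak_neg=peak_neg,
                peak_pos=peak_pos,
                center_min_offset=center_min,
                bimodal=bool(bimodal),
            )
        report[mark.name] = entry
    return report
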