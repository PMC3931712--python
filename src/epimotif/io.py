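"""Readers and writers for the formats the pipeline consumes and emits.

Coordinate conventions: GFF is 1-based inclusive and converted to the
internal 0-based half-open system on read; BED and the 2-column nucleosome
TSV are already 0-based.  Score tables are written with fixed 6-decimal
floats and a deterministic (chrom, start) row order so identical runs give
byte-identical files.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome_model import (
    BindingSite,
    BindingSiteSet,
    GenomicInterval,
    NucleosomeTrack,
)
from .pipeline import LabeledInterval

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_gff_sites",
    "write_gff_sites",
    "read_nucleosome_track",
    "write_nucleosome_track",
    "read_tracks_dir",
    "write_scores",
    "read_scores",
    "RunConfig",
    "load_config",
    "save_config",
    "file_checksum",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load all records of a FASTA file as ``{name: sequence}`` (upper-cased)."""
    genome = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }
    if not genome:
        raise ValueError(f"no FASTA records in {path}")
    return genome


def write_fasta(genome: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


_GFF3_NAME = re.compile(r"(?:^|;)\s*(?:Name|name|ID)=([^;]+)", re.IGNORECASE)
_GFF2_NAME = re.compile(r'(?:^|;)\s*\w+\s+"([^"]+)"')


def _attr_names(attr: str) -> list[str]:
    """Candidate feature names from a GFF2 or GFF3 attribute column."""
    names = _GFF3_NAME.findall(attr) + _GFF2_NAME.findall(attr)
    return names if names else [attr.strip()]


def read_gff_sites(path: str | Path, tf_name: str) -> BindingSiteSet:
    """Binding sites of one factor from a GFF2/GFF3 annotation.

    Records are kept when ``tf_name`` matches the feature type (column 3)
    or any Name/ID-like attribute.  Coordinates are converted from 1-based
    inclusive to 0-based half-open.
    """
    sites: list[BindingSite] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 8:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 8 tab-separated GFF "
                    f"columns, got {len(cols)}"
                )
            chrom, _src, feature, start, end, _score, strand = cols[:7]
            attr = cols[8] if len(cols) > 8 else ""
            names = {feature, *(n.strip() for n in _attr_names(attr))}
            if tf_name not in names:
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinates "
                    f"{start!r}/{end!r}"
                ) from exc
            if strand not in ("+", "-"):
                strand = "+"
            iv = GenomicInterval(chrom, start_i - 1, end_i)
            sites.append(BindingSite(iv=iv, strand=strand))
    if not sites:
        raise ValueError(f"no {tf_name!r} binding sites found in {path}")
    return BindingSiteSet(tf_name, sites)


def write_gff_sites(sites: BindingSiteSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 2\n")
        for s in sites:
            fh.write(
                f"{s.iv.chrom}\tepimotif\tTFBS\t{s.iv.start + 1}\t"
                f"{s.iv.end}\t.\t{s.strand}\t.\tname \"{sites.tf_name}\"\n"
            )


def read_nucleosome_track(path: str | Path, mark: str) -> NucleosomeTrack:
    """Nucleosome centers from a 2-column TSV (chrom, center) or BED3.

    BED3 rows (chrom, start, end) contribute the midpoint
    ``floor((start + end) / 2)``.  Output is sorted and deduplicated.
    """
    centers: dict[str, list[int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            try:
                if len(cols) >= 3:
                    chrom, start, end = cols[0], int(cols[1]), int(cols[2])
                    center = (start + end) // 2
                elif len(cols) == 2:
                    chrom, center = cols[0], int(cols[1])
                else:
                    raise ValueError("expected 2 (TSV) or 3+ (BED) columns")
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            centers.setdefault(chrom, []).append(center)
    return NucleosomeTrack(mark, centers)


def write_nucleosome_track(track: NucleosomeTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chromosomes:
            for c in track.centers_on(chrom):
                fh.write(f"{chrom}\t{c}\n")


def read_tracks_dir(
    directory: str | Path, marks: list[str] | None = None
) -> dict[str, NucleosomeTrack]:
    """Load every ``<mark>.tsv`` in a directory (or just the given marks)."""
    directory = Path(directory)
    paths = sorted(directory.glob("*.tsv"))
    if marks is not None:
        paths = [directory / f"{m}.tsv" for m in marks]
    tracks = {p.stem: read_nucleosome_track(p, p.stem) for p in paths}
    if not tracks:
        raise ValueError(f"no nucleosome tracks found in {directory}")
    return tracks


def _fmt(x: float | None) -> str:
    return "NA" if x is None else f"{x:.6f}"


def write_scores(intervals: list[LabeledInterval], path: str | Path) -> None:
    """Scores TSV: chrom, start, end, label, pwm_score, lrc_proba,
    combined_score, flags; deterministic row order; floats at 6 decimals."""
    rows = sorted(intervals, key=lambda r: (r.iv.chrom, r.iv.start))
    with open(path, "w") as fh:
        fh.write(
            "chrom\tstart\tend\tlabel\tpwm_score\tlrc_proba\t"
            "combined_score\tflags\n"
        )
        for r in rows:
            flags = ",".join(r.flags) if r.flags else "."
            fh.write(
                f"{r.iv.chrom}\t{r.iv.start}\t{r.iv.end}\t{r.label}\t"
                f"{_fmt(r.pwm_score)}\t{_fmt(r.lrc_proba)}\t"
                f"{_fmt(r.combined_score)}\t{flags}\n"
            )


def read_scores(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    expected = {
        "chrom", "start", "end", "label",
        "pwm_score", "lrc_proba", "combined_score", "flags",
    }
    missing = expected - set(df.columns)
    if missing:
        raise ValueError(f"scores file {path} lacks columns: {sorted(missing)}")
    return df


@dataclass
class RunConfig:
    """All knobs of an end-to-end run, serializable to YAML/JSON."""

    out_dir: str = "results"
    # synthetic-data generation (used when no input paths are given)
    n_chromosomes: int = 3
    chrom_length: int = 2_000_000
    n_sites: int = 500
    # optional external inputs
    fasta: str | None = None
    sites_gff: str | None = None
    tf_name: str | None = None
    tracks_dir: str | None = None
    # method parameters
    bin_size: int = 1000
    flank: int = 1000
    footprint: int = 15
    mode: str = "mnn"
    marks: list[str] | None = None
    pseudocount: str | float = "sqrt_n"
    combine: str = "product"
    l2: float = 0.0
    training_chromosome: str = "chr1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("mnn", "mno"):
            raise ValueError(f"mode must be mnn|mno, got {self.mode!r}")
        if self.combine not in ("product", "loglinear"):
            raise ValueError(f"combine must be product|loglinear")


def load_config(path: str | Path) -> RunConfig:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in fields(RunConfig)}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**doc)
    if cfg.marks is not None:
        cfg.marks = list(cfg.marks)
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(cfg), sort_keys=True))


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
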