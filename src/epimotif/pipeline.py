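"""Training/test-set assembly and the combined classifier-by-matrix score.

Training examples are anchored at binding-site centers (positives) and at
twice as many uniformly sampled positions in non-gapped sequence of the
training chromosome (negatives).  Test examples are fixed-width genome bins
labeled positive when they contain a reported site center; their features
are computed at the bin center.  That asymmetry — site centers for
training, bin centers for testing — is deliberate: at prediction time the
true site position inside a bin is unknown.

The fused region score multiplies the classifier's binding probability with
the bin's relative matrix score; both factors live in [0, 1], so the
product does too, and a region must look good to both the sequence model
and the chromatin model to rank highly.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np

from .classifier import LRCModel, TrainingSet, predict_proba
from .features import (
    MissingMarkError,
    mnn_vector,
    mno_vector,
    nearest_nucleosome_distance,
    occupancy_count,
)
from .genome_model import (
    BindingSiteSet,
    GenomicInterval,
    GenomicPosition,
    NucleosomeTrack,
    bin_chromosome,
    interval_center,
)
from .pwm import PWM, score_interval

__all__ = [
    "LabeledInterval",
    "sample_negative_positions",
    "build_training_set",
    "build_test_set",
    "combined_score",
    "score_test_set",
    "transfer_predict",
]

NEGATIVES_PER_POSITIVE = 2


@dataclass
class LabeledInterval:
    """One scored genome bin."""

    iv: GenomicInterval
    label: int
    pwm_score: float | None = None
    features: np.ndarray | None = None
    lrc_proba: float | None = None
    combined_score: float | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0/1, got {self.label}")


def non_gapped_runs(seq: str, min_run: int = 1000) -> list[tuple[int, int]]:
    """Maximal runs without N of at least ``min_run`` bp, as (start, end)."""
    return [
        (m.start(), m.end())
        for m in re.finditer(r"[ACGTacgt]+", seq)
        if m.end() - m.start() >= min_run
    ]


def sample_negative_positions(
    seq: str, chrom: str, n: int, rng: np.random.Generator,
    min_run: int = 1000,
) -> list[GenomicPosition]:
    """Uniform positions over the non-gapped portion of one chromosome."""
    runs = non_gapped_runs(seq, min_run)
    if not runs:
        raise ValueError(
            f"no non-gapped run of >= {min_run} bp on {chrom}; "
            "cannot sample negative controls"
        )
    lengths = np.array([b - a for a, b in runs], dtype=float)
    starts = np.array([a for a, _ in runs], dtype=np.int64)
    cum = np.cumsum(lengths)
    total = cum[-1]
    u = rng.uniform(0, total, size=n)
    idx = np.searchsorted(cum, u, side="right")
    offs = u - (cum[idx] - lengths[idx])
    return [
        GenomicPosition(chrom, int(starts[i] + o)) for i, o in zip(idx, offs)
    ]


def _feature_matrix(
    tracks: dict[str, NucleosomeTrack],
    anchors: list[GenomicPosition],
    mode: str,
    marks: list[str],
    flank: int,
) -> np.ndarray:
    if mode == "mnn":
        return np.vstack([mnn_vector(tracks, a, marks) for a in anchors])
    if mode == "mno":
        return np.vstack([mno_vector(tracks, a, marks, flank) for a in anchors])
    raise ValueError(f"mode must be 'mnn' or 'mno', got {mode!r}")


def build_training_set(
    sites: BindingSiteSet,
    tracks: dict[str, NucleosomeTrack],
    genome_seq: str,
    chrom: str,
    mode: str = "mnn",
    marks: list[str] | None = None,
    flank: int = 1000,
    seed: int = 0,
) -> TrainingSet:
    """Assemble features and labels from one training chromosome.

    Positives are anchored at the site centers on ``chrom``; for each
    positive, two negative-control anchors are drawn uniformly from
    non-gapped regions of the same chromosome.
    """
    marks = list(tracks) if marks is None else list(marks)
    missing = [m for m in marks if m not in tracks]
    if missing:
        raise ValueError(f"tracks missing for requested marks: {missing}")
    pos_anchors = [
        GenomicPosition(chrom, int(c)) for c in sites.centers_on(chrom)
    ]
    if not pos_anchors:
        raise ValueError(f"no binding sites on training chromosome {chrom}")
    rng = np.random.default_rng(seed)
    neg_anchors = sample_negative_positions(
        genome_seq, chrom, NEGATIVES_PER_POSITIVE * len(pos_anchors), rng
    )
    X = _feature_matrix(tracks, pos_anchors + neg_anchors, mode, marks, flank)
    y = np.r_[np.ones(len(pos_anchors)), np.zeros(len(neg_anchors))].astype(int)
    prefix = "dist" if mode == "mnn" else "occ"
    return TrainingSet(X=X, y=y, feature_names=[f"{prefix}_{m}" for m in marks])


def build_test_set(
    genome: dict[str, str],
    sites: BindingSiteSet,
    tracks: dict[str, NucleosomeTrack],
    pwm: PWM | None = None,
    mode: str = "mnn",
    marks: list[str] | None = None,
    bin_size: int = 1000,
    flank: int = 1000,
    chromosomes: list[str] | None = None,
) -> list[LabeledInterval]:
    """Label and featurize fixed-width bins over the test chromosomes.

    A bin is positive when it contains the center of a reported site.
    Features are computed at the bin center; a mark with no nucleosome on
    the chromosome gets the chromosome length as a sentinel distance and
    the interval is flagged.
    """
    marks = list(tracks) if marks is None else list(marks)
    chroms = sorted(genome) if chromosomes is None else list(chromosomes)
    out: list[LabeledInterval] = []
    for chrom in chroms:
        seq = genome[chrom]
        centers = sites.centers_on(chrom)
        for start, end in bin_chromosome(len(seq), bin_size):
            iv = GenomicInterval(chrom, start, end)
            lo = np.searchsorted(centers, start, side="left")
            hi = np.searchsorted(centers, end, side="left")
            label = int(hi > lo)
            anchor = interval_center(iv)
            feats = np.empty(len(marks))
            flags: list[str] = []
            for j, mark in enumerate(marks):
                try:
                    if mode == "mnn":
                        feats[j] = float(
                            nearest_nucleosome_distance(tracks[mark], anchor)
                        )
                    else:
                        feats[j] = float(
                            occupancy_count(tracks[mark], anchor, flank)
                        )
                except MissingMarkError:
                    feats[j] = float(len(seq))  # sentinel: chromosome length
                    flags.append(f"sentinel:{mark}")
            if flags:
                warnings.warn(
                    f"marks absent on {chrom}: sentinel distances used "
                    f"({', '.join(flags)})",
                    stacklevel=2,
                )
            pwm_score = (
                score_interval(pwm, seq, start, end) if pwm is not None else None
            )
            out.append(
                LabeledInterval(
                    iv=iv, label=label, pwm_score=pwm_score,
                    features=feats, flags=flags,
                )
            )
    return out


def combined_score(
    lrc_proba: float, pwm_score: float, mode: str = "product",
    loglinear_weight: float = 0.5,
) -> float:
    """Fuse classifier probability and relative matrix score into one score.

    ``product`` multiplies the two factors; ``loglinear`` is the weighted
    geometric mean ``p**w * q**(1-w)``.
    """
    if not 0.0 <= lrc_proba <= 1.0:
        raise ValueError(f"lrc_proba out of range: {lrc_proba}")
    if not 0.0 <= pwm_score <= 1.0:
        raise ValueError(f"pwm_score out of range: {pwm_score}")
    if mode == "product":
        return lrc_proba * pwm_score
    if mode == "loglinear":
        w = loglinear_weight
        return float(lrc_proba**w * pwm_score ** (1.0 - w))
    raise ValueError(f"unknown combine mode {mode!r}")


def score_test_set(
    model: LRCModel,
    intervals: list[LabeledInterval],
    combine: str = "product",
) -> list[LabeledInterval]:
    """Attach classifier probabilities (and fused scores) to test bins."""
    if not intervals:
        return intervals
    X = np.vstack([iv.features for iv in intervals])
    proba = predict_proba(model, X)
    for iv, p in zip(intervals, proba):
        iv.lrc_proba = float(p)
        if iv.pwm_score is not None:
            iv.combined_score = combined_score(float(p), iv.pwm_score, combine)
    return intervals


def transfer_predict(
    model: LRCModel,
    pwm: PWM,
    genome: dict[str, str],
    sites: BindingSiteSet,
    tracks: dict[str, NucleosomeTrack],
    mode: str = "mnn",
    marks: list[str] | None = None,
    bin_size: int = 1000,
    flank: int = 1000,
    combine: str = "product",
) -> list[LabeledInterval]:
    """Score one factor's test bins with a classifier trained on another.

    The chromatin model (trained, say, on a ubiquitous factor) supplies the
    probability factor; the target factor's own matrix supplies the
    sequence factor, making the fused score specific to the target.
    """
    intervals = build_test_set(
        genome, sites, tracks, pwm=pwm, mode=mode, marks=marks,
        bin_size=bin_size, flank=flank,
    )
    return score_test_set(model, intervals, combine)
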