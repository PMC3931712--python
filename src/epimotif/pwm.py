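"""Position weight matrix construction, scoring and relative scaling.

The matrix is built from aligned, equal-length binding-site sequences with a
zero-order background model.  Counts receive background-proportional
pseudocounts: with ``N`` real counts per column, the total pseudocount mass
is ``P = sqrt(N)`` distributed as ``p_b = P * q_b`` where ``q_b`` is the
background frequency of base ``b``.  Frequencies are

    f[b, i] = (c[b, i] + p_b) / (N + P)

and log-odds matrix entries ``m[b, i] = log2(f[b, i] / q_b)``.  Raw window
scores (sums of matrix entries) are mapped onto a relative unit scale

    (raw - s_min) / (s_max - s_min)

where ``s_min`` / ``s_max`` are the sums of per-column minimum / maximum
entries, so every scored window lands in [0, 1].  The relative score does
not depend on the logarithm base, since a base change rescales every entry
by the same positive constant.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "PWM",
    "build_pwm",
    "score_subsequence",
    "scale_score",
    "score_interval",
    "revcomp",
    "save_pwm",
    "load_pwm",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

# byte -> row index; 255 marks non-ACGT (ambiguous / gap)
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _b, _i in _BASE_INDEX.items():
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode_sequence(seq: str) -> np.ndarray:
    """Encode DNA into row indices 0..3; non-ACGT bases map to 255."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class PWM:
    """A position weight matrix with its relative-scale bookkeeping.

    Attributes
    ----------
    freq : (4, L) array, rows in ACGT order; each column sums to 1.
    logodds : (4, L) array of log2(freq / background).
    background : length-4 zero-order background frequencies.
    s_min, s_max : sums of per-column minimum / maximum log-odds entries.
    pseudocount_total : the ``P`` used at construction ("sqrt_n" resolves
        to sqrt of the site count).
    """

    freq: np.ndarray
    logodds: np.ndarray
    background: np.ndarray
    s_min: float
    s_max: float
    pseudocount_total: str | float = "sqrt_n"
    log_base: float = 2.0
    counts: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.freq.shape != self.logodds.shape or self.freq.shape[0] != 4:
            raise ValueError("freq and logodds must both be (4, L)")
        colsums = self.freq.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            raise ValueError("every frequency column must sum to 1")
        if not np.all(self.freq > 0):
            raise ValueError("frequencies must be strictly positive")
        if not math.isclose(float(self.background.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("background frequencies must sum to 1")
        if not self.s_min < self.s_max:
            raise ValueError("degenerate matrix: s_min must be < s_max")

    @property
    def length(self) -> int:
        return self.freq.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.logodds, axis=0))


def build_pwm(
    sites: Sequence[str],
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    pseudocount_total: str | float = "sqrt_n",
    log_base: float = 2.0,
) -> PWM:
    """Build a PWM from aligned equal-length ACGT sequences.

    Parameters
    ----------
    sites : aligned binding-site sequences, all the same length, ACGT only.
    background : zero-order background frequencies in ACGT order.
    pseudocount_total : total pseudocount mass P per column; "sqrt_n" uses
        sqrt of the number of sites, a float fixes it directly.
    log_base : base of the log-odds logarithm (default 2).
    """
    if not sites:
        raise ValueError("need at least one binding-site sequence")
    L = len(sites[0])
    if L == 0:
        raise ValueError("binding-site sequences must be non-empty")
    q = np.asarray(background, dtype=float)
    if q.shape != (4,) or not math.isclose(float(q.sum()), 1.0, abs_tol=1e-9):
        raise ValueError("background must be 4 frequencies summing to 1")
    if np.any(q <= 0):
        raise ValueError("background frequencies must be strictly positive")

    counts = np.zeros((4, L), dtype=float)
    for k, site in enumerate(sites):
        if len(site) != L:
            raise ValueError(
                f"ragged input: site {k} has length {len(site)}, expected {L}"
            )
        for i, base in enumerate(site.upper()):
            idx = _BASE_INDEX.get(base)
            if idx is None:
                raise ValueError(
                    f"non-ACGT character {base!r} in site {k} at position {i}"
                )
            counts[idx, i] += 1.0

    n = float(len(sites))
    if pseudocount_total == "sqrt_n":
        p_total = math.sqrt(n)
    else:
        p_total = float(pseudocount_total)
        if p_total <= 0:
            raise ValueError("pseudocount_total must be positive")
    pseudo = p_total * q  # p_b = P * q_b

    freq = (counts + pseudo[:, None]) / (n + p_total)
    logodds = np.log(freq / q[:, None]) / math.log(log_base)
    s_min = float(logodds.min(axis=0).sum())
    s_max = float(logodds.max(axis=0).sum())
    return PWM(
        freq=freq,
        logodds=logodds,
        background=q,
        s_min=s_min,
        s_max=s_max,
        pseudocount_total=pseudocount_total,
        log_base=log_base,
        counts=counts,
    )


def score_subsequence(pwm: PWM, seq: str) -> float:
    """Raw log-odds score of one window of exactly the matrix length.

    Returns NaN (unscorable) if the window contains a non-ACGT base.
    """
    if len(seq) != pwm.length:
        raise ValueError(
            f"sequence length {len(seq)} != matrix length {pwm.length}"
        )
    codes = encode_sequence(seq)
    if np.any(codes == 255):
        return math.nan
    return float(pwm.logodds[codes, np.arange(pwm.length)].sum())


def scale_score(pwm: PWM, raw: float) -> float:
    """Map a raw log-odds score onto the relative unit scale [0, 1]."""
    rel = (raw - pwm.s_min) / (pwm.s_max - pwm.s_min)
    # clip only against floating-point drift; valid raw scores lie inside
    return min(1.0, max(0.0, rel))


def _window_scores(logodds: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Scaled-length sliding-window raw scores; NaN where a window holds a
    non-ACGT base."""
    L = logodds.shape[1]
    if codes.size < L:
        return np.empty(0)
    win = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = np.all(win != 255, axis=1)
    scores = np.full(win.shape[0], np.nan)
    if np.any(valid):
        safe = np.where(win[valid] == 255, 0, win[valid])
        scores[valid] = logodds[safe, np.arange(L)].sum(axis=1)
    return scores


def score_interval(
    pwm: PWM, genome_seq: str, start: int, end: int
) -> float:
    """Best double-strand relative score of a genomic interval.

    Every length-L window inside ``[start, end)`` is scored on the forward
    strand and as its reverse complement; the interval score is the maximum
    relative score over all windows and both strands.  Windows containing
    non-ACGT characters are skipped; if no window is scorable the interval
    scores 0.
    """
    if start < 0 or end > len(genome_seq) or start >= end:
        raise ValueError(f"interval [{start}, {end}) outside chromosome")
    if end - start < pwm.length:
        raise ValueError(
            f"interval length {end - start} shorter than matrix length "
            f"{pwm.length}"
        )
    codes = encode_sequence(genome_seq[start:end])
    fwd = _window_scores(pwm.logodds, codes)
    # reverse-complement scoring without materializing the rc sequence:
    # score the forward codes with the matrix complemented (rows A<->T,
    # C<->G) and reversed column-wise.
    rc_logodds = pwm.logodds[::-1, ::-1]
    rev = _window_scores(rc_logodds, codes)
    both = np.concatenate([fwd, rev])
    finite = both[~np.isnan(both)]
    if finite.size == 0:
        return 0.0
    return scale_score(pwm, float(finite.max()))


def save_pwm(pwm: PWM, path: str | Path) -> None:
    """Serialize to JSON (counts if available, frequencies, background,
    scale bookkeeping and pseudocount config)."""
    doc = {
        "format": "epimotif-pwm-1",
        "bases": BASES,
        "freq": pwm.freq.tolist(),
        "logodds": pwm.logodds.tolist(),
        "background": pwm.background.tolist(),
        "s_min": pwm.s_min,
        "s_max": pwm.s_max,
        "pseudocount_total": pwm.pseudocount_total,
        "log_base": pwm.log_base,
        "counts": None if pwm.counts is None else pwm.counts.tolist(),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_pwm(path: str | Path) -> PWM:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "epimotif-pwm-1":
        raise ValueError(f"not a PWM file: {path}")
    counts = doc.get("counts")
    return PWM(
        freq=np.asarray(doc["freq"], dtype=float),
        logodds=np.asarray(doc["logodds"], dtype=float),
        background=np.asarray(doc["background"], dtype=float),
        s_min=float(doc["s_min"]),
        s_max=float(doc["s_max"]),
        pseudocount_total=doc["pseudocount_total"],
        log_base=float(doc["log_base"]),
        counts=None if counts is None else np.asarray(counts, dtype=float),
    )
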