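"""Nucleosome-derived features and positional occupancy profiles.

Two features summarize the modified-nucleosome landscape around an anchor
position (a binding-site center or a bin center):

* nearest-neighbor distance (MNN): absolute distance in bp from the anchor
  to the closest nucleosome center carrying a given mark;
* occupancy (MNO): number of nucleosome centers of a mark inside a closed
  window ``[anchor - flank, anchor + flank]``.

The positional profile counts, for each offset relative to site centers,
how many nucleosome footprints (center +/- 15 bp) cover that offset,
normalized by the number of sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_model import BindingSiteSet, GenomicPosition, NucleosomeTrack

__all__ = [
    "MissingMarkError",
    "nearest_nucleosome_distance",
    "occupancy_count",
    "mnn_vector",
    "mno_vector",
    "PositionProfile",
    "position_profile",
]

#: canonical listing order of the 21 histone methylation marks
CANONICAL_MARKS = [
    "H2A.Z",
    "H3K4me1",
    "H3K4me2",
    "H3K4me3",
    "H3K9me1",
    "H3K9me2",
    "H3K9me3",
    "H3K27me1",
    "H3K27me2",
    "H3K27me3",
    "H3K36me1",
    "H3K36me3",
    "H3K79me1",
    "H3K79me2",
    "H3K79me3",
    "H3R2me1",
    "H3R2me2",
    "H4K20me1",
    "H4K20me3",
    "H4R3me2",
    "H2BK5me1",
]

#: marks most predictive of binding regions (all of the "active" class)
TOP_MARKS = [
    "H2A.Z",
    "H3K4me1",
    "H3K4me2",
    "H3K4me3",
    "H3K9me1",
    "H3K27me1",
    "H4K20me1",
    "H2BK5me1",
]


class MissingMarkError(KeyError):
    """A mark has no nucleosome on the requested chromosome."""

    def __init__(self, mark: str, chrom: str):
        super().__init__(f"no {mark} nucleosome on chromosome {chrom}")
        self.mark = mark
        self.chrom = chrom


def nearest_nucleosome_distance(
    track: NucleosomeTrack, anchor: GenomicPosition
) -> int:
    """Absolute distance from ``anchor`` to the nearest center of ``track``.

    Raises :class:`MissingMarkError` if the track has no center on the
    anchor's chromosome (the caller decides the substitution policy).
    """
    centers = track.centers_on(anchor.chrom)
    if centers.size == 0:
        raise MissingMarkError(track.mark_name, anchor.chrom)
    i = int(np.searchsorted(centers, anchor.pos))
    best = np.inf
    if i < centers.size:
        best = centers[i] - anchor.pos
    if i > 0:
        best = min(best, anchor.pos - centers[i - 1])
    return int(best)


def occupancy_count(
    track: NucleosomeTrack, anchor: GenomicPosition, flank: int = 1000
) -> int:
    """Number of centers in the closed window ``[pos - flank, pos + flank]``."""
    if flank <= 0:
        raise ValueError(f"flank must be > 0, got {flank}")
    centers = track.centers_on(anchor.chrom)
    lo = np.searchsorted(centers, anchor.pos - flank, side="left")
    hi = np.searchsorted(centers, anchor.pos + flank, side="right")
    return int(hi - lo)


def mnn_vector(
    tracks: dict[str, NucleosomeTrack], anchor: GenomicPosition,
    marks: list[str] | None = None,
) -> np.ndarray:
    """Per-mark nearest-neighbor distances at one anchor, in mark order."""
    marks = list(tracks) if marks is None else marks
    return np.array(
        [nearest_nucleosome_distance(tracks[m], anchor) for m in marks],
        dtype=float,
    )


def mno_vector(
    tracks: dict[str, NucleosomeTrack], anchor: GenomicPosition,
    marks: list[str] | None = None, flank: int = 1000,
) -> np.ndarray:
    """Per-mark occupancy counts at one anchor, in mark order."""
    marks = list(tracks) if marks is None else marks
    return np.array(
        [occupancy_count(tracks[m], anchor, flank) for m in marks],
        dtype=float,
    )


@dataclass(frozen=True)
class PositionProfile:
    """Per-offset nucleosome occupancy ratio around binding-site centers."""

    tf_name: str
    mark_name: str
    offsets: np.ndarray  # -(half_window+footprint) .. +(half_window+footprint)
    ratio: np.ndarray

    def __post_init__(self) -> None:
        if self.offsets.shape != self.ratio.shape:
            raise ValueError("offsets and ratio must have matching shapes")
        if np.any(self.ratio < 0):
            raise ValueError("ratios must be non-negative")


def position_profile(
    track: NucleosomeTrack,
    sites: BindingSiteSet,
    half_window: int = 1000,
    footprint: int = 15,
) -> PositionProfile:
    """Distribution of nucleosome positions around binding-site centers.

    Each nucleosome occupies the offsets ``[c - footprint, c + footprint]``
    around its center ``c``.  For every site center ``s``, each nucleosome
    with ``|c - s| <= half_window + footprint`` adds one count to the
    occupied offsets (relative to ``s``) that fall inside the plotted range
    ``[-(half_window + footprint), +(half_window + footprint)]``.  Counts
    are divided by the number of sites.  With the defaults the offsets span
    -1015 .. +1015 (2031 values).
    """
    if len(sites) == 0:
        raise ValueError("binding-site set is empty")
    reach = half_window + footprint
    offsets = np.arange(-reach, reach + 1)
    # accumulate range-additions with a difference array, then prefix-sum
    diff = np.zeros(offsets.size + 1, dtype=np.int64)
    for chrom in sites.chromosomes:
        centers = track.centers_on(chrom)
        if centers.size == 0:
            continue
        for s in sites.centers_on(chrom):
            lo = np.searchsorted(centers, s - reach, side="left")
            hi = np.searchsorted(centers, s + reach, side="right")
            for c in centers[lo:hi]:
                rel = int(c - s)
                a = max(rel - footprint, -reach) + reach
                b = min(rel + footprint, reach) + reach
                diff[a] += 1
                diff[b + 1] -= 1
    counts = np.cumsum(diff[:-1])
    return PositionProfile(
        tf_name=sites.tf_name,
        mark_name=track.mark_name,
        offsets=offsets,
        ratio=counts / len(sites),
    )
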