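"""Core genomic coordinate types and interval arithmetic.

All internal coordinates are 0-based, half-open ``[start, end)``.  External
formats are converted on read (GFF is 1-based inclusive, BED is already
0-based half-open).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomicPosition",
    "GenomicInterval",
    "BindingSite",
    "BindingSiteSet",
    "NucleosomeTrack",
    "bin_chromosome",
    "interval_center",
]


@dataclass(frozen=True)
class GenomicPosition:
    """A single base position on a named chromosome (0-based)."""

    chrom: str
    pos: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chromosome name must be non-empty")
        if self.pos < 0:
            raise ValueError(f"position must be >= 0, got {self.pos}")


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` in 0-based coordinates."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chromosome name must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class BindingSite:
    """One reported binding site: an interval with strand and center.

    The center is the midpoint of the interval, left-of-middle for
    even-length sites (a fixed convention; annotations rarely state one).
    """

    iv: GenomicInterval
    strand: str = "+"
    center: int = field(default=-1)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.center < 0:
            object.__setattr__(self, "center", interval_center(self.iv).pos)
        if not self.iv.contains(self.center):
            raise ValueError(
                f"center {self.center} outside interval "
                f"[{self.iv.start}, {self.iv.end})"
            )


class BindingSiteSet:
    """The reported binding sites of one transcription factor.

    Sites are stored per chromosome, sorted by start coordinate.
    """

    def __init__(self, tf_name: str, sites: Iterable[BindingSite]):
        if not tf_name:
            raise ValueError("tf_name must be non-empty")
        self.tf_name = tf_name
        by_chrom: dict[str, list[BindingSite]] = {}
        for s in sites:
            by_chrom.setdefault(s.iv.chrom, []).append(s)
        self._by_chrom = {
            c: sorted(v, key=lambda s: (s.iv.start, s.iv.end))
            for c, v in sorted(by_chrom.items())
        }

    @property
    def chromosomes(self) -> list[str]:
        return list(self._by_chrom)

    def sites_on(self, chrom: str) -> list[BindingSite]:
        return self._by_chrom.get(chrom, [])

    def __iter__(self):
        for sites in self._by_chrom.values():
            yield from sites

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_chrom.values())

    def centers_on(self, chrom: str) -> np.ndarray:
        """Sorted array of site-center coordinates on one chromosome."""
        return np.sort(
            np.array([s.center for s in self.sites_on(chrom)], dtype=np.int64)
        )

    def subset(self, chroms: Sequence[str]) -> "BindingSiteSet":
        keep = set(chroms)
        return BindingSiteSet(
            self.tf_name, (s for s in self if s.iv.chrom in keep)
        )


class NucleosomeTrack:
    """Center positions of nucleosomes carrying one histone mark.

    Centers are kept per chromosome as strictly increasing int64 arrays;
    duplicate positions collapse to one entry (a position set, not a
    coverage signal).
    """

    def __init__(self, mark_name: str, centers: Mapping[str, Iterable[int]]):
        if not mark_name:
            raise ValueError("mark_name must be non-empty")
        self.mark_name = mark_name
        self._centers: dict[str, np.ndarray] = {}
        for chrom, vals in sorted(centers.items()):
            arr = np.unique(np.asarray(list(vals), dtype=np.int64))
            if arr.size and arr[0] < 0:
                raise ValueError(
                    f"negative nucleosome center on {chrom} for {mark_name}"
                )
            self._centers[chrom] = arr

    @property
    def chromosomes(self) -> list[str]:
        return list(self._centers)

    def centers_on(self, chrom: str) -> np.ndarray:
        """Sorted, deduplicated centers on ``chrom`` (empty if absent)."""
        return self._centers.get(chrom, np.empty(0, dtype=np.int64))

    def n_centers(self) -> int:
        return sum(a.size for a in self._centers.values())


def bin_chromosome(chrom_length: int, bin_size: int = 1000) -> list[tuple[int, int]]:
    """Partition ``[0, chrom_length)`` into consecutive fixed-width bins.

    A trailing partial bin shorter than ``bin_size`` is dropped so that all
    bins have identical width (occupancy counts stay comparable across bins).

    Returns a list of ``(start, end)`` pairs.
    """
    if chrom_length <= 0:
        raise ValueError(f"chrom_length must be > 0, got {chrom_length}")
    if bin_size <= 0:
        raise ValueError(f"bin_size must be > 0, got {bin_size}")
    n = chrom_length // bin_size
    return [(i * bin_size, (i + 1) * bin_size) for i in range(n)]


def interval_center(iv: GenomicInterval) -> GenomicPosition:
    """Midpoint of an interval, left-of-middle for even lengths."""
    return GenomicPosition(iv.chrom, iv.start + (iv.end - iv.start) // 2)
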