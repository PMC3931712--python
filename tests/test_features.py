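import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from epimotif.features import (
    MissingMarkError,
    mnn_vector,
    mno_vector,
    nearest_nucleosome_distance,
    occupancy_count,
    position_profile,
)
from epimotif.genome_model import (
    BindingSite,
    BindingSiteSet,
    GenomicInterval,
    GenomicPosition,
    NucleosomeTrack,
)


def track(centers, mark="H3K4me3", chrom="chr1"):
    return NucleosomeTrack(mark, {chrom: centers})


def site_set(centers, chrom="chr1", tf="TF"):
    return BindingSiteSet(
        tf,
        [
            BindingSite(GenomicInterval(chrom, c - 5, c + 5), center=c)
            for c in centers
        ],
    )


class TestNearestDistance:
    @pytest.mark.parametrize(
        "centers,pos,expected",
        [
            ([5000], 5000, 0),
            ([4000, 5300], 5000, 300),
            ([100], 5000, 4900),
            ([4900, 5100], 5000, 100),  # equidistant tie -> the shared value
        ],
    )
    def test_examples(self, centers, pos, expected):
        d = nearest_nucleosome_distance(track(centers), GenomicPosition("chr1", pos))
        assert d == expected

    def test_missing_chromosome_raises_with_context(self):
        with pytest.raises(MissingMarkError) as exc:
            nearest_nucleosome_distance(track([100]), GenomicPosition("chr9", 5))
        assert exc.value.mark == "H3K4me3"
        assert exc.value.chrom == "chr9"

    @given(
        centers=st.lists(st.integers(0, 10**6), min_size=1, max_size=200),
        pos=st.integers(0, 10**6),
    )
    def test_matches_linear_scan_oracle(self, centers, pos):
        t = track(centers)
        got = nearest_nucleosome_distance(t, GenomicPosition("chr1", pos))
        assert got == min(abs(c - pos) for c in centers)


class TestOccupancy:
    def test_examples(self):
        t = track([4000, 5000, 6100])
        assert occupancy_count(t, GenomicPosition("chr1", 5000), 1000) == 2
        empty = NucleosomeTrack("m", {})
        assert occupancy_count(empty, GenomicPosition("chr1", 5000), 1000) == 0

    def test_window_edges_inclusive(self):
        t = track([4000, 6000])
        assert occupancy_count(t, GenomicPosition("chr1", 5000), 1000) == 2

    def test_invalid_flank(self):
        with pytest.raises(ValueError):
            occupancy_count(track([1]), GenomicPosition("chr1", 5), 0)

    @given(
        centers=st.lists(st.integers(0, 10**5), min_size=0, max_size=100),
        pos=st.integers(0, 10**5),
        flanks=st.tuples(st.integers(1, 5000), st.integers(1, 5000)),
    )
    def test_monotone_in_flank_and_matches_linear_scan(self, centers, pos, flanks):
        t = NucleosomeTrack("m", {"chr1": centers})
        anchor = GenomicPosition("chr1", pos)
        f1, f2 = sorted(flanks)
        c1 = occupancy_count(t, anchor, f1)
        c2 = occupancy_count(t, anchor, f2)
        assert c1 <= c2
        uniq = set(centers)
        assert c2 == sum(1 for c in uniq if pos - f2 <= c <= pos + f2)


class TestVectors:
    def test_mark_order_is_preserved(self):
        tracks = {
            "A": track([100], "A"),
            "B": track([300], "B"),
        }
        anchor = GenomicPosition("chr1", 0)
        assert mnn_vector(tracks, anchor, ["B", "A"]).tolist() == [300.0, 100.0]
        assert mno_vector(tracks, anchor, ["A", "B"], flank=500).tolist() == [
            1.0,
            1.0,
        ]


def brute_force_profile(centers, site_centers, half_window, footprint):
    """Triple loop over (site, nucleosome, offset) as an independent oracle."""
    reach = half_window + footprint
    offsets = np.arange(-reach, reach + 1)
    counts = np.zeros(offsets.size)
    for s in site_centers:
        for c in centers:
            if abs(c - s) > reach:
                continue
            for k, o in enumerate(offsets):
                if c - footprint <= s + o <= c + footprint:
                    counts[k] += 1
    return counts / len(site_centers)


class TestPositionProfile:
    def test_single_site_single_nucleosome(self):
        prof = position_profile(track([5000]), site_set([5000]))
        assert prof.offsets[0] == -1015 and prof.offsets[-1] == 1015
        assert prof.offsets.size == 2031
        inside = np.abs(prof.offsets) <= 15
        assert np.all(prof.ratio[inside] == 1.0)
        assert np.all(prof.ratio[~inside] == 0.0)

    def test_normalization_by_site_count(self):
        prof = position_profile(track([5000]), site_set([5000, 90000]))
        inside = np.abs(prof.offsets) <= 15
        assert np.all(prof.ratio[inside] == 0.5)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        centers = np.sort(rng.integers(0, 20_000, size=60))
        sites = np.sort(rng.choice(np.arange(2000, 18_000), size=5, replace=False))
        prof = position_profile(
            NucleosomeTrack("m", {"chr1": centers}), site_set(sites),
            half_window=1000, footprint=15,
        )
        want = brute_force_profile(
            np.unique(centers), sites, half_window=1000, footprint=15
        )
        assert np.allclose(prof.ratio, want)

    def test_mass_conservation_against_enumeration(self):
        rng = np.random.default_rng(11)
        centers = np.unique(rng.integers(0, 30_000, size=80))
        sites = [5000, 12_000, 21_000]
        prof = position_profile(
            NucleosomeTrack("m", {"chr1": centers}), site_set(sites)
        )
        total = prof.ratio.sum() * len(sites)
        reach = 1015
        expected = 0
        for s in sites:
            for c in centers:
                if abs(c - s) <= reach:
                    lo = max(c - s - 15, -reach)
                    hi = min(c - s + 15, reach)
                    expected += hi - lo + 1
        assert total == pytest.approx(expected)

    def test_translation_invariance(self):
        centers = [4000, 5200, 6100]
        sites = [5000, 6000]
        shift = 12_345
        p0 = position_profile(track(centers), site_set(sites))
        p1 = position_profile(
            track([c + shift for c in centers]),
            site_set([s + shift for s in sites]),
        )
        assert np.array_equal(p0.ratio, p1.ratio)
        # MNN / MNO translate too
        t0, t1 = track(centers), track([c + shift for c in centers])
        a0 = GenomicPosition("chr1", 5000)
        a1 = GenomicPosition("chr1", 5000 + shift)
        assert nearest_nucleosome_distance(t0, a0) == nearest_nucleosome_distance(t1, a1)
        assert occupancy_count(t0, a0, 1000) == occupancy_count(t1, a1, 1000)

    def test_empty_site_set_raises(self):
        with pytest.raises(ValueError):
            position_profile(track([100]), BindingSiteSet("TF", []))
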