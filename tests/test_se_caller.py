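import numpy as np
import pytest

from seforge.genomics_io import GenomicInterval, ReadAlignmentSet, TssAnnotation
from seforge.se_caller import (
    StitchedRegion,
    call_superenhancers,
    exclude_tss_proximal,
    hockey_stick_cutoff,
    score_regions,
    stitch,
)
from seforge.signal_quant import DensityConfig


def iv(chrom, start, end, name=None):
    return GenomicInterval(chrom, start, end, name=name)


class TestExcludeTssProximal:
    def test_fully_contained_removed(self):
        tss = [TssAnnotation("g", "chr1", 10_000)]
        assert exclude_tss_proximal([iv("chr1", 9_500, 10_500)], tss) == []

    def test_partial_overlap_kept(self):
        tss = [TssAnnotation("g", "chr1", 10_000)]
        kept = exclude_tss_proximal([iv("chr1", 7_000, 9_000)], tss)
        assert len(kept) == 1

    def test_empty_tss_is_identity(self):
        cs = [iv("chr1", 0, 100), iv("chr1", 500, 700)]
        assert exclude_tss_proximal(cs, []) == cs

    def test_other_chromosome_unaffected(self):
        tss = [TssAnnotation("g", "chr2", 10_000)]
        assert len(exclude_tss_proximal([iv("chr1", 9_500, 10_500)], tss)) == 1


class TestStitch:
    def test_gap_below_threshold_merges(self):
        regions = stitch([iv("chr1", 1_000, 2_000), iv("chr1", 10_000, 11_000)])
        assert len(regions) == 1
        assert (regions[0].interval.start, regions[0].interval.end) == (1_000, 11_000)
        assert len(regions[0].members) == 2

    def test_boundary_gap_inclusive(self):
        merged = stitch([iv("chr1", 0, 1_000), iv("chr1", 13_500, 14_000)])
        assert len(merged) == 1  # gap exactly 12,500
        split = stitch([iv("chr1", 0, 1_000), iv("chr1", 13_501, 14_000)])
        assert len(split) == 2

    def test_never_merges_across_chromosomes(self):
        regions = stitch([iv("chr1", 0, 1_000), iv("chr2", 0, 1_000)])
        assert len(regions) == 2

    def test_idempotent(self, rng):
        cs = [
            iv("chr1", int(s), int(s) + int(l))
            for s, l in zip(
                np.sort(rng.choice(500_000, 50, replace=False)) * 3,
                rng.integers(100, 2000, 50),
            )
        ]
        once = stitch(cs)
        twice = stitch([r.interval for r in once])
        assert [r.interval for r in twice] == [r.interval for r in once]

    def test_separation_and_member_conservation(self, rng):
        cs = [
            iv("chr1", int(s) * 2, int(s) * 2 + 500)
            for s in np.sort(rng.choice(200_000, 40, replace=False))
        ]
        regions = stitch(cs)
        for a, b in zip(regions, regions[1:]):
            assert b.interval.start - a.interval.end > 12_500
        members = [m for r in regions for m in r.members]
        assert sorted(members, key=lambda m: m.start) == sorted(cs, key=lambda m: m.start)


class TestScoreRegions:
    def _region(self, members):
        return stitch(members)

    def test_density_times_length(self):
        member = iv("chr1", 0, 1_000)
        reads = ReadAlignmentSet(
            [GenomicInterval("chr1", 100, 136, "+") for _ in range(10)], 10**6
        )
        (scored,) = score_regions(self._region([member]), reads)
        # 10 reads / 1e6 total * 1e6 rpm / 1000 bp * 1000 bp = 10
        assert scored.signal == pytest.approx(10.0)

    def test_member_additivity(self):
        members = [iv("chr1", 0, 1_000), iv("chr1", 5_000, 6_000)]
        reads = ReadAlignmentSet(
            [GenomicInterval("chr1", 100, 136, "+") for _ in range(10)]
            + [GenomicInterval("chr1", 5_100, 5_136, "+") for _ in range(5)],
            10**6,
        )
        (scored,) = score_regions(self._region(members), reads)
        assert scored.signal == pytest.approx(15.0)

    def test_control_floor_propagates(self):
        member = iv("chr1", 0, 1_000)
        chip = ReadAlignmentSet([GenomicInterval("chr1", 10, 46, "+")], 10**6)
        ctrl = ReadAlignmentSet(
            [GenomicInterval("chr1", 10, 46, "+") for _ in range(5)], 10**6
        )
        (scored,) = score_regions(self._region([member]), chip, control=ctrl)
        assert scored.signal == 0.0


class TestHockeyStickCutoff:
    def test_worked_vector(self):
        idx, sig = hockey_stick_cutoff([0, 1, 2, 4, 8, 16, 32, 64, 128, 256])
        assert (idx, sig) == (6, 32.0)
        assert sum(s > sig for s in [0, 1, 2, 4, 8, 16, 32, 64, 128, 256]) == 3

    def test_constant_vector_yields_zero_ses(self):
        idx, sig = hockey_stick_cutoff([5, 5, 5, 5])
        assert idx == 3 and sig == 5.0

    def test_linear_ramp_tie_breaks_last(self):
        idx, sig = hockey_stick_cutoff([0, 1, 2, 3, 4])
        assert idx == 4 and sig == 4.0

    def test_scale_invariance(self, rng):
        s = np.sort(rng.exponential(size=50)) ** 3
        idx1, sig1 = hockey_stick_cutoff(s)
        idx2, sig2 = hockey_stick_cutoff(s * 17.5)
        assert idx1 == idx2
        assert np.sum(s > sig1) == np.sum(s * 17.5 > sig2)

    def test_all_zero_is_error(self):
        with pytest.raises(ValueError):
            hockey_stick_cutoff([0.0, 0.0])

    def test_single_value_is_error(self):
        with pytest.raises(ValueError):
            hockey_stick_cutoff([3.0])

    def test_matches_tangency_oracle(self, rng):
        # brute-force: the cutoff is the point whose slope-1 line has no
        # curve point strictly below it (largest such index on ties)
        for _ in range(50):
            n = int(rng.integers(5, 60))
            s = np.cumsum(np.sort(rng.exponential(size=n)))
            idx, _ = hockey_stick_cutoff(s)
            x = np.arange(n) / (n - 1)
            y = np.sort(s) / np.sort(s)[-1]
            tangent = [
                i
                for i in range(n)
                if np.all(y - (y[i] + x - x[i]) >= -1e-12)
            ]
            assert idx == max(tangent)


class TestCallSuperenhancers:
    def test_order_invariance(self, rng):
        cs = [
            iv("chr1", int(s) * 30, int(s) * 30 + 800, name=f"c{i}")
            for i, s in enumerate(np.sort(rng.choice(20_000, 30, replace=False)))
        ]
        reads = []
        for c in cs[:5]:  # plant signal in 5 constituents
            reads += [
                GenomicInterval("chr1", int(p), int(p) + 36, "+")
                for p in rng.integers(c.start, c.end - 36, 200)
            ]
        for c in cs:
            reads += [
                GenomicInterval("chr1", int(p), int(p) + 36, "+")
                for p in rng.integers(c.start, c.end - 36, 10)
            ]
        rs = ReadAlignmentSet(reads, total_mapped=len(reads))
        res1 = call_superenhancers(cs, [], rs)
        perm = [cs[i] for i in rng.permutation(len(cs))]
        res2 = call_superenhancers(perm, [], rs)
        assert [r.interval for r in res1.regions] == [r.interval for r in res2.regions]
        assert res1.is_se == res2.is_se

    def test_single_region_is_error(self):
        cs = [iv("chr1", 0, 1_000)]
        rs = ReadAlignmentSet([GenomicInterval("chr1", 10, 46, "+")], 100)
        with pytest.raises(ValueError):
            call_superenhancers(cs, [], rs)

    def test_se_flag_matches_cutoff(self, rng):
        cs = [
            iv("chr1", i * 20_000, i * 20_000 + 1_000, name=f"c{i}") for i in range(20)
        ]
        reads = []
        for i, c in enumerate(cs):
            n = 300 if i < 3 else 20
            reads += [
                GenomicInterval("chr1", int(p), int(p) + 36, "+")
                for p in rng.integers(c.start, c.end - 36, n)
            ]
        rs = ReadAlignmentSet(reads, total_mapped=len(reads))
        res = call_superenhancers(cs, [], rs)
        for region, flag in zip(res.regions, res.is_se):
            assert flag == (region.signal > res.cutoff_signal)
        assert sum(res.is_se) == 3
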