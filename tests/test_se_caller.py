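"""Stitching, quantification and the rank-curve SE cutoff."""

import numpy as np
import pytest

from crckit.coverage import Coverage
from crckit.intervals import GeneAnnotation, GenomicInterval, Peak
from crckit.se_caller import (
    StitchedEnhancer,
    assign_se_genes,
    quantify,
    rank_and_cut,
    stitch,
)

from oracles import union_find_stitch


def peak(chrom, start, end, **kw):
    return Peak(interval=GenomicInterval(chrom, start, end, **kw))


class TestStitch:
    def test_gap_at_or_below_distance_joins(self):
        enh = stitch([peak("c", 0, 1000), peak("c", 13_000, 14_000)])
        assert len(enh) == 1
        assert (enh[0].span.start, enh[0].span.end) == (0, 14_000)

    def test_gap_above_distance_splits(self):
        enh = stitch([peak("c", 0, 1000), peak("c", 14_000, 15_000)])
        assert len(enh) == 2

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            stitch([peak("c", 0, 10)], stitch_distance=-1)

    def test_matches_union_find_oracle_on_random_peaks(self):
        rng = np.random.default_rng(19)
        peaks = []
        for i in range(300):
            chrom = f"chr{rng.integers(1, 3)}"
            s = int(rng.integers(0, 2_000_000))
            peaks.append(peak(chrom, s, s + int(rng.integers(200, 2000)),
                              name=str(i)))
        enh = stitch(peaks, stitch_distance=12_500)
        got = sorted(
            tuple(sorted(int(p.interval.name) for p in e.constituents))
            for e in enh
        )
        ivs = [p.interval for p in peaks]
        assert got == union_find_stitch(ivs, 12_500)

    def test_order_invariance_and_distance_monotonicity(self):
        rng = np.random.default_rng(5)
        peaks = [
            peak("c", s, s + 500, name=str(i))
            for i, s in enumerate(rng.integers(0, 500_000, size=80))
        ]
        shuffled = list(peaks)
        rng.shuffle(shuffled)
        spans = lambda enh: sorted((e.span.start, e.span.end) for e in enh)
        assert spans(stitch(peaks)) == spans(stitch(shuffled))
        n_prev = None
        for d in (0, 2000, 12_500, 50_000):
            n = len(stitch(peaks, stitch_distance=d))
            if n_prev is not None:
                assert n <= n_prev
            n_prev = n

    def test_tss_exclusion_removes_promoter_constituents(self):
        ann = [GeneAnnotation("g", "S", "c", 5000)]
        peaks = [peak("c", 4000, 6000), peak("c", 40_000, 41_000)]
        enh = stitch(peaks, tss_exclusion=(ann, 2500))
        assert len(enh) == 1 and enh[0].span.start == 40_000

    def test_constituents_partition(self):
        rng = np.random.default_rng(2)
        peaks = [
            peak("c", s, s + 300, name=str(i))
            for i, s in enumerate(sorted(rng.integers(0, 300_000, size=100)))
        ]
        enh = stitch(peaks)
        seen = [p.interval.name for e in enh for p in e.constituents]
        assert sorted(seen) == sorted(p.interval.name for p in peaks)


class TestQuantify:
    def test_constant_coverage_arithmetic(self):
        e = StitchedEnhancer(
            span=GenomicInterval("c", 0, 1000),
            constituents=[peak("c", 0, 1000)],
        )
        cov = Coverage.from_records([("c", 0, 1000, 2.0)])
        assert quantify(e, cov) == pytest.approx(2000.0)

    def test_chip_equal_control_floors_at_zero(self):
        e = StitchedEnhancer(
            span=GenomicInterval("c", 0, 500),
            constituents=[peak("c", 0, 500)],
        )
        cov = Coverage.from_records([("c", 0, 500, 3.0)])
        assert quantify(e, cov, cov) == 0.0

    def test_matches_naive_base_loop(self):
        rng = np.random.default_rng(8)
        cons = [peak("c", 100, 400), peak("c", 600, 900)]
        e = StitchedEnhancer(span=GenomicInterval("c", 100, 900),
                             constituents=cons)
        chip_vals = rng.uniform(0, 5, size=1000)
        ctrl_vals = rng.uniform(0, 2, size=1000)
        chip = Coverage.from_records(
            [("c", i, i + 1, float(chip_vals[i])) for i in range(1000)]
        )
        ctrl = Coverage.from_records(
            [("c", i, i + 1, float(ctrl_vals[i])) for i in range(1000)]
        )
        expected = 0.0
        for p in cons:
            for base in range(p.interval.start, p.interval.end):
                expected += chip_vals[base] - ctrl_vals[base]
        expected = max(0.0, expected)
        assert quantify(e, chip, ctrl) == pytest.approx(expected)

    def test_missing_chromosome_is_an_error(self):
        e = StitchedEnhancer(
            span=GenomicInterval("chrX", 0, 100),
            constituents=[peak("chrX", 0, 100)],
        )
        with pytest.raises(KeyError):
            quantify(e, Coverage.from_records([("c", 0, 10, 1.0)]))


def enhancers_from_signals(signals):
    out = []
    for i, s in enumerate(signals):
        e = StitchedEnhancer(
            span=GenomicInterval("c", i * 1000, i * 1000 + 500),
            constituents=[peak("c", i * 1000, i * 1000 + 500)],
            signal=float(s),
        )
        out.append(e)
    return out


class TestRankAndCut:
    def test_flat_curve_has_zero_supers(self):
        r = rank_and_cut(enhancers_from_signals([5.0] * 10))
        assert r.n_super == 0

    def test_needs_at_least_two(self):
        with pytest.raises(ValueError):
            rank_and_cut(enhancers_from_signals([1.0]))

    def test_geometric_series_matches_numeric_slope_oracle(self):
        signals = [2.0**i for i in range(64)]
        r = rank_and_cut(enhancers_from_signals(signals))
        # independent dense numeric evaluation of the rescaled curve
        s = np.sort(np.array(signals))
        x = np.linspace(0.0, 1.0, len(s))
        y = (s - s[0]) / (s[-1] - s[0])
        grid = np.linspace(0.0, 1.0, 200_001)
        dense = np.interp(grid, x, y)
        slope = np.gradient(dense, grid)
        first = np.nonzero(slope >= 1.0)[0][0]
        # map the crossing back to the segment's lower endpoint
        seg = int(np.clip(np.floor(grid[first] * (len(s) - 1)), 0, len(s) - 2))
        assert r.cutoff_signal == pytest.approx(s[seg], rel=1e-9)
        assert r.n_super == int((s > s[seg]).sum())

    def test_ranks_are_descending_and_supers_above_cutoff(self):
        rng = np.random.default_rng(1)
        r = rank_and_cut(enhancers_from_signals(rng.lognormal(3, 1, size=200)))
        sig = [e.signal for e in r.enhancers]
        assert sig == sorted(sig, reverse=True)
        for e in r.enhancers:
            assert e.is_super == (e.signal > r.cutoff_signal)

    def test_boosting_a_constituent_never_lowers_rank(self):
        rng = np.random.default_rng(4)
        signals = rng.lognormal(3, 1, size=50)
        base = rank_and_cut(enhancers_from_signals(signals))
        target = base.enhancers[30]  # some mid-ranked enhancer
        boosted_signals = [
            e.signal + (5.0 if e.span == target.span else 0.0)
            for e in base.enhancers
        ]
        boosted = rank_and_cut(enhancers_from_signals_like(base.enhancers,
                                                           boosted_signals))
        new_rank = next(
            e.rank for e in boosted.enhancers if e.span == target.span
        )
        assert new_rank <= target.rank


def enhancers_from_signals_like(enhancers, signals):
    return [
        StitchedEnhancer(span=e.span, constituents=e.constituents,
                         signal=float(s))
        for e, s in zip(enhancers, signals)
    ]


class TestAssignSeGenes:
    def ranking(self, spans):
        enh = []
        for i, (s, e) in enumerate(spans):
            enh.append(
                StitchedEnhancer(
                    span=GenomicInterval("c", s, e),
                    constituents=[peak("c", s, e)],
                    signal=float(1000 - i),
                )
            )
        return rank_and_cut(enh + enhancers_from_signals([1.0, 1.0]))

    def test_tss_inside_span_is_assigned(self):
        r = self.ranking([(10_000, 20_000)])
        ann = [GeneAnnotation("g1", "S1", "c", 15_000)]
        genes = assign_se_genes(r, ann)
        (gene_list,) = [v for k, v in genes.items() if "10000" in k]
        assert [g.symbol for g in gene_list] == ["S1"]

    def test_distant_nearest_gene_is_sole_fallback(self):
        r = self.ranking([(10_000, 20_000)])
        ann = [
            GeneAnnotation("g1", "S1", "c", 80_000),   # 60 kb away
            GeneAnnotation("g2", "S2", "c", 200_000),
        ]
        genes = assign_se_genes(r, ann, window=50_000)
        (gene_list,) = [v for k, v in genes.items() if "10000" in k]
        assert [g.symbol for g in gene_list] == ["S1"]

    def test_matches_exhaustive_window_filter(self):
        rng = np.random.default_rng(6)
        spans = sorted(
            {(int(s), int(s) + 5000) for s in rng.integers(0, 3_000_000, size=10)}
        )
        r = self.ranking(spans)
        ann = [
            GeneAnnotation(f"g{i:02d}", f"S{i}", "c",
                           int(rng.integers(0, 3_100_000)))
            for i in range(40)
        ]
        got = assign_se_genes(r, ann, window=50_000)
        for e in r.supers:
            expected = set()
            for g in ann:
                if e.span.start - 50_000 <= g.tss <= e.span.end - 1 + 50_000:
                    expected.add(g.gene_id)
            if not expected:
                continue  # fallback case covered above
            assert {g.gene_id for g in got[e.enhancer_id]} == expected
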