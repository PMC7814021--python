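"""PWM scoring, exact DP p-values, scanning and window conventions."""

import itertools

import numpy as np
import pytest

from crckit.intervals import GenomicInterval, Peak
from crckit.motifs import (
    PWM,
    logodds,
    make_windows,
    read_meme,
    scan,
    score_pvalue,
    write_meme,
)
from crckit.sequences import InMemoryGenome, revcomp

from oracles import exhaustive_word_scores


def random_pwm(rng, width=5, name="m"):
    return PWM(name=name, probs=rng.dirichlet(np.ones(4) * 0.8, size=width))


class TestLogodds:
    def test_uniform_pwm_scores_zero_everywhere(self):
        pwm = PWM(name="u", probs=np.full((4, 4), 0.25), pseudocount=0.0)
        for word in ("ACGT", "AAAA", "TTTT", "ANGT"):
            assert logodds(pwm, word) == pytest.approx(0.0)

    def test_certain_position_scores_two_bits(self):
        # P(A)=1 per position with zero pseudocount: log2(1/0.25) = 2 bits
        probs = np.zeros((4, 4))
        probs[:, 0] = 1.0
        pwm = PWM(name="a", probs=probs, pseudocount=0.0)
        assert logodds(pwm, "AAAA") == pytest.approx(8.0)  # 2 bits x 4

    def test_ambiguous_base_contributes_background_mean(self):
        probs = np.zeros((4, 4))
        probs[:, 0] = 1.0
        pwm = PWM(name="a", probs=probs, pseudocount=0.0)
        # N at one position replaces a +2.0 contribution with the
        # background-weighted mean of (2, -inf...) -> with zero pseudocount
        # the mean is -inf; use a soft PWM instead
        soft = PWM(name="s", probs=np.full((4, 4), 0.25), pseudocount=0.0)
        assert logodds(soft, "ANNT") == pytest.approx(0.0)

    def test_rejects_bad_words(self):
        pwm = PWM(name="u", probs=np.full((5, 4), 0.25))
        with pytest.raises(ValueError):
            logodds(pwm, "ACGT")  # wrong length
        with pytest.raises(ValueError):
            logodds(pwm, "ACGTX")

    def test_matches_exhaustive_evaluation_width5(self):
        rng = np.random.default_rng(13)
        pwm = random_pwm(rng, width=5)
        expected = exhaustive_word_scores(pwm)
        for word, exp in expected.items():
            assert logodds(pwm, word) == pytest.approx(exp, abs=1e-9)


class TestScorePvalue:
    def test_minimum_score_has_pvalue_one(self):
        rng = np.random.default_rng(1)
        pwm = random_pwm(rng, width=6)
        smin = min(exhaustive_word_scores(pwm).values())
        assert score_pvalue(pwm, smin) == 1.0

    def test_unique_top_word_tail_is_quarter_to_the_width(self):
        rng = np.random.default_rng(2)
        # near-certain consensus, distinct per position -> unique best word
        probs = np.full((6, 4), 0.01 / 3)
        for i in range(6):
            probs[i, i % 4] = 0.99
        pwm = PWM(name="c", probs=probs, pseudocount=0.0)
        smax = max(exhaustive_word_scores(pwm).values())
        assert score_pvalue(pwm, smax) == pytest.approx(0.25**6, abs=1e-12)

    def test_monotone_non_increasing_in_score(self):
        rng = np.random.default_rng(3)
        pwm = random_pwm(rng, width=6)
        scores = np.linspace(-10, 12, 60)
        ps = [score_pvalue(pwm, s) for s in scores]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    @pytest.mark.parametrize("trial", range(4))
    def test_matches_exhaustive_enumeration(self, trial):
        rng = np.random.default_rng(100 + trial)
        pwm = random_pwm(rng, width=6, name=f"t{trial}")
        scores = np.sort(list(exhaustive_word_scores(pwm).values()))
        uniq = np.unique(scores)
        gaps = np.diff(uniq)
        big = np.nonzero(gaps > 1e-3)[0]
        for i in big[np.linspace(0, len(big) - 1, 5).astype(int)]:
            t = (uniq[i] + uniq[i + 1]) / 2
            p_enum = float((scores >= t).mean())
            assert abs(score_pvalue(pwm, t) - p_enum) <= 1e-6


class TestScan:
    def planted_genome(self, word, offset=120, length=400, seed=5):
        rng = np.random.default_rng(seed)
        seq = list("ACGT"[i] for i in rng.integers(0, 4, size=length))
        seq[offset : offset + len(word)] = list(word)
        return InMemoryGenome({"chr1": "".join(seq)})

    def consensus_pwm(self, word, name="tf"):
        probs = np.full((len(word), 4), 0.04)
        for i, b in enumerate(word):
            probs[i, "ACGT".index(b)] = 0.88
        return PWM(name=name, probs=probs)

    def test_planted_word_is_recovered_at_its_offset(self):
        word = "ACGTACGTT"
        genome = self.planted_genome(word)
        region = GenomicInterval("chr1", 0, 400, name="r")
        hits = scan([region], genome, [self.consensus_pwm(word)])
        assert any(h.offset == 120 and h.strand == "+" for h in hits)

    def test_all_n_region_yields_no_hits(self):
        genome = InMemoryGenome({"chr1": "N" * 300})
        region = GenomicInterval("chr1", 0, 300)
        assert scan([region], genome, [self.consensus_pwm("ACGTACGT")]) == []

    def test_region_outside_chromosome_is_an_error(self):
        genome = InMemoryGenome({"chr1": "ACGT" * 50})
        with pytest.raises(ValueError):
            scan([GenomicInterval("chr1", 0, 500)], genome,
                 [self.consensus_pwm("ACGTACGT")])

    def test_strand_symmetry_under_reverse_complement(self):
        rng = np.random.default_rng(17)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=600))
        pwms = [random_pwm(rng, width=7, name="x")]
        fwd = scan([GenomicInterval("chr1", 0, 600)],
                   InMemoryGenome({"chr1": seq}), pwms, p_threshold=5e-3)
        rev = scan([GenomicInterval("chr1", 0, 600)],
                   InMemoryGenome({"chr1": revcomp(seq)}), pwms,
                   p_threshold=5e-3)
        key = lambda hits: sorted((round(h.score, 6), round(h.pvalue, 12))
                                  for h in hits)
        flip = {"+": "-", "-": "+"}
        assert key(fwd) == key(rev)
        assert sorted(flip[h.strand] for h in fwd) == sorted(
            h.strand for h in rev
        )

    def test_matches_naive_double_strand_rescan(self):
        import networkx as nx

        rng = np.random.default_rng(23)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=20_000))
        genome = InMemoryGenome({"chr1": seq})
        pwms = [random_pwm(rng, width=6, name=f"m{k}") for k in range(3)]
        regions = []
        for i in range(50):
            s = int(rng.integers(0, 19_000))
            regions.append(
                GenomicInterval("chr1", s, s + int(rng.integers(30, 500)),
                                name=f"r{i}")
            )
        p_thr = 2e-3
        got = {
            (h.region.name, h.pwm_name, h.offset, h.strand,
             round(h.score, 4), round(h.pvalue, 10))
            for h in scan(regions, genome, pwms, p_threshold=p_thr)
        }

        gran = 1e-4
        expected = set()
        for pwm in pwms:
            w = pwm.width
            for region in regions:
                rseq = genome.fetch(region.chrom, region.start, region.end)
                for strand in "+-":
                    raw = []
                    for off in range(0, len(rseq) - w + 1):
                        window = rseq[off : off + w]
                        word = window if strand == "+" else revcomp(window)
                        # direct per-position evaluation on the documented
                        # integer grid (per-position rounding, then sum)
                        s_int = sum(
                            round(np.log2(pwm.probs[i, "ACGT".index(b)] / 0.25)
                                  / gran)
                            for i, b in enumerate(word)
                        )
                        s = s_int * gran
                        p = score_pvalue(pwm, s)
                        if p <= p_thr:
                            raw.append((off, s, p))
                    # independent dedup: components of the overlap graph
                    g = nx.Graph()
                    g.add_nodes_from(range(len(raw)))
                    for i_, (o1, _, _) in enumerate(raw):
                        for j_, (o2, _, _) in enumerate(raw):
                            if i_ < j_ and abs(o1 - o2) < w:
                                g.add_edge(i_, j_)
                    for comp in nx.connected_components(g):
                        best = max(
                            (raw[i_] for i_ in comp),
                            key=lambda t: (t[1], -t[0]),
                        )
                        expected.add(
                            (region.name, pwm.name, best[0], strand,
                             round(best[1], 4), round(best[2], 10))
                        )
        assert got == expected


class TestMakeWindows:
    def peak_at(self, center, summit=True, width=200):
        start = center - width // 2
        return Peak(
            interval=GenomicInterval("c", start, start + width),
            summit_offset=(width // 2) if summit else None,
        )

    def test_tf_peak_window_convention(self):
        # +/-100 bp around the center: 201 bp half-open window
        (w,) = make_windows([self.peak_at(5000)], mode="tf_peak")
        assert (w.start, w.end) == (4900, 5101)

    def test_atac_window_clips_at_chromosome_start(self):
        p = Peak(interval=GenomicInterval("c", 0, 60), summit_offset=30)
        (w,) = make_windows([p], mode="atac")
        assert (w.start, w.end) == (0, 81)

    def test_center_is_summit_else_midpoint(self):
        with_summit = Peak(interval=GenomicInterval("c", 1000, 1200),
                           summit_offset=20)
        without = Peak(interval=GenomicInterval("c", 1000, 1200))
        w1, w2 = make_windows([with_summit, without], mode="atac")
        assert w1.start == 1020 - 50
        assert w2.start == 1100 - 50

    def test_unknown_mode_is_an_error(self):
        with pytest.raises(ValueError, match="mode"):
            make_windows([], mode="bogus")

    def test_clip_at_chromosome_end(self):
        p = Peak(interval=GenomicInterval("c", 900, 1000), summit_offset=50)
        (w,) = make_windows([p], mode="se_te", chrom_sizes={"c": 1000})
        assert (w.start, w.end) == (0, 1000)


class TestMemeIO:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(9)
        pwms = [random_pwm(rng, width=8, name=f"TF{k}") for k in range(3)]
        path = tmp_path / "motifs.meme"
        write_meme(path, pwms)
        back = read_meme(path)
        assert [p.name for p in back] == ["TF0", "TF1", "TF2"]
        for a, b in zip(pwms, back):
            # the reader re-applies its pseudocount: p -> (p+c)/(1+4c) with
            # c=1e-3 shifts any entry by at most 4e-3
            np.testing.assert_allclose(a.probs, b.probs, rtol=0, atol=4e-3)
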