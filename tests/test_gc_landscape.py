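"""Windowed GC, SD scaling, GC3, dN/dS partition, bins, flank correlation."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from carapace.gc import (
    GCWindowSpec, GeneComposition, expected_sd, flank_gc_correlation,
    gc3, gc_bins, partition_dnds, sd_profile, window_gc,
)
from carapace.synthetic import simulate_gc_genome


class TestWindowGC:
    def test_direct_count(self):
        profile = window_gc("ACGT", GCWindowSpec(2))
        assert list(profile.values) == [0.5, 0.5]

    def test_all_gc(self):
        assert list(window_gc("GGGG", GCWindowSpec(2)).values) == [1.0, 1.0]

    def test_trailing_partial_window_dropped(self):
        assert len(window_gc("ACGTA", GCWindowSpec(2)).values) == 2

    def test_missing_data_exclusion(self):
        # 3 N in a 10-base window is 30% missing: over the 20% cap
        seq = "GCGCGCGNNN" + "ATATATATAT"
        profile = window_gc(seq, GCWindowSpec(10))
        assert profile.n_excluded == 1
        assert list(profile.values) == [0.0]

    def test_gc_over_non_n_bases(self):
        # one N allowed: GC is 5 of 9 non-N bases, not 5 of 10
        profile = window_gc("GCGCGATATN", GCWindowSpec(10))
        assert profile.values[0] == pytest.approx(5 / 9)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            window_gc("", GCWindowSpec(10))

    @given(st.text(alphabet="ACGTN", min_size=4, max_size=120),
           st.integers(2, 10))
    @settings(max_examples=150, deadline=None)
    def test_matches_character_counting(self, seq, w):
        profile = window_gc(seq, GCWindowSpec(w, max_missing=0.5))
        expected = []
        for i in range(0, (len(seq) // w) * w, w):
            win = seq[i:i + w]
            n_n = win.count("N")
            if n_n > 0.5 * w:
                continue
            non_n = w - n_n
            expected.append((win.count("G") + win.count("C")) / non_n
                            if non_n else 0.0)
        assert np.allclose(profile.values, expected)


class TestSDScaling:
    def test_closed_form(self):
        assert expected_sd(GCWindowSpec(4, 0.5)) == 0.25
        assert expected_sd(GCWindowSpec(5000, 0.41)) == \
            pytest.approx(math.sqrt(0.41 * 0.59 / 5000))

    def test_quadrupling_halves_exactly(self):
        for p, w in [(0.41, 5000), (0.5, 128), (0.2, 13)]:
            ratio = expected_sd(GCWindowSpec(4 * w, p)) / \
                expected_sd(GCWindowSpec(w, p))
            assert ratio == pytest.approx(0.5, abs=1e-12)

    def test_constant_sequence_has_zero_sd(self):
        assert sd_profile("G" * 10000, [100, 500]) == [(100, 0.0), (500, 0.0)]

    def test_homogeneous_genome_matches_iid_expectation(self):
        genome = simulate_gc_genome(4_000_000, "homogeneous", 0.5, seed=2)
        for w, sd in sd_profile(genome, [2000, 8000], gc=0.5):
            assert sd == pytest.approx(expected_sd(GCWindowSpec(w, 0.5)),
                                       rel=0.05)

    def test_blockwise_genome_declines_slower_than_homogeneous(self):
        # below the block scale the between-block variance floor keeps the
        # SD from halving per quadrupling: the isochore signature
        genome = simulate_gc_genome(4_000_000, "blockwise", 0.45,
                                    block_length=100_000, gc_spread=0.1,
                                    seed=3)
        prof = dict(sd_profile(genome, [5000, 20000], gc=0.45))
        assert prof[20000] / prof[5000] > 0.6

    def test_too_few_windows_omitted_with_warning(self):
        with pytest.warns(UserWarning):
            out = sd_profile("ACGT" * 500, [1500, 100])
        assert [w for w, _sd in out] == [100]


class TestGC3:
    @pytest.mark.parametrize("cds,expected", [
        ("ATGGCATTT", 1 / 3),   # thirds G, A, T
        ("ATGGCG", 1.0),        # thirds G, G
        ("ATGGCATT", 0.5),      # trailing 2-mer ignored: thirds G, A
    ])
    def test_third_position_counting(self, cds, expected):
        assert gc3(cds) == pytest.approx(expected)

    def test_n_at_third_positions_excluded(self):
        # thirds G, N, C -> 2 usable, both GC... G and C: 2/2
        assert gc3("ATGGCNGCC") == pytest.approx(1.0)

    def test_no_complete_codon_rejected(self):
        with pytest.raises(ValueError):
            gc3("AT")

    @given(st.text(alphabet="ACGT", min_size=3, max_size=90))
    @settings(max_examples=100, deadline=None)
    def test_matches_character_counting(self, cds):
        thirds = [cds[i] for i in range(2, (len(cds) // 3) * 3, 3)]
        assert gc3(cds) == pytest.approx(
            sum(c in "GC" for c in thirds) / len(thirds))


def exact_mw_pvalue(x, y):
    """Two-sided exact Mann-Whitney p by full enumeration (tie-free data)."""
    pooled = list(x) + list(y)
    n = len(x)
    u_obs = sum(1 for xi in x for yi in y if xi > yi)
    us = []
    for idx in itertools.combinations(range(len(pooled)), n):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(sum(1 for xi in xs for yi in ys if xi > yi))
    us = np.array(us)
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(p, 1.0)


class TestPartitionDnds:
    def test_two_vs_two_exact_enumeration(self):
        genes = [GeneComposition("a", 0.8, 0.1), GeneComposition("b", 0.9, 0.2),
                 GeneComposition("c", 0.2, 0.3), GeneComposition("d", 0.3, 0.4)]
        high, low, u, p = partition_dnds(genes)
        assert u == 0
        assert p == pytest.approx(2 / 6)
        assert high["median_dnds"] < low["median_dnds"]

    def test_fully_tied_data_gives_p_one(self):
        genes = [GeneComposition(f"g{i}", g, 0.25)
                 for i, g in enumerate([0.8, 0.9, 0.2, 0.3])]
        *_rest, p = partition_dnds(genes)
        assert p == 1.0

    def test_ties_at_median_go_low(self):
        genes = [GeneComposition(f"g{i}", g, d) for i, (g, d) in enumerate(
            [(0.5, 0.1), (0.5, 0.2), (0.5, 0.3), (0.9, 0.4), (0.8, 0.5)])]
        high, low, _u, _p = partition_dnds(genes)
        assert (high["n"], low["n"]) == (2, 3)

    def test_degenerate_split_rejected(self):
        genes = [GeneComposition(f"g{i}", 0.5, 0.1 * i) for i in range(4)]
        with pytest.raises(ValueError):
            partition_dnds(genes)

    def test_exact_p_matches_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            n = int(rng.integers(5, 12))
            gc3s = rng.permutation(np.arange(1, n + 1)) / (n + 1)
            dnds = rng.permutation(np.arange(1, n + 1)) / 10.0
            genes = [GeneComposition(f"g{i}", gc3s[i], dnds[i])
                     for i in range(n)]
            med = np.median(gc3s)
            x = [g.dnds for g in genes if g.gc3 > med]
            y = [g.dnds for g in genes if g.gc3 <= med]
            *_s, p = partition_dnds(genes)
            assert p == pytest.approx(exact_mw_pvalue(x, y))

    def test_direction_on_synthetic_gradient(self):
        # low-GC3 genes drawn with stochastically larger dN/dS
        rng = np.random.default_rng(11)
        genes = []
        for i in range(200):
            g = rng.uniform(0.3, 0.7)
            d = rng.gamma(2.0, 0.1 if g > 0.5 else 0.25)
            genes.append(GeneComposition(f"g{i}", g, d))
        high, low, _u, p = partition_dnds(genes)
        assert high["median_dnds"] < low["median_dnds"]
        assert p < 0.01


class TestGCBins:
    def test_one_item_per_bin(self):
        items = [(100, 0.3), (200, 0.4), (300, 0.5), (400, 0.6)]
        bins = gc_bins(items, 4, "by_length")
        assert [gc for _rng, gc in bins] == [0.3, 0.4, 0.5, 0.6]
        assert bins[0][0] == (100, 100)

    def test_single_bin_is_weighted_mean(self):
        items = [(100, 0.3), (100, 0.5)] * 4
        ((_rng, pooled),) = gc_bins(items, 1)
        assert pooled == pytest.approx(0.4)

    def test_weighting_by_length(self):
        ((_rng, pooled),) = gc_bins([(300, 0.4), (100, 0.8)], 1)
        assert pooled == pytest.approx((0.4 * 300 + 0.8 * 100) / 400)

    def test_monotone_gc_in_length_gives_monotone_bins(self):
        items = [(ln, ln / 1000) for ln in range(100, 600, 50)]
        bins = gc_bins(items, 5, "by_length")
        gcs = [gc for _rng, gc in bins]
        assert gcs == sorted(gcs)
        # direct recomputation per bin
        ordered = sorted(items)
        for i, (_rng, gc) in enumerate(bins):
            chunk = ordered[i * 2:(i + 1) * 2]
            assert gc == pytest.approx(
                sum(g * ln for ln, g in chunk) / sum(ln for ln, _ in chunk))

    def test_remainder_goes_to_last_bin(self):
        items = [(100, 0.5)] * 7
        bins = gc_bins(items, 3)
        assert len(bins) == 3  # 2 + 2 + 3 items

    def test_fewer_items_than_bins_rejected(self):
        with pytest.raises(ValueError):
            gc_bins([(100, 0.5)], 2)


class TestFlankCorrelation:
    def test_perfect_correlation(self):
        genes = [GeneComposition(f"g{i}", 0.5, 0.1, gene_gc=g, flank_gc=g)
                 for i, g in enumerate([0.3, 0.4, 0.5, 0.6])]
        r, n = flank_gc_correlation(genes)
        assert r == pytest.approx(1.0)
        assert n == 4

    def test_missing_flanks_excluded_from_n(self):
        genes = [GeneComposition(f"g{i}", 0.5, 0.1, gene_gc=g, flank_gc=g)
                 for i, g in enumerate([0.3, 0.4, 0.5])]
        genes.append(GeneComposition("g4", 0.5, 0.1, gene_gc=0.7,
                                     flank_gc=None))
        _r, n = flank_gc_correlation(genes)
        assert n == 3

    def test_independent_flanks_near_zero(self):
        rng = np.random.default_rng(5)
        n = 400
        genes = [GeneComposition(f"g{i}", 0.5, 0.1,
                                 gene_gc=rng.uniform(0.3, 0.7),
                                 flank_gc=rng.uniform(0.3, 0.7))
                 for i in range(n)]
        r, _n = flank_gc_correlation(genes)
        assert abs(r) < 3 / math.sqrt(n)

    def test_zero_variance_rejected(self):
        genes = [GeneComposition(f"g{i}", 0.5, 0.1, gene_gc=0.5, flank_gc=g)
                 for i, g in enumerate([0.3, 0.4, 0.5])]
        with pytest.raises(ValueError):
            flank_gc_correlation(genes)
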