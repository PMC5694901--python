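"""Differential accessibility, enrichment testing and gene classes."""
import itertools
import math

import numpy as np
import pytest
from scipy import stats

from starrkit.intervals import GeneModel, GenomicInterval
from starrkit.simulate import SimulationConfig, simulate_expression_and_tsa, simulate_genome
from starrkit.tsa import (
    ConditionCounts,
    TwoByTwo,
    _exact_two_group_p,
    _log_binom_sf,
    classify_gene_classes,
    differential_accessibility,
    enrichment_test,
    tsa_overlap_classify,
)


def region(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


def make_counts(counts, conditions=("vehicle",) * 3 + ("treated",) * 3, lib_sizes=None):
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    regions = [region(1000 * i, 1000 * i + 500) for i in range(counts.shape[0])]
    if lib_sizes is None:
        lib_sizes = np.full(counts.shape[1], 1e6)
    return ConditionCounts(regions, counts, list(conditions), np.asarray(lib_sizes))


class TestDifferentialAccessibility:
    def test_identical_conditions_not_called(self):
        cc = make_counts([[100, 100, 100, 100, 100, 100]] * 5)
        sites, excluded = differential_accessibility(cc)
        assert sites == [] and excluded == []

    def test_all_zero_region_excluded(self):
        cc = make_counts([[0, 0, 0, 0, 0, 0], [10, 12, 9, 60, 55, 70]])
        sites, excluded = differential_accessibility(cc)
        assert len(excluded) == 1
        assert excluded[0].start == 0

    def test_direction_labels(self):
        cc = make_counts(
            [[10, 12, 9, 60, 55, 70], [80, 90, 85, 10, 12, 9]], lib_sizes=np.full(6, 1e6)
        )
        sites, _ = differential_accessibility(cc, dispersion=0.0)
        dirs = {s.region.start: s.direction for s in sites}
        assert dirs[0] == "gain" and dirs[1000] == "loss"

    def test_poisson_limit_of_nb_exact_test(self):
        for ya, yb in [(30, 10), (5, 5), (100, 40), (0, 7)]:
            p_nb = _exact_two_group_p(ya, yb, 3, 3, 1e-9)
            p_po = _exact_two_group_p(ya, yb, 3, 3, 0.0)
            assert p_nb == pytest.approx(p_po, abs=1e-6)

    def test_poisson_branch_matches_conditional_binomial(self):
        # with equal group sizes, the dispersion-0 exact test is the
        # two-sided equal-tailed binomial test conditional on the total
        ya, yb = 30, 10
        t = ya + yb
        pmf = stats.binom.pmf(np.arange(t + 1), t, 0.5)
        expected = pmf[pmf <= pmf[ya] * (1 + 1e-9)].sum()
        assert _exact_two_group_p(ya, yb, 3, 3, 0.0) == pytest.approx(expected, rel=1e-9)

    def test_planted_gains_recovered_with_controlled_false_calls(self):
        # 5x gain in 100 of 2000 regions, 3 vs 3 samples, NB dispersion 0.1
        rng = np.random.default_rng(42)
        n_regions, n_gain = 2000, 100
        base = 100.0
        alpha = 0.1
        r = 1 / alpha

        def draw(mean, size):
            return rng.negative_binomial(r, r / (r + mean), size=size)

        counts = np.zeros((n_regions, 6))
        counts[:, :3] = draw(base, (n_regions, 3))
        counts[:, 3:] = draw(base, (n_regions, 3))
        counts[:n_gain, 3:] = draw(5 * base, (n_gain, 3))
        cc = make_counts(counts)
        sites, _ = differential_accessibility(cc)
        called = {s.region.start // 1000 for s in sites if s.direction == "gain"}
        tp = len(called & set(range(n_gain)))
        assert tp / n_gain >= 0.8
        assert (len(called) - tp) <= 0.1 * max(len(called), 1)

    def test_null_generator_yields_almost_no_calls(self):
        cfg = SimulationConfig(seed=9, tsa_opened_fraction=0.0,
                               tsa_opened_fraction_inactive=0.0,
                               n_input_fragments=0, n_output_fragments=0)
        truth = simulate_genome(cfg)
        _, atac = simulate_expression_and_tsa(cfg, truth)
        sites, _ = differential_accessibility(atac)
        assert len(sites) <= 0.01 * len(atac.regions)


class TestTsaOverlapClassify:
    def test_constructed_fixture_exact_table(self):
        active = [region(i * 1000, i * 1000 + 100) for i in range(10)]
        inactive = [region(100_000 + i * 1000, 100_000 + i * 1000 + 100) for i in range(10)]
        gains = [region(i * 1000, i * 1000 + 50) for i in range(3)] + [
            region(100_000 + i * 1000, 100_000 + i * 1000 + 50) for i in range(2)
        ]
        table, overlap = tsa_overlap_classify(active, inactive, gains)
        assert (table.a, table.b, table.c, table.d) == (3, 7, 2, 8)
        assert len(overlap) == 3

    def test_empty_gain_sites(self):
        table, overlap = tsa_overlap_classify([region(0, 10)], [region(100, 110)], [])
        assert (table.a, table.c) == (0, 0)
        assert overlap == []

    def test_overlapping_classes_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            tsa_overlap_classify([region(0, 100)], [region(50, 150)], [])

    def test_matches_brute_force(self, rng):
        active = [region(int(s), int(s) + 50) for s in rng.integers(0, 50_000, 30) * 2]
        inactive = [region(int(s) + 200_000, int(s) + 200_050) for s in rng.integers(0, 50_000, 30)]
        gains = [region(int(s), int(s) + 80) for s in rng.integers(0, 300_000, 40)]
        table, _ = tsa_overlap_classify(active, inactive, gains)
        brute_a = sum(any(a.overlaps(g) for g in gains) for a in active)
        brute_c = sum(any(i.overlaps(g) for g in gains) for i in inactive)
        assert (table.a, table.b) == (brute_a, len(active) - brute_a)
        assert (table.c, table.d) == (brute_c, len(inactive) - brute_c)
        assert table.a + table.b == len(active)
        assert table.c + table.d == len(inactive)


def fisher_enumeration(a, b, c, d):
    """One-sided enrichment p by hypergeometric enumeration."""
    n, K, k = a + b + c + d, a + b, a + c
    total = math.comb(n, k)
    p = 0
    for x in range(a, min(K, k) + 1):
        if k - x > n - K:
            continue
        p += math.comb(K, x) * math.comb(n - K, k - x)
    return p / total


class TestEnrichmentTest:
    def test_diagonal_table(self):
        p, odds = enrichment_test(TwoByTwo(3, 0, 0, 3), "fisher")
        assert p == pytest.approx(1 / 20)
        assert odds > 1

    def test_zero_a_with_nonzero_margins(self):
        p, _ = enrichment_test(TwoByTwo(0, 5, 3, 7), "fisher")
        assert p == pytest.approx(1.0)

    def test_fisher_matches_enumeration_small_sweep(self):
        for a, b, c, d in itertools.product(range(5), repeat=4):
            if min(a + b, c + d) == 0 or a + b + c + d == 0:
                continue
            p, _ = enrichment_test(TwoByTwo(a, b, c, d), "fisher")
            assert p == pytest.approx(fisher_enumeration(a, b, c, d), rel=1e-9)

    def test_binomial_log_space_tail(self):
        log10p = _log_binom_sf(615, 3263, 0.03)
        assert log10p < -250
        # high-precision oracle via log-gamma summation
        from scipy.special import gammaln, logsumexp

        ks = np.arange(615, 3264)
        logs = (
            gammaln(3264) - gammaln(ks + 1) - gammaln(3264 - ks)
            + ks * math.log(0.03) + (3263 - ks) * math.log(0.97)
        )
        assert log10p == pytest.approx(logsumexp(logs) / math.log(10), rel=1e-10)

    def test_haldane_odds_ratio_with_zero_cell(self):
        table = TwoByTwo(5, 0, 2, 10)
        assert table.odds_ratio == pytest.approx((5.5 * 10.5) / (0.5 * 2.5))

    def test_degenerate_margins_rejected(self):
        with pytest.raises(ValueError):
            enrichment_test(TwoByTwo(0, 0, 3, 4), "fisher")
        with pytest.raises(ValueError, match="p0"):
            enrichment_test(TwoByTwo(1, 1, 1, 1), "binomial")


def gene_at(tss, gid="g", chrom="chr1"):
    return GeneModel(gid, GenomicInterval(chrom, max(tss - 100, 0), tss + 100, "+"), tss, 200)


class TestClassifyGeneClasses:
    def test_class_one_example(self):
        g = gene_at(100_000, "g1")
        classes = classify_gene_classes([g], [region(130_000, 131_000)], [], [])
        assert classes == {"g1": "ClassI"}

    def test_loss_site_excludes(self):
        g = gene_at(100_000, "g1")
        classes = classify_gene_classes(
            [g], [region(130_000, 131_000)], [], [region(110_000, 110_500)]
        )
        assert classes == {"g1": "neither"}

    def test_class_two_and_priority(self):
        g1, g2 = gene_at(100_000, "g1"), gene_at(500_000, "g2")
        cao = [region(130_000, 131_000)]
        cio = [region(120_000, 121_000), region(520_000, 521_000)]
        classes = classify_gene_classes([g1, g2], cao, cio, [])
        # g1 has both kinds nearby -> ClassI takes priority; g2 only inactive
        assert classes == {"g1": "ClassI", "g2": "ClassII"}

    def test_window_edge_is_inclusive_at_50kb(self):
        g = gene_at(100_000, "g1")
        # region whose closest edge sits exactly 50 kb from the TSS
        classes = classify_gene_classes([g], [region(150_000, 151_000)], [], [])
        assert classes["g1"] == "ClassI"
        classes = classify_gene_classes([g], [region(150_001, 151_000)], [], [])
        assert classes["g1"] == "neither"

    def test_classes_disjoint_on_simulated_truth(self):
        cfg = SimulationConfig(seed=21, n_input_fragments=0, n_output_fragments=0)
        truth = simulate_genome(cfg)
        cao = [e.region for e in truth.enhancers if not e.open_chromatin and e.tsa_opened]
        cio = [r.region for r in truth.closed_inactive_regions if r.tsa_opened]
        classes = classify_gene_classes(truth.genes, cao, cio, [])
        # exact agreement with a brute-force reclassification
        for g in truth.genes:
            near = lambda rs: any(
                max(r.start - g.tss, g.tss - (r.end - 1), 0) <= 50_000 for r in rs
            )
            expected = "ClassI" if near(cao) else ("ClassII" if near(cio) else "neither")
            assert classes[g.gene_id] == expected
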