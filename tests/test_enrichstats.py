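import itertools

import numpy as np
import pytest
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from chromfiber.enrichstats import (
    ScoredInterval,
    differential_matrix,
    fisher_enrichment,
    log_odds_density_enrichment,
    pca_density_correlation,
    read_blast_tabular,
    storey_qvalues,
    weighted_interval_schedule,
)


def hypergeom_two_sided_p(a, b, c, d):
    """Exact two-sided Fisher p by direct hypergeometric tail enumeration."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    probs = hypergeom.pmf(np.arange(lo, hi + 1), n, row1, col1)
    p_obs = hypergeom.pmf(a, n, row1, col1)
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())


def brute_force_wis(intervals):
    best = 0.0
    for r in range(len(intervals) + 1):
        for combo in itertools.combinations(intervals, r):
            if all(
                not x.overlaps(y) for x, y in itertools.combinations(combo, 2)
            ):
                best = max(best, sum(iv.score for iv in combo))
    return best


class TestFisher:
    def test_sample_odds_ratio(self):
        # one cluster, one domain: a=20, b=80, c=10, d=90
        cl = np.array(["x"] * 100 + ["y"] * 100)
        dm = np.array(["in"] * 20 + ["out"] * 80 + ["in"] * 10 + ["out"] * 90)
        res = fisher_enrichment(cl, dm)
        i, j = res.clusters.index("x"), res.domains.index("in")
        assert res.odds_ratio[i, j] == pytest.approx((20 * 90) / (80 * 10))

    def test_p_values_match_hypergeometric_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            n = int(rng.integers(20, 200))
            cl = rng.choice(["a", "b"], size=n)
            dm = rng.choice(["u", "v"], size=n)
            res = fisher_enrichment(cl, dm)
            for i, c in enumerate(res.clusters):
                for j, d in enumerate(res.domains):
                    a = int(np.sum((cl == c) & (dm == d)))
                    b = int(np.sum((cl == c) & (dm != d)))
                    cc = int(np.sum((cl != c) & (dm == d)))
                    dd = int(np.sum((cl != c) & (dm != d)))
                    if res.undefined[i, j]:
                        continue
                    assert res.p_value[i, j] == pytest.approx(
                        hypergeom_two_sided_p(a, b, cc, dd), abs=1e-10
                    )

    def test_null_false_positive_rate_near_alpha(self):
        rng = np.random.default_rng(3)
        rejections, total = 0, 0
        for _ in range(300):
            cl = rng.choice(["a", "b"], size=120)
            dm = rng.choice(["u", "v"], size=120)
            res = fisher_enrichment(cl, dm)
            rejections += int((res.p_value[~res.undefined] < 0.05).sum())
            total += int((~res.undefined).sum())
        # exact tests are conservative under the null; should not exceed alpha
        assert rejections / total < 0.07

    def test_empty_margin_flagged_not_dropped(self):
        cl = np.array(["a", "a", "a"])
        dm = np.array(["u", "u", "v"])
        res = fisher_enrichment(cl, dm)
        assert res.undefined.any()
        assert res.p_value.shape == (1, 2)


class TestStorey:
    def test_all_ones_stay_one(self):
        assert np.all(storey_qvalues(np.ones(50)) == 1.0)

    def test_pi0_one_equals_benjamini_hochberg(self):
        rng = np.random.default_rng(4)
        p = rng.random(200)
        q = storey_qvalues(p, pi0=1.0)
        bh = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(q, bh, atol=1e-12)

    def test_pi0_estimate_near_one_under_null(self):
        rng = np.random.default_rng(5)
        p = rng.random(10_000)
        # recover the estimate by comparing q to BH at the largest p
        q = storey_qvalues(p)
        bh = multipletests(p, method="fdr_bh")[1]
        ratio = q[np.argmax(p)] / bh[np.argmax(p)]
        assert 0.9 <= ratio <= 1.1

    def test_signal_shrinks_pi0_and_qvalues(self):
        rng = np.random.default_rng(6)
        p = np.concatenate([rng.random(5_000), rng.beta(0.1, 10, 5_000)])
        q = storey_qvalues(p)
        bh = multipletests(p, method="fdr_bh")[1]
        assert np.all(q <= bh + 1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            storey_qvalues([0.5, 1.5])

    def test_small_family_falls_back_to_bh(self):
        p = np.array([0.01, 0.2, 0.8])
        assert np.allclose(storey_qvalues(p), multipletests(p, method="fdr_bh")[1])


class TestDifferentialMatrix:
    def test_identical_matrices_zero(self):
        m = np.array([[1.0, 2.0], [0.5, 4.0]])
        assert np.all(differential_matrix(m, m) == 0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(7)
        a, b = rng.random((3, 4)) + 0.1, rng.random((3, 4)) + 0.1
        assert np.allclose(differential_matrix(a, b), -differential_matrix(b, a))

    def test_infinite_cells_masked_as_nan(self):
        a = np.array([[np.inf, 2.0]])
        b = np.array([[1.0, 1.0]])
        d = differential_matrix(a, b)
        assert np.isnan(d[0, 0]) and d[0, 1] == 1.0

    def test_planted_enrichment_localizes(self):
        rng = np.random.default_rng(8)
        n = 4000
        domains = rng.choice(["d0", "d1", "d2"], size=n)
        cl_a = rng.choice(["c0", "c1"], size=n)
        cl_b = cl_a.copy()
        # condition b: molecules in d2 preferentially switch to c1
        flip = (domains == "d2") & (rng.random(n) < 0.5)
        cl_b[flip] = "c1"
        ra = fisher_enrichment(cl_a, domains)
        rb = fisher_enrichment(cl_b, domains)
        d = differential_matrix(ra.odds_ratio, rb.odds_ratio)
        j = ra.domains.index("d2")
        off = np.abs(np.delete(d, j, axis=1))
        assert np.abs(d[:, j]).max() > off.max()


class TestPcaDensityCorrelation:
    def test_rank_one_matrix_gives_perfect_correlation(self):
        dens = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        loadings = np.array([0.5, -1.0, 2.0])
        diff = np.outer(loadings, dens)  # clusters x domains
        res = pca_density_correlation(diff, dens)
        assert abs(res["pearson_r"]) == pytest.approx(1.0, abs=1e-9)
        ev = res["explained_variance_ratio"]
        assert ev[0] == max(ev)

    def test_permuted_densities_decorrelate_on_average(self):
        rng = np.random.default_rng(9)
        dens = np.arange(1.0, 9.0)
        diff = np.outer(np.array([1.0, -2.0, 0.5]), dens) + rng.normal(0, 0.1, (3, 8))
        rs = []
        for _ in range(200):
            perm = rng.permutation(dens)
            rs.append(pca_density_correlation(diff, perm)["pearson_r"])
        assert abs(np.mean(rs)) < 0.15

    def test_too_few_domains_rejected(self):
        with pytest.raises(ValueError):
            pca_density_correlation(np.zeros((2, 2)), [1.0, 2.0])


class TestLogOddsDensity:
    BINS = np.linspace(0, 10, 11)

    def test_identical_distributions_zero(self):
        x = np.array([1.0, 2.5, 7.0, 7.2])
        assert np.allclose(log_odds_density_enrichment(x, x, self.BINS), 0.0)

    def test_shifted_cluster_sign_pattern(self):
        rng = np.random.default_rng(10)
        background = rng.uniform(0, 10, 2000)
        cluster = rng.uniform(4, 5, 500)  # all in one bin
        lo = log_odds_density_enrichment(cluster, background, self.BINS)
        assert lo[4] > 0
        assert np.all(np.delete(lo, 4) < lo[4])

    def test_smoothing_keeps_everything_finite(self):
        lo = log_odds_density_enrichment([0.5], [9.5], self.BINS)
        assert np.all(np.isfinite(lo))


class TestWeightedIntervalScheduling:
    def test_documented_example(self):
        chosen, total = weighted_interval_schedule(
            [(0, 10, 5.0), (5, 15, 7.0), (12, 20, 4.0)]
        )
        assert total == 9.0
        assert [(c.start, c.end) for c in chosen] == [(0, 10), (12, 20)]

    def test_empty_and_singleton(self):
        assert weighted_interval_schedule([]) == ([], 0.0)
        chosen, total = weighted_interval_schedule([(3, 9, 2.5)])
        assert total == 2.5 and len(chosen) == 1

    def test_matches_exhaustive_search_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = int(rng.integers(1, 16))
            ivs = []
            for _ in range(n):
                s = int(rng.integers(0, 100))
                ivs.append(
                    ScoredInterval(s, s + int(rng.integers(1, 30)), float(rng.integers(0, 50)))
                )
            chosen, total = weighted_interval_schedule(ivs)
            assert total == pytest.approx(brute_force_wis(ivs))
            assert all(
                not x.overlaps(y) for x, y in itertools.combinations(chosen, 2)
            )

    def test_negative_scores_rejected(self):
        with pytest.raises(ValueError):
            weighted_interval_schedule([(0, 5, -1.0)])


def test_blast_tabular_reader(tmp_path):
    path = tmp_path / "hits.tsv"
    path.write_text(
        "q1\tmajor_sat\t95.2\t120\t5\t1\t101\t220\t1\t120\t1e-30\t150.3\n"
        "q1\tminor_sat\t88.0\t60\t7\t0\t300\t241\t60\t1\t1e-10\t80.0\n"
    )
    ivs = read_blast_tabular(path)
    assert (ivs[0].start, ivs[0].end, ivs[0].label) == (100, 220, "major_sat")
    assert ivs[0].score == 150.3
    # reversed query coordinates are normalized to forward half-open
    assert (ivs[1].start, ivs[1].end) == (240, 300)
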