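import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import nbinom, poisson

from dielortho import de as de_mod
from dielortho.de import (
    NBDifferentialExpression,
    adjust_bh,
    adjust_bh_log,
    call_significant,
    estimate_dispersion,
    exact_test,
    exact_test_pvalue,
    method_consensus,
    normalize_median_ratio,
    normalize_tmm,
    select_stratum,
    wald_test,
)
from dielortho.simulate import SimConfig, simulate_counts

from conftest import make_counts, small_config


def brute_force_exact_p(y_a, y_b, n_a, n_b, phi):
    """Independent enumeration oracle: conditional split probabilities from
    scipy's NB/Poisson pmf directly."""
    total = y_a + y_b
    if total == 0:
        return 1.0
    mu = total / (n_a + n_b)
    probs = np.empty(total + 1)
    for t in range(total + 1):
        if phi > 0:
            ra, rb = n_a / phi, n_b / phi
            pa = nbinom.pmf(t, ra, ra / (ra + n_a * mu))
            pb = nbinom.pmf(total - t, rb, rb / (rb + n_b * mu))
        else:
            pa = poisson.pmf(t, n_a * mu)
            pb = poisson.pmf(total - t, n_b * mu)
        probs[t] = pa * pb
    probs = probs / probs.sum()
    obs = probs[y_a]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum()))


class TestNormalizeTmm:
    def test_identical_samples_give_unit_factors(self):
        m = make_counts(np.tile([[10], [50], [200]], (1, 4)))
        np.testing.assert_allclose(normalize_tmm(m).factors, 1.0)

    def test_doubled_sample_gives_sqrt2_factors(self):
        a = np.array([10, 50, 5, 100, 30])
        m = make_counts(np.column_stack([a, 2 * a]), n_day=1, n_night=1)
        # validate_design is not invoked here; two samples suffice for TMM
        np.testing.assert_allclose(
            sorted(normalize_tmm(m).factors), [1 / np.sqrt(2), np.sqrt(2)]
        )

    def test_single_sample_is_error(self):
        m = make_counts(np.array([[1], [2]]), n_day=1, n_night=0)
        with pytest.raises(ValueError, match="2 samples"):
            normalize_tmm(m)

    def test_factors_multiply_to_one(self):
        rng = np.random.default_rng(3)
        m = make_counts(rng.integers(0, 300, size=(100, 4)))
        assert np.prod(normalize_tmm(m).factors) == pytest.approx(1.0)


class TestNormalizeMedianRatio:
    def test_identical_samples(self):
        m = make_counts(np.tile([[10], [50]], (1, 4)))
        np.testing.assert_allclose(normalize_median_ratio(m).factors, 1.0)

    def test_tripled_sample_proportional(self):
        a = np.array([10, 50, 5, 100])
        m = make_counts(np.column_stack([a, 3 * a]), n_day=1, n_night=1)
        f = normalize_median_ratio(m).factors
        assert f[1] / f[0] == pytest.approx(3.0)

    def test_all_zero_genes_fall_back_with_warning(self):
        counts = np.array([[5, 0, 3, 1], [0, 4, 2, 7]])  # every gene has a zero
        m = make_counts(counts)
        with pytest.warns(UserWarning, match="falling back"):
            normalize_median_ratio(m)


class TestDispersion:
    def test_poisson_data_yields_near_zero(self):
        cfg = small_config(n_ref_genes=2000, dispersion=0.0, n_flipped=0, n_concordant=0,
                           n_single_species=0, key_gene=False, n_modules=0, module_kinds=())
        counts, _, _ = simulate_counts(cfg)
        m = counts["AN"]
        phi = estimate_dispersion(m, normalize_tmm(m))
        assert np.median(phi) <= 0.01

    def test_recovers_planted_dispersion(self):
        cfg = small_config(n_ref_genes=2000, dispersion=0.2, n_flipped=0, n_concordant=0,
                           n_single_species=0, key_gene=False, n_modules=0, module_kinds=())
        counts, _, _ = simulate_counts(cfg)
        m = counts["AN"]
        phi = estimate_dispersion(m, normalize_tmm(m))
        assert 0.1 <= np.median(phi) <= 0.3

    def test_constant_gene_gets_trend_value(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(100, size=(50, 6))
        counts[0] = 100  # zero variance
        m = make_counts(counts, n_day=3, n_night=3)
        fac = normalize_tmm(m)
        phi = estimate_dispersion(m, fac)
        assert phi[0] > 0  # shrunk to the (floored) trend, not zero


class TestExactTest:
    def test_poisson_limit_extreme_split(self):
        assert exact_test_pvalue(10, 0, 3, 3, 0.0) == pytest.approx(2 * 0.5**10)

    def test_identical_groups_are_null(self):
        counts = np.tile([[40], [80]], (1, 6))
        m = make_counts(counts, n_day=3, n_night=3)
        fac = normalize_tmm(m)
        res = exact_test(m, fac, np.array([0.1, 0.1]))
        assert (res["log2fc"] == 0).all()
        np.testing.assert_allclose(res["p"], 1.0, rtol=1e-9)

    @pytest.mark.parametrize("phi", [0.0, 0.1, 0.5])
    def test_matches_enumeration_oracle_small_totals(self, phi):
        rng = np.random.default_rng(11)
        for _ in range(25):
            total = int(rng.integers(1, 51))
            y_a = int(rng.integers(0, total + 1))
            n_a, n_b = int(rng.integers(1, 4)), int(rng.integers(1, 4))
            got = exact_test_pvalue(y_a, total - y_a, n_a, n_b, phi)
            want = brute_force_exact_p(y_a, total - y_a, n_a, n_b, phi)
            assert got == pytest.approx(want, rel=1e-9), (y_a, total, n_a, n_b, phi)

    def test_sign_convention_flips_with_phase_relabel(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson([[50], [400], [10]], size=(3, 6))
        m = make_counts(counts, n_day=3, n_night=3)
        fac = normalize_tmm(m)
        phi = np.full(3, 0.1)
        res = exact_test(m, fac, phi)
        # relabel: swap day and night phases
        from dielortho.io import CountMatrix, SampleDesign
        swapped = CountMatrix(
            gene_ids=m.gene_ids,
            samples=[
                SampleDesign(s.sample_id, s.species,
                             "night" if s.diel_phase == "day" else "day",
                             s.activity_niche, s.replicate)
                for s in m.samples
            ],
            counts=m.counts,
        )
        res2 = exact_test(swapped, fac, phi)
        np.testing.assert_allclose(res2["log2fc"], -res["log2fc"])
        np.testing.assert_allclose(res2["p"], res["p"])


class TestWaldTest:
    def test_equal_group_means_are_null(self):
        counts = np.tile([[60], [200]], (1, 6))
        m = make_counts(counts, n_day=3, n_night=3)
        fac = normalize_tmm(m)
        res = wald_test(m, fac, np.array([0.1, 0.1]))
        assert (res["p"] > 0.99).all()

    def test_recovers_planted_fold_change(self):
        rng = np.random.default_rng(9)
        n_genes, lfc, phi = 500, 4.0, 0.1
        mu = 100.0
        r = 1 / phi
        day = rng.negative_binomial(r, r / (r + mu), size=(n_genes, 3))
        night = rng.negative_binomial(r, r / (r + mu * 2**lfc), size=(n_genes, 3))
        m = make_counts(np.hstack([day, night]), n_day=3, n_night=3)
        fac = de_mod.NormFactors(np.ones(6), "tmm")
        res = wald_test(m, fac, np.full(n_genes, phi))
        err = res["log2fc"] - lfc
        # delta-method sd of the estimate is ~0.38 log2 units at these
        # settings, so the calibrated expectations are ~81% within +-0.5 and
        # ~99% within +-1.15 (3 sd); also check the estimator is unbiased
        assert abs(err.mean()) < 0.05
        assert (err.abs() <= 0.5).mean() >= 0.75
        assert (err.abs() <= 1.15).mean() >= 0.97

    def test_all_zero_gene_reported_null(self):
        counts = np.vstack([np.zeros(6, dtype=int), np.full(6, 50)])
        m = make_counts(counts, n_day=3, n_night=3)
        fac = de_mod.NormFactors(np.ones(6), "tmm")
        res = wald_test(m, fac, np.array([0.1, 0.1]))
        assert res.loc[0, "p"] == 1.0 and res.loc[0, "log2fc"] == 0.0

    def test_perfect_separation_is_finite(self):
        counts = np.array([[0, 0, 0, 90, 110, 100]])
        m = make_counts(counts, n_day=3, n_night=3)
        fac = de_mod.NormFactors(np.ones(6), "tmm")
        res = wald_test(m, fac, np.array([0.1]))
        assert np.isfinite(res.loc[0, "log2fc"])
        assert res.loc[0, "log2fc"] > 5  # strong night overexpression


class TestBenjaminiHochberg:
    def test_worked_example(self):
        np.testing.assert_allclose(
            adjust_bh([0.01, 0.02, 0.03, 0.5]), [0.04, 0.04, 0.04, 0.5]
        )

    def test_degenerate_cases(self):
        np.testing.assert_allclose(adjust_bh([1.0, 1.0, 1.0]), 1.0)
        np.testing.assert_allclose(adjust_bh([0.123]), [0.123])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=40))
    def test_properties_and_log_space_agreement(self, ps):
        adj = adjust_bh(ps)
        assert (adj >= np.asarray(ps) - 1e-12).all()
        assert (adj <= 1.0 + 1e-12).all()
        # monotone in p ranks
        order = np.argsort(ps)
        assert (np.diff(adj[order]) >= -1e-12).all()
        # log-space implementation agrees
        np.testing.assert_allclose(np.exp(adjust_bh_log(np.log(ps))), adj, rtol=1e-9)


class TestSignificanceAndConsensus:
    def test_threshold_boundaries(self):
        df = pd.DataFrame(
            {
                "gene_id": ["a", "b", "c"],
                "log2fc": [2.5, 1.9, -6.0],
                "adj_p": [0.03, 0.03, 0.2],
            }
        )
        out = call_significant(df)
        assert out["significant"].tolist() == [True, False, False]

    def test_stratum_selection(self):
        df = pd.DataFrame(
            {
                "gene_id": ["a", "b", "c"],
                "log2fc": [-6.0, -4.0, 7.0],
                "adj_p": [0.01, 0.01, 0.01],
                "significant": [True, True, True],
            }
        )
        assert select_stratum(df, "<=-5")["gene_id"].tolist() == ["a"]
        assert select_stratum(df, ">=5")["gene_id"].tolist() == ["c"]
        assert select_stratum(df, ">=2")["gene_id"].tolist() == ["c"]

    def test_consensus_is_intersection(self):
        a = pd.DataFrame({"gene_id": ["x", "y", "z"], "significant": [True, True, False]})
        b = pd.DataFrame({"gene_id": ["x", "y", "z"], "significant": [False, True, True]})
        shared, sizes = method_consensus(a, b)
        assert shared == {"y"}
        assert sizes == {"n_a": 2, "n_b": 2, "n_shared": 1}

    def test_estimator_api(self):
        rng = np.random.default_rng(0)
        X = rng.poisson(50, size=(6, 20))
        y = ["day"] * 3 + ["night"] * 3
        est = NBDifferentialExpression(method="wald").fit(X, y)
        assert est.results_.shape[0] == 20
        assert est.predict().dtype == bool
        params = est.get_params()
        assert params["method"] == "wald"
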