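import numpy as np
import pandas as pd
import pytest

from dielortho.coexpression import (
    CoexpressionNetwork,
    adjacency,
    adjacency_tom,
    detect_modules,
    module_eigengenes,
    module_trait,
    pick_soft_power,
    preprocess_expression,
    prune_by_membership,
    tom_similarity,
)
from dielortho.de import NormFactors
from dielortho.simulate import simulate_counts

from conftest import make_counts, make_design, small_config


def planted_expression(n_noise=150, module_size=50, noise_sd=0.4, n_samples=20, seed=0):
    """Two latent-factor modules plus independent noise genes; samples x genes."""
    rng = np.random.default_rng(seed)
    f1 = rng.normal(size=n_samples)
    f2 = rng.normal(size=n_samples)
    cols, names, truth = [], [], []
    for i in range(module_size):
        cols.append(f1 + rng.normal(0, noise_sd, n_samples))
        names.append(f"m1_{i}")
        truth.append("M1")
    for i in range(module_size):
        cols.append(f2 + rng.normal(0, noise_sd, n_samples))
        names.append(f"m2_{i}")
        truth.append("M2")
    for i in range(n_noise):
        cols.append(rng.normal(size=n_samples))
        names.append(f"n_{i}")
        truth.append("none")
    expr = pd.DataFrame(np.column_stack(cols), columns=names)
    return expr, pd.Series(truth, index=names)


class TestAdjacencyTom:
    def test_perfect_correlation_gives_unit_adjacency(self):
        x = np.linspace(0, 1, 10)
        expr = np.column_stack([x, 2 * x + 1, -x])
        a = adjacency(expr, power=6, network_type="unsigned")
        assert a[0, 1] == pytest.approx(1.0)
        assert a[0, 2] == pytest.approx(1.0)  # unsigned folds the sign
        a_signed = adjacency(expr, power=6, network_type="signed")
        assert a_signed[0, 2] == pytest.approx(0.0)

    def test_three_gene_toy_tom(self):
        a = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        tom = tom_similarity(a)
        assert tom[0, 1] == pytest.approx(1.0)
        assert tom[0, 0] == 1.0

    def test_tom_bounds_symmetry_unit_diagonal(self):
        rng = np.random.default_rng(12)
        expr = rng.normal(size=(15, 40))
        tom = adjacency_tom(expr, power=6)
        assert tom.shape == (40, 40)
        assert ((tom >= 0) & (tom <= 1)).all()
        np.testing.assert_allclose(tom, tom.T)
        np.testing.assert_allclose(np.diag(tom), 1.0)


class TestSoftPower:
    def test_single_candidate_returned(self):
        expr, _ = planted_expression(n_noise=50, module_size=20, n_samples=12)
        beta, table = pick_soft_power(
            ((expr - expr.mean()) / expr.std()).to_numpy(), candidate_powers=[9]
        )
        assert beta == 9
        assert len(table) == 1

    def test_choice_is_smallest_power_reaching_target(self):
        expr, _ = planted_expression(seed=3)
        z = ((expr - expr.mean()) / expr.std()).to_numpy()
        import warnings as w

        with w.catch_warnings():
            w.simplefilter("ignore")
            beta, table = pick_soft_power(z)
        ok = table[(table["r2"] >= 0.8) & (table["slope"] < 0)]
        if len(ok):
            assert beta == int(ok.iloc[0]["power"])
        else:
            assert beta in set(table["power"])

    def test_pure_noise_falls_back_with_warning(self):
        rng = np.random.default_rng(1)
        z = rng.normal(size=(8, 30))
        with pytest.warns(UserWarning, match="argmax"):
            pick_soft_power(z, candidate_powers=[1, 2])


class TestModuleDetection:
    def test_two_planted_modules_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        expr, truth = planted_expression(seed=5)
        net = CoexpressionNetwork(power=6).fit(expr)
        nongrey = net.labels_.index[net.labels_ != "grey"]
        assert len(set(net.labels_) - {"grey"}) == 2
        sizes = net.labels_.value_counts()
        for mod in set(net.labels_) - {"grey"}:
            assert 45 <= sizes[mod] <= 55
        ari = adjusted_rand_score(truth[nongrey], net.labels_[nongrey])
        assert ari >= 0.9

    def test_pure_noise_is_all_grey(self):
        rng = np.random.default_rng(7)
        expr = pd.DataFrame(rng.normal(size=(12, 100)))
        expr.columns = [f"g{i}" for i in range(100)]
        net = CoexpressionNetwork(power=9).fit(expr)
        assert set(net.labels_) == {"grey"}

    def test_min_module_size_above_n_genes_is_all_grey(self):
        expr, _ = planted_expression(n_noise=0, module_size=10, n_samples=10)
        tom = adjacency_tom(((expr - expr.mean()) / expr.std()).to_numpy(), 6)
        labels = detect_modules(tom, list(expr.columns), min_module_size=1000)
        assert set(labels) == {"grey"}

    def test_labels_invariant_under_gene_permutation(self):
        expr, _ = planted_expression(n_noise=30, module_size=15, seed=9)
        rng = np.random.default_rng(0)
        perm = rng.permutation(expr.columns)
        net1 = CoexpressionNetwork(power=6).fit(expr)
        net2 = CoexpressionNetwork(power=6).fit(expr[perm])
        assert (net1.labels_.sort_index() == net2.labels_.sort_index()).all()


class TestEigengenes:
    def test_identical_genes_reproduce_shared_profile(self):
        rng = np.random.default_rng(2)
        profile = rng.normal(size=12)
        expr = pd.DataFrame({f"g{i}": profile for i in range(5)})
        labels = pd.Series("turquoise", index=expr.columns)
        eig = module_eigengenes(expr, labels)
        z = (profile - profile.mean()) / profile.std(ddof=1)
        np.testing.assert_allclose(eig.loc["turquoise"], z, atol=1e-8)

    def test_matches_svd_oracle_on_small_modules(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(rng.normal(size=(14, 8)), columns=[f"g{i}" for i in range(8)])
        labels = pd.Series("blue", index=expr.columns)
        eig = module_eigengenes(expr, labels).loc["blue"].to_numpy()
        z = (expr - expr.mean()) / expr.std(ddof=0)
        u, s, vt = np.linalg.svd(z.to_numpy(), full_matrices=False)
        oracle = u[:, 0] / u[:, 0].std(ddof=1)
        agree = min(np.abs(eig - oracle).max(), np.abs(eig + oracle).max())
        assert agree < 1e-8

    def test_orientation_positive_mean_correlation(self):
        rng = np.random.default_rng(4)
        for seed in range(5):
            expr, truth = planted_expression(n_noise=0, module_size=10, seed=seed)
            labels = pd.Series("red", index=expr.columns[truth == "M1"])
            eig = module_eigengenes(expr[labels.index], labels)
            cors = [
                np.corrcoef(eig.loc["red"], expr[g])[0, 1] for g in labels.index
            ]
            assert np.mean(cors) > 0


class TestModuleTrait:
    def design(self):
        return make_design(n_day=3, n_night=3, species="AN") + make_design(
            n_day=3, n_night=3, species="DR", niche="nocturnal"
        )

    def test_phase_indicator_eigengene(self):
        design = self.design()
        phase = np.array([1.0 if s.diel_phase == "night" else 0.0 for s in design])
        eig = pd.DataFrame([phase], index=["turquoise"],
                           columns=[s.sample_id for s in design])
        tt = module_trait(eig, design)
        row = tt[(tt.module == "turquoise") & (tt.trait == "diel_phase")].iloc[0]
        assert row["cor"] == pytest.approx(1.0)
        assert row["p"] < 1e-10

    def test_orthogonal_eigengene_uncorrelated(self):
        design = self.design()
        vec = np.array([1.0, -1.0] * 6)  # alternates within phases
        eig = pd.DataFrame([vec], index=["blue"], columns=[s.sample_id for s in design])
        tt = module_trait(eig, design)
        row = tt[(tt.module == "blue") & (tt.trait == "diel_phase")].iloc[0]
        assert abs(row["cor"]) < 0.35
        assert row["p"] > 0.2


class TestPreprocess:
    def test_zscore_and_constant_gene_dropped(self):
        cfg = small_config()
        counts, _, _ = simulate_counts(cfg)
        m = counts["AN"]
        m.counts[0, :] = 7  # constant gene
        factors = {"AN": NormFactors(np.ones(len(m.samples)), "tmm")}
        expr, dropped = preprocess_expression({"AN": m}, factors, combined=False)
        assert m.gene_ids[0] in dropped
        np.testing.assert_allclose(expr.mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(expr.std(axis=0, ddof=0), 1, atol=1e-9)

    def test_combined_restricts_to_shared_genes(self, small_bundle):
        counts = small_bundle.counts
        factors = {
            sp: NormFactors(np.ones(len(m.samples)), "tmm") for sp, m in counts.items()
        }
        gene_map = {sp: dict(m) for sp, m in small_bundle.orthology.transcript_map.items()}
        expr, _ = preprocess_expression(counts, factors, combined=True, gene_map=gene_map)
        shared = set(gene_map["AN"].values()) & set(gene_map["DR"].values())
        assert set(expr.columns) <= shared
        assert len(expr) == sum(len(m.samples) for m in counts.values())
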