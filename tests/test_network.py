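import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from mirisonet.core_io import ExpressionMatrix
from mirisonet.network import (
    GREY,
    ModuleAssignment,
    adjacency,
    build_network,
    detect_modules,
    module_eigengene,
    module_trait_and_kme,
    tom_similarity,
)


def _block_expression(rng, sizes, n_tissues=6, reps=2, noise=0.05):
    """Block-structured matrix: block b is high in tissue b, low elsewhere."""
    design = {}
    cols = []
    for t in range(n_tissues):
        for r in range(reps):
            s = f"t{t}_r{r}"
            design[s] = f"t{t}"
            cols.append(s)
    rows, names = [], []
    for b, size in enumerate(sizes):
        profile = np.full(n_tissues, 1.0)
        profile[b % n_tissues] = 20.0
        for i in range(size):
            vals = [
                profile[t] * (1 + noise * rng.standard_normal())
                for t in range(n_tissues)
                for _ in range(reps)
            ]
            rows.append(vals)
            names.append(f"b{b}_f{i}")
    values = pd.DataFrame(rows, index=names, columns=cols)
    return ExpressionMatrix(values, "FPKM", design)


class TestAdjacency:
    def test_perfect_correlation_is_one(self):
        x = np.vstack([np.arange(6.0), 2 * np.arange(6.0) + 3])
        a = adjacency(x, beta=6)
        assert a[0, 1] == pytest.approx(1.0)

    def test_unsigned_half_correlation_beta6(self):
        # construct two features with cor exactly -0.5
        x = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        # cor = -0.5 for these indicator-like profiles
        assert np.corrcoef(x)[0, 1] == pytest.approx(-0.5)
        a = adjacency(x, beta=6)
        assert a[0, 1] == pytest.approx(0.5**6)

    def test_symmetric_unit_range(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((15, 8))
        a = adjacency(x, beta=6)
        assert np.allclose(a, a.T)
        assert (a >= 0).all() and (a <= 1).all()
        assert np.allclose(np.diag(a), 1.0)

    def test_zero_variance_feature_rejected(self):
        x = np.vstack([np.ones(5), np.arange(5.0)])
        with pytest.raises(ValueError, match="zero-variance"):
            adjacency(x, beta=6)


class TestTom:
    def test_complete_triangle_is_all_ones(self):
        a = np.ones((3, 3))
        assert np.allclose(tom_similarity(a), 1.0)

    def test_isolated_pair_is_zero(self):
        a = np.eye(4)
        a[0, 1] = a[1, 0] = 0.0
        tom = tom_similarity(a)
        assert tom[0, 1] == 0.0

    def test_three_node_chain_hand_value(self):
        # a12=a23=0.5, a13=0: L12=0, k1=0.5, k2=1.0 ->
        # TOM12 = (0+0.5)/(min(0.5,1)+1-0.5) = 0.5
        a = np.eye(3)
        a[0, 1] = a[1, 0] = 0.5
        a[1, 2] = a[2, 1] = 0.5
        tom = tom_similarity(a)
        assert tom[0, 1] == pytest.approx(0.5)

    def test_exhaustive_three_node_grid_matches_formula(self):
        """TOM equals the hand formula on every 3-node adjacency with
        entries in {0, 0.25, 0.5, 0.75, 1}."""
        grid = [0.0, 0.25, 0.5, 0.75, 1.0]
        for a12, a13, a23 in itertools.product(grid, repeat=3):
            A = np.array([[1, a12, a13], [a12, 1, a23], [a13, a23, 1.0]])
            tom = tom_similarity(A)
            for i, j in [(0, 1), (0, 2), (1, 2)]:
                u = 3 - i - j
                L = A[i, u] * A[u, j]
                k_i = sum(A[i, v] for v in range(3) if v != i)
                k_j = sum(A[j, v] for v in range(3) if v != j)
                denom = min(k_i, k_j) + 1 - A[i, j]
                expected = (L + A[i, j]) / denom if denom > 0 else 0.0
                expected = min(max(expected, 0.0), 1.0)
                assert tom[i, j] == pytest.approx(expected, abs=1e-12)

    def test_asymmetric_input_rejected(self):
        a = np.eye(3)
        a[0, 1] = 0.4
        with pytest.raises(ValueError, match="symmetric"):
            tom_similarity(a)


class TestEigengene:
    def test_shared_profile_recovered(self):
        profile = np.array([5.0, 1.0, 1.0, 9.0])
        X = np.vstack([profile * s for s in (1.0, 2.0, 0.5)])
        eig = module_eigengene(X)
        z = (profile - profile.mean()) / profile.std()
        r = np.corrcoef(eig, z)[0, 1]
        assert abs(r) == pytest.approx(1.0)
        # members correlate positively by the orientation contract
        assert np.corrcoef(X[0], eig)[0, 1] > 0.99

    def test_sign_orientation_under_negation(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((6, 8)) + 3 * np.sin(np.arange(8))
        for mat in (X, -X):
            eig = module_eigengene(mat)
            cors = [np.corrcoef(row, eig)[0, 1] for row in mat]
            assert np.mean(cors) > 0

    def test_pc1_variance_dominates_members(self):
        """PC1 explains at least the share of any single standardized
        member, checked against a full PCA decomposition."""
        rng = np.random.default_rng(1)
        X = np.outer(np.ones(10), rng.standard_normal(7)) + 0.3 * rng.standard_normal(
            (10, 7)
        )
        Z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
        svals = np.linalg.svd(Z, compute_uv=False)
        var_pc1 = svals[0] ** 2 / (svals**2).sum()
        assert var_pc1 >= 1.0 / len(Z) - 1e-12
        eig = module_eigengene(X)
        proj = Z @ eig / np.linalg.norm(eig)
        assert (proj**2).sum() / (Z**2).sum() == pytest.approx(var_pc1, rel=1e-6)


class TestDetectModules:
    def test_two_planted_blocks_recovered_exactly(self):
        rng = np.random.default_rng(2)
        expr = _block_expression(rng, [30, 30])
        asn = build_network(expr, min_module_size=10)
        truth = [n.split("_")[0] for n in expr.feature_ids]
        assert len(asn.modules) == 2
        assert adjusted_rand_score(truth, asn.labels.values) == 1.0

    def test_small_cluster_goes_grey(self):
        rng = np.random.default_rng(3)
        expr = _block_expression(rng, [30, 5])
        asn = build_network(expr, min_module_size=10)
        small = [n for n in expr.feature_ids if n.startswith("b1_")]
        assert (asn.labels.loc[small] == GREY).all()

    def test_identical_profiles_merge_into_one_module(self):
        rng = np.random.default_rng(4)
        # two blocks with the SAME tissue profile -> eigengene dissimilarity ~0
        expr = _block_expression(rng, [20, 20], noise=0.02)
        vals = expr.values.copy()
        b1 = [n for n in expr.feature_ids if n.startswith("b1_")]
        b0 = [n for n in expr.feature_ids if n.startswith("b0_")]
        vals.loc[b1] = vals.loc[b0].to_numpy() * 1.5 + 0.2 * rng.standard_normal(
            vals.loc[b1].shape
        )
        expr2 = ExpressionMatrix(vals, "FPKM", dict(expr.design))
        asn = build_network(expr2, min_module_size=10, merge_threshold=0.5)
        assert len(asn.modules) == 1

    def test_oversized_min_module_size_warns_all_grey(self):
        rng = np.random.default_rng(5)
        expr = _block_expression(rng, [10])
        tom = np.eye(10)
        with pytest.warns(UserWarning):
            asn = detect_modules(tom, expr.values, min_module_size=100)
        assert (asn.labels == GREY).all()

    def test_labels_invariant_to_feature_order(self):
        rng = np.random.default_rng(6)
        expr = _block_expression(rng, [25, 25])
        perm = rng.permutation(len(expr.feature_ids))
        shuffled = ExpressionMatrix(
            expr.values.iloc[perm], "FPKM", dict(expr.design)
        )
        a1 = build_network(expr, min_module_size=10).labels
        a2 = build_network(shuffled, min_module_size=10).labels
        common = list(a1.index)
        assert adjusted_rand_score(a1.loc[common].values, a2.loc[common].values) == 1.0


class TestModuleTraitAndKme:
    def test_eigengene_matching_indicator_has_unit_correlation(self):
        rng = np.random.default_rng(7)
        expr = _block_expression(rng, [30], noise=0.001)
        asn = build_network(expr, min_module_size=10)
        (mod,) = asn.modules
        r = asn.module_trait_r.loc[mod]
        assert r["t0"] == pytest.approx(1.0, abs=0.01)

    def test_hub_count_is_min_of_quota_and_size(self):
        rng = np.random.default_rng(8)
        expr = _block_expression(rng, [200, 120])
        asn = build_network(expr, min_module_size=10, hub_count=150)
        sizes = sorted(len(asn.members(m)) for m in asn.modules)
        assert sizes == [120, 200]
        hub_sizes = sorted(len(asn.hubs[m]) for m in asn.modules)
        assert hub_sizes == [120, 150]
        for m in asn.modules:
            assert set(asn.hubs[m]) <= set(asn.members(m))

    def test_trait_pvalue_matches_permutation_oracle(self):
        rng = np.random.default_rng(9)
        n = 15
        design = {f"s{i}": ("leaf" if i < 5 else f"t{i}") for i in range(n)}
        vals = pd.DataFrame(
            rng.standard_normal((12, n)) + 2.0,
            index=[f"f{i}" for i in range(12)],
            columns=list(design),
        )
        vals.iloc[:, :5] += 3.0  # leaf-correlated block
        expr = ExpressionMatrix(vals.clip(lower=0.0), "FPKM", design)
        asn = build_network(expr, min_module_size=5)
        (mod,) = asn.modules
        eig = asn.eigengenes.loc[mod].to_numpy()
        indicator = np.array([1.0 if design[s] == "leaf" else 0.0 for s in design])
        r_obs = abs(np.corrcoef(eig, indicator)[0, 1])
        perm_r = []
        prng = np.random.default_rng(10)
        for _ in range(4000):
            perm_r.append(abs(np.corrcoef(eig, prng.permutation(indicator))[0, 1]))
        p_perm = np.mean(np.array(perm_r) >= r_obs - 1e-12)
        p_t = asn.module_trait_p.loc[mod, "leaf"]
        assert p_t == pytest.approx(p_perm, abs=0.02)
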