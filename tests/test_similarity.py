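"""Factor-matching indexes against brute-force oracles and hand evaluations."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import syndromics as sy


# --- independent brute-force oracles (plain Python, no shared code paths) ---

def oracle_cc(x, y):
    num = math.fsum(a * b for a, b in zip(x, y))
    return num / math.sqrt(math.fsum(a * a for a in x) * math.fsum(b * b for b in y))


def oracle_rmse(x, y):
    return math.sqrt(math.fsum((a - b) ** 2 for a, b in zip(x, y)) / len(x))


def oracle_s(x, y, cutoff):
    def status(a):
        if a > cutoff:
            return "PS"
        if a < -cutoff:
            return "NS"
        return "H"

    f = {}
    for a, b in zip(x, y):
        f[(status(a), status(b))] = f.get((status(a), status(b)), 0) + 1
    g = f.get
    num = g(("PS", "PS"), 0) + g(("NS", "NS"), 0) - g(("PS", "NS"), 0) - g(("NS", "PS"), 0)
    den = (
        g(("PS", "PS"), 0)
        + g(("NS", "NS"), 0)
        + g(("PS", "NS"), 0)
        + g(("NS", "PS"), 0)
        + (g(("PS", "H"), 0) + g(("H", "PS"), 0) + g(("NS", "H"), 0) + g(("H", "NS"), 0)) / 2
    )
    return None if den == 0 else num / den


class TestCongruence:
    def test_self_and_reflection(self):
        x = np.array([0.5, -0.3, 0.8])
        assert sy.congruence_coefficient(x, x) == pytest.approx(1.0)
        assert sy.congruence_coefficient(x, -x) == pytest.approx(-1.0)

    def test_example_table_pc1_vs_pc2_near_zero(self, example_loadings):
        x, y = example_loadings.column("PC1"), example_loadings.column("PC2")
        assert sy.congruence_coefficient(x, y) == pytest.approx(oracle_cc(x, y), abs=1e-12)
        assert abs(sy.congruence_coefficient(x, y)) < 0.01  # near-orthogonal components

    def test_zero_norm_raises(self):
        with pytest.raises(ValueError):
            sy.congruence_coefficient(np.zeros(3), np.ones(3))

    @given(
        a=st.floats(-5, 5).filter(lambda t: abs(t) > 1e-3),
        b=st.floats(-5, 5).filter(lambda t: abs(t) > 1e-3),
        seed=st.integers(0, 100),
    )
    def test_scale_invariance(self, a, b, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=6), rng.normal(size=6)
        lhs = sy.congruence_coefficient(a * x, b * y)
        rhs = np.sign(a * b) * sy.congruence_coefficient(x, y)
        assert lhs == pytest.approx(rhs, abs=1e-9)


class TestPearson:
    def test_affine_invariance(self):
        y = np.array([0.1, -0.4, 0.7, 0.2])
        assert sy.pearson_similarity(2 * y + 0.1, y) == pytest.approx(1.0)

    def test_equals_cc_for_centered_vectors(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=10), rng.normal(size=10)
        x, y = x - x.mean(), y - y.mean()
        assert sy.pearson_similarity(x, y) == pytest.approx(
            sy.congruence_coefficient(x, y), abs=1e-12
        )

    def test_constant_vector_raises(self):
        with pytest.raises(ValueError):
            sy.pearson_similarity(np.ones(4), np.arange(4.0))


class TestRmse:
    def test_zero_iff_identical_and_constant_shift(self):
        x = np.array([0.2, -0.5, 0.9])
        assert sy.rmse_similarity(x, x) == 0.0
        assert sy.rmse_similarity(x + 0.3, x) == pytest.approx(0.3)

    @given(seed=st.integers(0, 500))
    def test_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)
        x, y, z = rng.normal(size=(3, 8))
        assert sy.rmse_similarity(x, z) <= (
            sy.rmse_similarity(x, y) + sy.rmse_similarity(y, z) + 1e-12
        )


class TestCrossClassifyAndS:
    def test_example_table_cross_classification(self, example_loadings):
        t = sy.cross_classify(
            example_loadings.column("PC1"), example_loadings.column("PC2"), 0.1
        )
        assert t.f(1, 1) == 3 and t.f(3, 3) == 5
        assert t.f(1, 3) == 4 and t.f(3, 1) == 5
        assert t.f(1, 2) == 1
        assert t.n_variables == 18
        # every other cell empty
        assert t.counts.sum() == 3 + 5 + 4 + 5 + 1

    def test_boundary_value_is_hyperplane(self):
        t = sy.cross_classify(np.array([0.1, -0.1]), np.array([0.2, 0.2]), 0.1)
        assert t.f(2, 1) == 2  # both exactly at the cutoff stay in H

    def test_s_perfect_match_and_dissimilarity(self):
        x = np.array([0.5, -0.4, 0.05])
        assert sy.s_index(x, x, 0.1) == pytest.approx(1.0)
        assert sy.s_index(x, -x, 0.1) == pytest.approx(-1.0)

    def test_example_table_s_value(self, example_loadings):
        s = sy.s_index(
            example_loadings.column("PC1"), example_loadings.column("PC2"), 0.1
        )
        assert s == pytest.approx(-1 / 17.5, abs=1e-12)  # = -0.0571..., prints -0.057
        assert round(s, 3) == -0.057

    def test_all_hyperplane_is_undefined(self):
        with pytest.raises(ValueError):
            sy.s_index(np.array([0.01, -0.02]), np.array([0.0, 0.03]), 0.1)

    def test_brute_force_equivalence_on_random_pairs(self):
        rng = np.random.default_rng(1)
        checked = 0
        for _ in range(1000):
            x, y = rng.uniform(-1, 1, size=(2, 12))
            cutoff = rng.uniform(0.05, 0.6)
            expected = oracle_s(x, y, cutoff)
            if expected is None:
                continue
            assert sy.s_index(x, y, cutoff) == pytest.approx(expected, abs=1e-12)
            assert sy.congruence_coefficient(x, y) == pytest.approx(
                oracle_cc(x, y), abs=1e-12
            )
            assert sy.rmse_similarity(x, y) == pytest.approx(
                oracle_rmse(x, y), abs=1e-12
            )
            checked += 1
        assert checked > 900  # the degenerate all-hyperplane case is rare


class TestComponentSimilarity:
    def test_identical_matrices_are_perfectly_similar(self, example_loadings):
        res = sy.component_similarity([example_loadings] * 3, s_cut_off=0.1)
        assert len(res.pair_results) == 3 * example_loadings.k  # 3 pairs x 3 PCs
        for pc_row in res.summary.itertuples():
            assert pc_row.cc_index_mean == pytest.approx(1.0)
            assert pc_row.rmse_mean == pytest.approx(0.0)
            assert pc_row.s_index_mean == pytest.approx(1.0)
            assert pc_row.cc_index_sd == pytest.approx(0.0)

    @pytest.mark.parametrize("m", range(2, 7))
    def test_pair_count(self, example_loadings, m):
        res = sy.component_similarity([example_loadings] * m, metrics="cc_index", ndim=1)
        assert len(res.pair_results) == m * (m - 1) // 2

    def test_metric_subset_and_unknown_metric(self, example_loadings):
        res = sy.component_similarity([example_loadings] * 2, metrics=("rmse",))
        assert res.pair_results[0].cc is None
        assert res.pair_results[0].rmse == pytest.approx(0.0)
        with pytest.raises(ValueError):
            sy.component_similarity([example_loadings] * 2, metrics=("bogus",))

    def test_refit_collection_of_planted_structure_is_stable(self, planted_one_factor):
        tables = []
        for seed in range(25):
            sol = sy.fit_linear_pca(planted_one_factor(n=150, seed=seed))
            tables.append(sol.loadings.retain(1))
        res = sy.component_similarity(tables, metrics="cc_index", ndim=1)
        assert float(res.summary["cc_index_mean"].iloc[0]) > 0.95


class TestImputationStability:
    def test_identical_matrices_converge_immediately(self, example_loadings):
        res = sy.imputation_stability([example_loadings] * 4)
        assert res.converged
        assert np.allclose(res.summary["cc_index_mean"], 1.0)
        assert np.allclose(res.summary["rmse_mean"], 0.0, atol=1e-12)

    def test_orthogonal_transforms_of_one_parent_align_exactly(self, example_loadings):
        rng = np.random.default_rng(2)
        tables = []
        for _ in range(5):
            Q, R = np.linalg.qr(rng.standard_normal((3, 3)))
            Q = Q * np.sign(np.diag(R))
            tables.append(
                sy.LoadingsTable(
                    example_loadings.variables,
                    example_loadings.components,
                    example_loadings.values @ Q,
                )
            )
        res = sy.imputation_stability(tables, metrics="cc_index")
        assert np.all(np.abs(res.summary["cc_index_mean"] - 1.0) < 1e-6)

    def test_surrogate_imputations_with_strong_structure_stay_congruent(self):
        model = sy.PlantedModel(
            n=150, L=sy.planted_loadings(6, 1, 0.8), noise_sd=0.6, seed=3
        )
        datasets = sy.generate_imputation_surrogates(model, m=10, corruption_fraction=0.1)
        tables = [sy.fit_linear_pca(d).loadings.retain(1) for d in datasets]
        res = sy.imputation_stability(tables, metrics="cc_index", ndim=1)
        assert float(res.summary["cc_index_mean"].iloc[0]) >= 0.9

    def test_single_pass_variant_runs(self, example_loadings):
        res = sy.imputation_stability([example_loadings] * 3, iterative=False)
        assert np.allclose(res.summary["cc_index_mean"], 1.0)
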