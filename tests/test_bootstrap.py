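"""Bootstrap schemes, BCa intervals, and the component-stability workflow."""

import numpy as np
import pytest

import syndromics as sy
from syndromics.bootstrap import BootstrapConfig, bca_ci
from syndromics.pca import _fit_arrays


class TestBootstrapIndices:
    @pytest.mark.parametrize("n, B", [(4, 3), (10, 25), (7, 100)])
    def test_balanced_counts_exactly_B_per_subject(self, n, B):
        idx = sy.bootstrap_indices(n, B, "balanced", np.random.default_rng(0))
        assert idx.shape == (B, n)
        assert np.array_equal(np.bincount(idx.reshape(-1), minlength=n), np.full(n, B))

    def test_ordinary_unique_fraction_near_one_minus_inv_e(self):
        idx = sy.bootstrap_indices(100, 1000, "ordinary", np.random.default_rng(1))
        uniq = np.mean([np.unique(row).size for row in idx]) / 100
        assert abs(uniq - (1 - 1 / np.e)) < 0.02

    def test_fixed_seed_reproducible(self):
        a = sy.bootstrap_indices(20, 10, "balanced", np.random.default_rng(7))
        b = sy.bootstrap_indices(20, 10, "balanced", np.random.default_rng(7))
        assert np.array_equal(a, b)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            sy.bootstrap_indices(1, 5)
        with pytest.raises(ValueError):
            sy.bootstrap_indices(5, 5, scheme="bogus")


class TestBootPcaSample:
    def test_identity_indices_reproduce_parent(self, planted_one_factor):
        data = planted_one_factor(n=50, seed=0)
        sol = sy.fit_linear_pca(data)
        out = sy.boot_pca_sample(data, np.arange(50), sol, ndim=2)
        assert np.abs(out.values - sol.loadings.values[:, :2]).max() < 1e-8

    def test_duplicated_rows_reproduce_parent(self, planted_one_factor):
        # doubling every subject leaves the correlation structure unchanged
        data = planted_one_factor(n=50, seed=1)
        sol = sy.fit_linear_pca(data)
        idx = np.repeat(np.arange(50), 2)
        out = sy.boot_pca_sample(data, idx, sol, ndim=2)
        assert np.abs(out.values - sol.loadings.values[:, :2]).max() < 1e-8

    def test_resampled_mean_close_to_parent(self, planted_one_factor):
        data = planted_one_factor(n=120, seed=2)
        sol = sy.fit_linear_pca(data)
        rng = np.random.default_rng(3)
        acc = np.zeros((6, 1))
        B = 200
        for _ in range(B):
            acc += sy.boot_pca_sample(data, rng.integers(0, 120, 120), sol, 1).values
        assert np.abs(acc / B - sol.loadings.values[:, :1]).max() < 0.1


class TestBcaCi:
    def test_symmetric_samples_close_to_percentile(self):
        rng = np.random.default_rng(0)
        samples = rng.standard_normal(5000)
        res = bca_ci(samples, float(np.median(samples)), None, 0.95)
        lo, hi = np.quantile(samples, [0.025, 0.975])
        assert res.method == "bca"
        assert res.low == pytest.approx(lo, abs=0.1)
        assert res.high == pytest.approx(hi, abs=0.1)

    def test_constant_samples_fall_back_to_percentile(self):
        res = bca_ci(np.full(50, 3.0), 3.0, None, 0.95)
        assert res == (3.0, 3.0, "percentile")

    def test_normal_quantile_oracle(self):
        rng = np.random.default_rng(1)
        samples = rng.standard_normal(10_000)
        res = bca_ci(samples, 0.0, None, 0.95)  # jackknife None -> acceleration 0
        assert res.low == pytest.approx(-1.96, abs=0.05)
        assert res.high == pytest.approx(1.96, abs=0.05)

    def test_all_samples_on_one_side_fall_back(self):
        samples = np.linspace(1.0, 2.0, 100)
        res = bca_ci(samples, 0.5, None, 0.9)
        assert res.method == "percentile"

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            bca_ci(np.array([]), 0.0, None)

    def test_matches_scipy_bca_on_the_mean(self):
        # same data, same statistic: both BCa constructions should agree
        from scipy.stats import bootstrap as scipy_bootstrap

        rng = np.random.default_rng(2)
        x = rng.exponential(size=60)  # skewed so the correction matters
        B = 4000
        boot_means = np.array(
            [x[rng.integers(0, 60, 60)].mean() for _ in range(B)]
        )
        jack = np.array([np.delete(x, i).mean() for i in range(60)])
        ours = bca_ci(boot_means, float(x.mean()), jack, 0.95)
        ref = scipy_bootstrap(
            (x,),
            np.mean,
            n_resamples=B,
            confidence_level=0.95,
            method="BCa",
            random_state=np.random.default_rng(3),
        ).confidence_interval
        assert ours.low == pytest.approx(ref.low, abs=0.05)
        assert ours.high == pytest.approx(ref.high, abs=0.05)


class TestPcStability:
    def test_smoke_run_populates_all_fields(self, planted_one_factor):
        data = planted_one_factor(n=30, seed=0)
        sol = sy.fit_linear_pca(data)
        res = sy.pc_stability(sol, data, BootstrapConfig(B=2, ndim=2, seed=1))
        assert res.rotated_loadings.shape == (2, 6, 2)
        assert res.loading_mean.shape == (6, 2)
        assert np.all(res.loading_ci_low <= res.loading_ci_high + 1e-12)
        assert set(np.unique(res.ci_method_used)) <= {"bca", "percentile"}
        assert res.similarity_summary is not None
        assert res.communality_mean.shape == (6,)

    def test_reproducible_under_seed(self, planted_one_factor):
        data = planted_one_factor(n=40, seed=2)
        sol = sy.fit_linear_pca(data)
        cfg = BootstrapConfig(B=25, ndim=1, seed=5)
        a = sy.pc_stability(sol, data, cfg)
        b = sy.pc_stability(sol, data, cfg)
        assert np.array_equal(a.rotated_loadings, b.rotated_loadings)

    def test_strong_structure_is_stable(self, planted_one_factor):
        data = planted_one_factor(n=150, seed=3)
        sol = sy.fit_linear_pca(data)
        res = sy.pc_stability(sol, data, BootstrapConfig(B=200, ndim=1, seed=4))
        cc = float(res.similarity_summary["cc_index_mean"].iloc[0])
        assert cc >= 0.95
        assert np.abs(res.loading_mean - res.original).max() < 0.1

    def test_noise_pc1_is_unstable_in_most_seeds(self, noise_data):
        below = 0
        for seed in range(5):
            data = noise_data(n=30, v=6, seed=seed)
            sol = sy.fit_linear_pca(data)
            res = sy.pc_stability(
                sol,
                data,
                BootstrapConfig(B=120, ndim=1, seed=seed, ci_type="percentile"),
            )
            if float(res.similarity_summary["cc_index_mean"].iloc[0]) < 0.9:
                below += 1
        assert below >= 3

    def test_procrustes_correction_tightens_distribution(self, planted_one_factor):
        # rotated resamples sit closer to the parent than raw refits
        worse = 0
        for seed in range(10):
            data = planted_one_factor(n=60, v=6, seed=seed)
            sol = sy.fit_linear_pca(data)
            ndim = 2
            parent = sol.loadings.values[:, :ndim]
            rng = np.random.default_rng(100 + seed)
            raw_d, rot_d = [], []
            for _ in range(60):
                idx = rng.integers(0, 60, 60)
                _, _, load, _, _, _ = _fit_arrays(data.values[idx], True, True)
                raw_d.append(np.linalg.norm(load[:, :ndim] - parent))
                rot = sy.boot_pca_sample(data, idx, sol, ndim)
                rot_d.append(np.linalg.norm(rot.values - parent))
            if np.mean(rot_d) >= np.mean(raw_d):
                worse += 1
        assert worse == 0

    def test_percentile_interval_coverage_of_population_loading(self):
        # 95% percentile CIs should cover the population value of the PCA
        # loading functional in the vast majority of replicates.  For the
        # one-factor model (v=6, factor correlation 0.8, noise sd 0.6) the
        # population correlation matrix is R = 0.64 J + 0.36 I, whose top
        # eigenvalue is 0.64 v + 0.36 with uniform eigenvector, so the
        # population PC1 loading is sqrt((0.64 v + 0.36) / v).
        pop = float(np.sqrt((0.64 * 6 + 0.36) / 6))
        covered = 0
        reps = 60
        for seed in range(reps):
            model = sy.PlantedModel(
                n=80, L=sy.planted_loadings(6, 1, 0.8), noise_sd=0.6, seed=seed
            )
            data = sy.generate(model)
            sol = sy.fit_linear_pca(data)
            res = sy.pc_stability(
                sol,
                data,
                BootstrapConfig(
                    B=100, ndim=1, seed=seed, ci_type="percentile",
                    test_similarity=False,
                ),
            )
            if res.loading_ci_low[0, 0] <= pop <= res.loading_ci_high[0, 0]:
                covered += 1
        assert covered / reps >= 0.85

    def test_rejects_and_redraws_degenerate_resamples(self):
        # a column with one outlying non-constant value makes many
        # resamples zero-variance under scaling
        X = np.column_stack([np.r_[np.zeros(9), 1.0], np.arange(10.0), np.random.default_rng(0).normal(size=10)])
        data = sy.DataMatrix(X, ["spike", "x", "y"])
        sol = sy.fit_linear_pca(data)
        with pytest.warns(UserWarning, match="rejected"):
            res = sy.pc_stability(
                sol,
                data,
                BootstrapConfig(B=40, ndim=1, seed=1, ci_type="percentile",
                                test_similarity=False),
            )
        assert res.rejected_resamples > 0
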