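import numpy as np
import pytest
from scipy import stats

from odontolife.comparative import (
    ComparativeObservation,
    RatioObservation,
    compare_elpd,
    fit_lifespan_ratio,
    fit_phylo_regression,
    menopause_contrast,
    ou_covariance,
    pointwise_loo_density,
)
from odontolife.data_model import Chronogram
from odontolife.synthetic import CladeSimConfig, simulate_clade


def _star_tree(n, depth=1.0, index=0):
    taxa = [f"sp{i:02d}" for i in range(n)]
    D = 2 * depth * (1 - np.eye(n))
    return Chronogram(taxa=taxa, distances=D, tree_index=index)


def _obs_from_truth(tt, response="lifespan_obs", sd="lifespan_obs_sd", meno=True):
    return [
        ComparativeObservation(
            species=r.species, response_mean=getattr(r, response),
            response_sd=getattr(r, sd), menopause=int(r.menopause) if meno else 0,
            predictor_mean=r.log_length_obs, predictor_sd=r.log_length_obs_sd)
        for r in tt.itertuples()
    ]


class TestOUCovariance:
    def test_diagonal_is_eta_squared(self):
        D = np.array([[0.0, 2.0], [2.0, 0.0]])
        K = ou_covariance(D, 1.5, 0.3)
        assert np.allclose(np.diag(K), 1.5**2)

    def test_unit_value(self):
        K = ou_covariance(np.array([[0.0, 1.0], [1.0, 0.0]]), 1.0, 1.0)
        assert K[0, 1] == pytest.approx(np.exp(-1.0))

    def test_decay_to_zero_at_large_distance(self):
        K = ou_covariance(np.array([[0.0, 1e4], [1e4, 0.0]]), 1.0, 1.0)
        assert K[0, 1] < 1e-300 or K[0, 1] == 0.0

    def test_positive_semidefinite(self):
        rng = np.random.default_rng(0)
        pts = rng.random((6, 1)) * 10
        D = np.abs(pts - pts.T)
        K = ou_covariance(D, 2.0, 0.4)
        assert np.min(np.linalg.eigvalsh(K)) > -1e-10

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            ou_covariance(np.array([[0.0, 1.0], [2.0, 0.0]]), 1.0, 1.0)


class TestRegression:
    def test_ols_oracle_without_phylogeny_or_error(self):
        # no measurement error and no between-species covariance (kernel
        # off-diagonals forced to 0) reduces the model to iid regression
        rng = np.random.default_rng(1)
        n = 5
        s = np.linspace(-1, 1, n)
        M = np.array([0, 0, 0, 1, 1])
        y = 0.5 + 1.2 * s + 0.8 * M + 0.05 * rng.standard_normal(n)
        obs = [ComparativeObservation(f"sp{i:02d}", y[i], 0.0, int(M[i]), s[i], 0.0)
               for i in range(n)]
        tree = _star_tree(n)
        post = fit_phylo_regression(obs, [tree], seed=2, fix_rho=50.0,
                                    n_steps=1500, n_burn=1000)
        X = np.column_stack([np.ones(n), s, M])
        coef = np.linalg.lstsq(X, y, rcond=None)[0]
        assert abs(post.draws["beta_size"].mean() - coef[1]) < 1e-2
        # beta_pr has a much wider posterior here (only 2 menopause species),
        # so its Monte-Carlo error alone is ~5e-3; bound it accordingly
        assert abs(post.draws["beta_pr"].mean() - coef[2]) < 0.05

    def test_gls_oracle_with_fixed_kernel(self):
        # <=6 taxa, no measurement error, eta and rho pinned: posterior mean
        # should match the closed-form GLS estimate
        rng = np.random.default_rng(3)
        n = 6
        pts = np.sort(rng.random(n)) * 4
        D = np.abs(pts[:, None] - pts[None, :])
        tree = Chronogram(taxa=[f"sp{i:02d}" for i in range(n)], distances=D)
        eta, rho = 0.5, 0.6
        K = ou_covariance(D, eta, rho)
        s = rng.standard_normal(n)
        M = (np.arange(n) < 2).astype(float)
        y = 0.3 + 0.9 * s + 0.7 * M + rng.multivariate_normal(np.zeros(n), K)
        obs = [ComparativeObservation(f"sp{i:02d}", y[i], 0.0, int(M[i]), s[i], 0.0)
               for i in range(n)]
        post = fit_phylo_regression(obs, [tree], seed=4, fix_eta=eta, fix_rho=rho,
                                    n_steps=2000, n_burn=1000)
        X = np.column_stack([np.ones(n), s, M])
        Ki = np.linalg.inv(K + 1e-8 * np.eye(n))
        gls = np.linalg.solve(X.T @ Ki @ X, X.T @ Ki @ y)
        assert abs(post.draws["beta_size"].mean() - gls[1]) < 1e-2
        assert abs(post.draws["beta_pr"].mean() - gls[2]) < 1e-2

    def test_recovery_of_menopause_offset(self):
        cfg = CladeSimConfig(n_species=16, n_menopause=4, n_trees=3,
                             menopause_offset=40.0, seed=12)
        trees, _, truth = simulate_clade(cfg)
        post = fit_phylo_regression(_obs_from_truth(truth.table), trees, seed=13)
        b = post.draws["beta_pr"]
        assert abs(b.mean() - 40.0) < 2 * b.std()
        assert post.tail_probability("beta_pr", "greater") > 0.95

    def test_pooling_invariant_to_tree_order(self):
        cfg = CladeSimConfig(n_species=8, n_menopause=2, n_trees=2, seed=14)
        trees, _, truth = simulate_clade(cfg)
        obs = _obs_from_truth(truth.table)
        p1 = fit_phylo_regression(obs, trees, seed=15, n_steps=300, n_burn=300)
        p2 = fit_phylo_regression(obs, trees[::-1], seed=15, n_steps=300, n_burn=300)
        assert np.allclose(np.sort(p1.draws["beta_pr"]), np.sort(p2.draws["beta_pr"]))

    def test_too_few_species_rejected(self):
        obs = [ComparativeObservation("a", 1.0, 0.1, 0), ComparativeObservation("b", 2.0, 0.1, 1)]
        with pytest.raises(ValueError):
            fit_phylo_regression(obs, [_star_tree(2)])


class TestElpd:
    def _fitted_pair(self, offset, seed):
        cfg = CladeSimConfig(n_species=14, n_menopause=4, n_trees=2,
                             menopause_offset=offset, seed=seed)
        trees, _, truth = simulate_clade(cfg)
        obs_w = _obs_from_truth(truth.table)
        obs_wo = _obs_from_truth(truth.table, meno=False)
        pw = fit_phylo_regression(obs_w, trees, seed=seed + 1, n_steps=400, n_burn=500)
        pwo = fit_phylo_regression(obs_wo, trees, seed=seed + 1, n_steps=400, n_burn=500)
        return pw, pwo, obs_w, obs_wo, trees

    def test_self_comparison_is_exactly_zero(self):
        pw, _, obs_w, _, trees = self._fitted_pair(0.0, 20)
        d, se = compare_elpd(pw, pw, obs_w, obs_w, trees)
        assert d == 0.0 and se == 0.0

    def test_strong_effect_favors_menopause_model(self):
        pw, pwo, obs_w, obs_wo, trees = self._fitted_pair(40.0, 22)
        d, se = compare_elpd(pw, pwo, obs_w, obs_wo, trees)
        assert d < -2 * se < 0

    def test_pointwise_density_matches_closed_form(self):
        # 3-species toy, fixed parameters: conditional leave-one-out densities
        # recomputed from the joint multinormal by direct partitioning
        D = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 2.0], [2.0, 2.0, 0.0]])
        tree = Chronogram(taxa=["a", "b", "c"], distances=D)
        obs = [ComparativeObservation("a", 1.0, 0.3, 0, 0.1, 0.2),
               ComparativeObservation("b", 2.0, 0.4, 1, -0.2, 0.1),
               ComparativeObservation("c", 0.5, 0.2, 0, 0.4, 0.3)]
        alpha, bs, bp, eta, rho = 0.7, 1.1, -0.4, 0.9, 0.5
        got = pointwise_loo_density(obs, tree, alpha, bs, bp, eta, rho)
        y = np.array([1.0, 2.0, 0.5])
        s = np.array([0.1, -0.2, 0.4])
        sy = np.array([0.3, 0.4, 0.2])
        ss = np.array([0.2, 0.1, 0.3])
        M = np.array([0.0, 1.0, 0.0])
        C = ou_covariance(D, eta, rho) + np.diag(sy**2 + bs**2 * ss**2 + 1e-8)
        mu = alpha + bs * s + bp * M
        for i in range(3):
            j = [k for k in range(3) if k != i]
            cm = mu[i] + C[i, j] @ np.linalg.solve(C[np.ix_(j, j)], y[j] - mu[j])
            cv = C[i, i] - C[i, j] @ np.linalg.solve(C[np.ix_(j, j)], C[j, i])
            assert got[i] == pytest.approx(stats.norm.logpdf(y[i], cm, np.sqrt(cv)), abs=1e-8)

    def test_mismatched_species_rejected(self):
        pw, pwo, obs_w, obs_wo, trees = self._fitted_pair(0.0, 24)
        with pytest.raises(ValueError):
            compare_elpd(pw, pwo, obs_w, obs_wo[:-1], trees)


class TestLifespanRatio:
    def test_null_centred_when_sexes_equal(self):
        obs = [RatioObservation(f"sp{i}", 40.0 + i, 1.0, 40.0 + i, 1.0, int(i < 3))
               for i in range(12)]
        post = fit_lifespan_ratio(obs, seed=30, n_steps=500, n_burn=500)
        b = post.draws["beta_pr"]
        assert abs(b.mean()) < 2 * b.std()
        assert 0.05 < post.tail_probability("less") < 0.95

    def test_sign_recovery_across_replicates(self):
        hits = 0
        n_rep = 20
        for rep in range(n_rep):
            rng = np.random.default_rng(100 + rep)
            obs = []
            for i in range(10):
                meno = int(i < 3)
                f = 40 + 8 * rng.standard_normal()
                m = f * (0.8 if meno else 1.0) * np.exp(0.05 * rng.standard_normal())
                obs.append(RatioObservation(f"sp{i}", f, 1.5, m, 1.5, meno))
            post = fit_lifespan_ratio(obs, seed=200 + rep, n_steps=300, n_burn=400)
            # menopause raises the female:male ratio here
            if post.draws["beta_pr"].mean() > 0:
                hits += 1
        assert hits >= 18

    def test_zero_sd_matches_point_value_oracle(self):
        rng = np.random.default_rng(31)
        obs = []
        for i in range(14):
            meno = int(i < 4)
            f = 35 + 10 * rng.random()
            m = f * np.exp(-0.15 * meno + 0.08 * rng.standard_normal())
            obs.append(RatioObservation(f"sp{i}", f, 0.0, m, 0.0, meno))
        post = fit_lifespan_ratio(obs, seed=32)
        z = np.log([o.female_mean / o.male_mean for o in obs])
        M = np.array([o.menopause for o in obs], dtype=float)
        X = np.column_stack([np.ones(len(obs)), M])
        ols = np.linalg.lstsq(X, z, rcond=None)[0]
        b = post.draws["beta_pr"]
        assert abs(b.mean() - ols[1]) < max(2 * b.std() / np.sqrt(100), 0.02)

    def test_nonpositive_lifespan_rejected(self):
        with pytest.raises(ValueError):
            RatioObservation("sp", -1.0, 0.1, 30.0, 0.1, 0)


class TestMenopauseContrast:
    def test_missing_species_listed(self):
        with pytest.raises(ValueError, match="spB"):
            menopause_contrast({"spA": np.ones(5)}, {"spA": 0, "spB": 1},
                               [_star_tree(2)])

    def test_point_mass_equivalence_with_direct_regression(self):
        rng = np.random.default_rng(40)
        n = 8
        vals = rng.random(n) + np.array([0.7] * 3 + [0.0] * (n - 3))
        flags = {f"sp{i:02d}": int(i < 3) for i in range(n)}
        # literal point masses: mean is exactly vals[i], sd exactly 0
        draws = {f"sp{i:02d}": np.array([vals[i]]) for i in range(n)}
        tree = _star_tree(n)
        pc = menopause_contrast(draws, flags, [tree], seed=41, n_steps=300, n_burn=300)
        obs = [ComparativeObservation(f"sp{i:02d}", vals[i], 0.0, flags[f"sp{i:02d}"])
               for i in range(n)]
        pr = fit_phylo_regression(obs, [tree], seed=41, n_steps=300, n_burn=300)
        assert np.allclose(pc.draws["beta_pr"].values, pr.draws["beta_pr"].values)

    def test_shift_detected(self):
        rng = np.random.default_rng(42)
        n = 12
        flags = {f"sp{i:02d}": int(i < 4) for i in range(n)}
        draws = {f"sp{i:02d}": 0.5 + 0.7 * flags[f"sp{i:02d}"] + 0.05 * rng.standard_normal(80)
                 for i in range(n)}
        post = menopause_contrast(draws, flags, [_star_tree(n)], seed=43,
                                  n_steps=400, n_burn=500)
        assert post.tail_probability("beta_pr", "greater") > 0.95

    def test_shared_distribution_is_null(self):
        rng = np.random.default_rng(44)
        n = 12
        flags = {f"sp{i:02d}": int(i < 4) for i in range(n)}
        draws = {f"sp{i:02d}": 0.5 + 0.1 * rng.standard_normal(80) for i in range(n)}
        post = menopause_contrast(draws, flags, [_star_tree(n)], seed=45,
                                  n_steps=400, n_burn=500)
        assert 0.05 < post.tail_probability("beta_pr", "greater") < 0.95
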