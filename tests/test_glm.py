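import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from patchforage import glm
from patchforage import synthetic as syn


def random_design(rng, n=500, p=3):
    X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
    beta = rng.normal(0, 0.8, size=p)
    q = glm.logistic(X @ beta + rng.normal(0, 0.5, size=n))
    return X, q


class TestSoftLogistic:
    def test_hard_labels_collapse_to_standard_fit(self, rng):
        X, _ = random_design(rng)
        y = (rng.uniform(size=len(X)) < 0.4).astype(float)
        beta, info = glm.fit_soft_logistic(X, y)
        ref = sm.Logit(y, X).fit(disp=0).params
        assert np.allclose(beta, ref, atol=1e-7)

    def test_single_soft_observation_intercept_only(self):
        beta, info = glm.fit_soft_logistic(np.ones((1, 1)), np.array([0.5]))
        assert beta[0] == pytest.approx(0.0, abs=1e-10)
        assert info["loglik"] == pytest.approx(-np.log(2), rel=1e-12)

    def test_matches_weighted_row_expansion(self, rng):
        """KL objective == logistic fit on rows expanded to (q, 1-q) weights."""
        for _ in range(10):
            X, q = random_design(rng, n=300)
            beta, _ = glm.fit_soft_logistic(X, q)
            X2, y2, w2 = glm.expand_soft_rows(X, q)
            ref = sm.GLM(y2, X2, family=sm.families.Binomial(), freq_weights=w2).fit().params
            assert np.allclose(beta, ref, atol=1e-6)

    def test_parameter_recovery_within_three_se(self, rng):
        true = np.array([-1.0, 1.5, 0.02, -0.5, -0.8])
        n = 3000
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 4))])
        y = (rng.uniform(size=n) < glm.logistic(X @ true)).astype(float)
        beta, _ = glm.fit_soft_logistic(X, y)
        cov = np.linalg.inv((X.T * (glm.logistic(X @ beta) * (1 - glm.logistic(X @ beta)))) @ X)
        se = np.sqrt(np.diag(cov))
        assert np.all(np.abs(beta - true) <= 3 * se)

    def test_separation_raises_advising_ridge(self):
        X = np.column_stack([np.ones(20), np.r_[np.full(10, -1.0), np.full(10, 1.0)]])
        y = np.r_[np.zeros(10), np.ones(10)]
        with pytest.raises(glm.SeparationError, match="ridge|separ"):
            glm.fit_soft_logistic(X, y)
        beta, _ = glm.fit_soft_logistic(X, y, ridge_lam=0.1)  # penalized fit succeeds
        assert np.isfinite(beta).all()

    def test_ridge_shrinks_slopes_not_intercept(self, rng):
        X, q = random_design(rng, n=400)
        b0, _ = glm.fit_soft_logistic(X, q)
        b1, _ = glm.fit_soft_logistic(X, q, ridge_lam=5.0)
        assert np.all(np.abs(b1[1:]) < np.abs(b0[1:]) + 1e-12)


class TestCovariates:
    @staticmethod
    def _five_encounter_fixture():
        """One worm, exploit at the third sensed encounter."""
        return pd.DataFrame({
            "worm_id": [0] * 5,
            "k": range(5),
            "entry_time_s": [600.0, 1800.0, 3000.0, 4800.0, 6000.0],
            "exit_time_s": [660.0, 1860.0, 3300.0, 4860.0, 6060.0],
            "density": [1.0, 5.0, 10.0, 1.0, 5.0],
            "q": [0.0, 0.0, 1.0, 0.0, 0.0],
        })

    def test_bookkeeping_oracle(self):
        rows = glm.build_covariates(self._five_encounter_fixture(), acclimation_density=200.0)
        la = np.log(200.0)
        # first encounter: tau_s equals total elapsed time; priors at acclimation
        assert rows.loc[0, "tau_s"] == pytest.approx(600 / 3600)
        assert rows.loc[0, "rho_h"] == pytest.approx(la)
        assert rows.loc[0, "rho_e"] == pytest.approx(la)
        # second: off-food excludes the 60 s on patch 1
        assert rows.loc[1, "tau_s"] == pytest.approx((1800 - 660 + 600) / 3600)
        assert rows.loc[1, "rho_h"] == pytest.approx(np.log(1.0))
        # exploit at k=3 (q=1) resets the satiety clock at its exit (3300 s)
        assert rows.loc[3, "tau_s"] == pytest.approx((4800 - 3300) / 3600)
        assert rows.loc[3, "rho_e"] == pytest.approx(np.log(10.0))
        assert rows.loc[4, "rho_e"] == pytest.approx(np.log(10.0))
        # rho_e stays at acclimation before the first exploit
        assert rows.loc[2, "rho_e"] == pytest.approx(la)
        # tau_s never exceeds tau_t
        assert (rows["tau_s"] <= rows["tau_t"] + 1e-12).all()

    def test_density_zero_rejected(self):
        enc = self._five_encounter_fixture()
        enc.loc[2, "density"] = 0.0
        with pytest.raises(ValueError, match="density"):
            glm.build_covariates(enc, 200.0)

    def test_generator_and_builder_agree_on_true_sensed_set(self):
        """Rebuilding covariates over the truly sensed encounters reproduces
        the generator's own bookkeeping."""
        cfg = syn.SimConfig(seed=17)
        cov, gt = syn.simulate_decision_sequence(cfg, 30)
        sensed = gt.encounters[gt.encounters["sensed"]]
        rebuilt = glm.build_covariates(sensed, cfg.acclimation_density)
        merged = rebuilt.merge(cov, on=["worm_id", "k"], suffixes=("_r", "_g"))
        assert len(merged) == len(cov)
        for col in ("rho_k", "tau_s", "tau_t", "rho_h", "rho_e"):
            assert np.allclose(merged[f"{col}_r"], merged[f"{col}_g"], atol=1e-9), col


class TestResampling:
    def test_sample_encounters_extremes(self, rng):
        masks = glm.sample_encounters(np.ones(50), n_reps=5, seed=1)
        assert all(m.all() for m in masks)
        masks = glm.sample_encounters(np.zeros(50), n_reps=5, seed=1)
        assert all(not m.any() for m in masks)

    def test_worked_encounter_sampling_example(self):
        """10 encounters with sensing draws v=0 at k1,k3,k6,k8 leave the
        sensed subsequence K* = (k2,k4,k5,k7,k9,k10)."""
        v = np.array([0, 1, 0, 1, 1, 0, 1, 0, 1, 1], dtype=bool)  # k1..k10
        kept = np.flatnonzero(v) + 1
        assert kept.tolist() == [2, 4, 5, 7, 9, 10]
        enc = pd.DataFrame({
            "worm_id": 0, "k": np.arange(1, 11),
            "entry_time_s": np.arange(10) * 100.0,
            "exit_time_s": np.arange(10) * 100.0 + 30.0,
            "density": 5.0, "q": 0.0,
        })
        rows = glm.build_covariates(enc[v], 200.0)
        assert rows["k"].tolist() == [2, 4, 5, 7, 9, 10]
        assert rows["k_star"].tolist() == list(range(6))

    def test_bootstrap_preserves_worm_count_and_identity(self, rng):
        reps = glm.bootstrap_worms(np.arange(443), n_reps=50, seed=2)
        assert all(len(r) == 443 for r in reps)
        frac_absent = np.mean([1 - np.isin(np.arange(443), r).mean() for r in reps])
        assert frac_absent == pytest.approx(np.exp(-1), abs=0.02)

    def test_single_worm_bootstrap_trivial(self):
        reps = glm.bootstrap_worms([7], n_reps=10, seed=3)
        assert all((r == 7).all() for r in reps)

    def test_replicate_product_count(self):
        cfg = syn.SimConfig(seed=4, n_encounters_per_worm=8)
        _, gt = syn.simulate_decision_sequence(cfg, 25)
        fit = glm.fit_replicated(gt.encounters, cfg.acclimation_density,
                                 n_encounter_reps=4, n_worm_reps=5, seed=0,
                                 max_failed_frac=0.5)
        assert fit.n_replicates + fit.n_failed == 20


class TestHypothesisTests:
    def _fit_with_beta(self, b):
        return glm.FitResult(beta=np.asarray(b, dtype=float), coef_names=("b0", "bk"),
                             loglik=np.zeros(len(b)), aic=np.zeros(len(b)), bic=np.zeros(len(b)))

    def test_all_positive_replicates_hit_floor(self, rng):
        b = np.column_stack([np.abs(rng.normal(1, 0.1, 400)), rng.normal(0, 1, 400)])
        out = glm.test_coefficients(self._fit_with_beta(b))
        assert out.loc[0, "p_value"] == pytest.approx(2 / 401)
        assert out.loc[0, "at_floor"]

    def test_symmetric_distribution_p_near_one(self, rng):
        b = np.column_stack([rng.normal(0, 1, 1000), rng.normal(0, 1, 1000)])
        out = glm.test_coefficients(self._fit_with_beta(b))
        assert out["p_value"].min() > 0.5

    def test_strain_z_examples(self, rng):
        base = rng.normal(0, 1, size=(400, 2))
        fit_ref = glm.FitResult(beta=base, coef_names=("b0", "bk"), loglik=np.zeros(400),
                                aic=np.zeros(400), bic=np.zeros(400))
        fit_same = glm.FitResult(beta=base.copy(), coef_names=("b0", "bk"), loglik=np.zeros(400),
                                 aic=np.zeros(400), bic=np.zeros(400))
        out = glm.compare_strains(fit_same, fit_ref)
        assert np.allclose(out["z"], 0.0)
        assert out.loc[0, "p_value"] == pytest.approx(1.0)  # two-tailed at z=0
        # shifted mutant: left-tailed p = Phi(-3) for a density coefficient
        sa = base.std(axis=0, ddof=1)
        shift = base.copy()
        shift[:, 1] -= 3.0 * np.sqrt(2) * sa[1]
        fit_mut = glm.FitResult(beta=shift, coef_names=("b0", "bk"), loglik=np.zeros(400),
                                aic=np.zeros(400), bic=np.zeros(400))
        out = glm.compare_strains(fit_mut, fit_ref)
        assert out.loc[1, "p_value"] == pytest.approx(stats.norm.cdf(-3), rel=0.05)

    def test_mismatched_coefficients_rejected(self, rng):
        a = self._fit_with_beta(rng.normal(size=(200, 2)))
        b = glm.FitResult(beta=rng.normal(size=(200, 2)), coef_names=("b0", "bs"),
                          loglik=np.zeros(200), aic=np.zeros(200), bic=np.zeros(200))
        with pytest.raises(ValueError):
            glm.compare_strains(a, b)

    def test_benjamini_hochberg_by_hand(self):
        from statsmodels.stats.multitest import multipletests
        adj = multipletests([0.005, 0.01, 0.03, 0.04], method="fdr_bh")[1]
        assert np.allclose(adj, [0.02, 0.02, 0.04, 0.04])

    def test_shuffled_null_only_intercept_significant(self):
        """Shuffling the soft responses destroys every covariate effect."""
        cfg = syn.SimConfig(seed=5)
        _, gt = syn.simulate_decision_sequence(cfg, 150)
        fit = glm.fit_replicated(gt.encounters, cfg.acclimation_density,
                                 n_encounter_reps=10, n_worm_reps=20,
                                 seed=1, shuffle_response=True)
        out = glm.test_coefficients(fit)
        non_intercept = out[out["coef"] != "b0"]
        assert (non_intercept["p_value"] > 0.05).all()


class TestRidgeAndSelection:
    def test_lambda_grid_of_one(self, rng):
        cfg = syn.SimConfig(seed=6)
        cov, _ = syn.simulate_decision_sequence(cfg, 40)
        best, table = glm.optimize_ridge(cov, ("rho_k", "tau_s"), [0.3], seed=0)
        assert best == 0.3 and len(table) == 1

    def test_abundant_data_prefers_small_lambda(self, rng):
        cfg = syn.SimConfig(seed=7)
        cov, _ = syn.simulate_decision_sequence(cfg, 200)
        best, _ = glm.optimize_ridge(cov, ("rho_k", "tau_s", "rho_h", "rho_e"),
                                     [0.0, 1.0, 30.0], seed=0)
        assert best <= 1.0

    def test_collinear_small_n_prefers_positive_lambda(self, rng):
        n = 24
        x = rng.normal(size=n)
        rows = pd.DataFrame({
            "worm_id": np.repeat(np.arange(8), 3),
            "rho_k": x, "rho_h": x + rng.normal(0, 1e-3, n),
            "q": (rng.uniform(size=n) < glm.logistic(2 * x)).astype(float),
        })
        best, _ = glm.optimize_ridge(rows, ("rho_k", "rho_h"), [0.0, 0.5, 2.0], seed=1)
        assert best > 0.0

    def test_duplicate_covariate_changes_bic_not_loglik(self):
        cfg = syn.SimConfig(seed=8)
        cov, _ = syn.simulate_decision_sequence(cfg, 60)
        cov = cov.assign(rho_dup=cov["rho_k"] + 1e-9 * np.arange(len(cov)))
        glm._COV_TO_COEF.setdefault("rho_dup", "bk2")
        table = glm.model_selection(cov, {
            "base": ("rho_k", "tau_s"),
            "dup": ("rho_k", "rho_dup", "tau_s"),
        }, ridge_lam=1e-6)
        ll = table.set_index("model")["loglik"]
        bic = table.set_index("model")["bic"]
        assert ll["dup"] == pytest.approx(ll["base"], abs=0.05)
        assert bic["dup"] > bic["base"]

    def test_bic_prefers_true_model(self):
        cfg = syn.SimConfig(seed=9, n_encounters_per_worm=25, frac_sensed=1.0)
        cov, _ = syn.simulate_decision_sequence(cfg, 120)  # n = 3000 sensed
        table = glm.model_selection(cov, {
            "null": (),
            "true": ("rho_k", "tau_s", "rho_h", "rho_e"),
        })
        bic = table.set_index("model")["bic"]
        assert bic["true"] < bic["null"]

    def test_lrt_under_null_calibrates_to_chi2(self, rng):
        """2 delta-loglik for an irrelevant added covariate is ~ chi2(1)."""
        stats_ = []
        for i in range(120):
            rg = np.random.default_rng(i)
            n = 250
            rows = pd.DataFrame({
                "worm_id": np.repeat(np.arange(25), 10),
                "rho_k": rg.normal(size=n),
                "tau_s": rg.normal(size=n),  # irrelevant under H0
                "q": (rg.uniform(size=n) < glm.logistic(0.5 * rg.normal(size=n))).astype(float),
            })
            stat, df, p = glm.likelihood_ratio_test(rows, ("rho_k",), ("rho_k", "tau_s"))
            assert df == 1
            stats_.append(stat)
        ks = stats.kstest(stats_, stats.chi2(1).cdf)
        assert ks.pvalue > 0.01

    def test_non_nested_lrt_rejected(self):
        cfg = syn.SimConfig(seed=10)
        cov, _ = syn.simulate_decision_sequence(cfg, 20)
        with pytest.raises(ValueError, match="nested"):
            glm.likelihood_ratio_test(cov, ("rho_k",), ("tau_s",))


class TestPredictions:
    def test_first_exploitation_geometric_law(self):
        p = 0.25
        seqs = [np.full(40, p)] * 50
        out = glm.simulate_first_exploitation(seqs, n_sims=200, seed=0)
        expect = p * (1 - p)  # P(first at k=2)
        n = out["n_total"].iloc[0]
        se = np.sqrt(expect * (1 - expect) / n)
        assert out.loc[out["k"] == 2, "probability"].iloc[0] == pytest.approx(expect, abs=3 * se)
        # monotone decreasing histogram under constant p
        probs = out["probability"].to_numpy()[:10]
        assert np.all(np.diff(probs) <= 1e-3)

    def test_certain_exploit_all_mass_at_first(self):
        out = glm.simulate_first_exploitation([np.ones(5)] * 3, n_sims=50, seed=1)
        assert out.loc[out["k"] == 1, "probability"].iloc[0] == 1.0
        assert out["n_censored"].iloc[0] == 0

    def test_probability_surface_values_and_monotonicity(self):
        beta = np.array([0.0, 1.0, -0.5])
        names = ("b0", "bk", "bh")
        grid = np.array([-1.0, 0.0, np.log(3), 2.0])
        surf = glm.predict_probability_surface(beta, names, grid, np.array([0.0]),
                                               vary=("bk", "bh"), fixed={})
        assert surf[1, 0] == pytest.approx(0.5)
        assert surf[2, 0] == pytest.approx(0.75)  # beta.x = ln 3
        # bh < 0: decreasing in rho_h at fixed rho_k
        surf2 = glm.predict_probability_surface(beta, names, np.array([1.0]),
                                                np.linspace(-2, 2, 9), vary=("bk", "bh"), fixed={})
        assert np.all(np.diff(surf2[0]) < 0)
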