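"""Cox models: oracle agreement, frailty behaviour, influence screen,
model comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from inbrex.axes import derive_axes
from inbrex.exceptions import (
    DegenerateInputError,
    MismatchedDataError,
    NotNestedError,
    SingularInformationError,
)
from inbrex.simulate import SimConfig, generate_line_fitness, generate_lineage_histories
from inbrex.survival import (
    CoxFrailty,
    CoxPH,
    compare_aic,
    dfbeta_outlier_screen,
    extract_line_random_intercepts,
    fit_cox_frailty,
    fit_cox_ph,
    lrt,
)

SQRT2 = np.sqrt(2.0)


def _oracle_breslow_loglik(beta, time, event, x):
    """Directly coded partial log-likelihood for distinct event times."""
    ll = 0.0
    for t, d in zip(time[event], x[event]):
        at_risk = time >= t
        ll += beta * d - np.log(np.sum(np.exp(beta * x[at_risk])))
    return ll


class TestCoxPH:
    def test_toy_set_matches_direct_partial_likelihood(self, toy_survival):
        df = toy_survival
        time = df["time"].to_numpy()
        event = df["event"].to_numpy().astype(bool)
        x = df["x"].to_numpy()
        res = optimize.minimize_scalar(
            lambda b: -_oracle_breslow_loglik(b, time, event, x),
            bracket=(-2, 2))
        fit = CoxPH().fit(df[["x"]], df[["time", "event"]])
        assert abs(fit.coef_[0] - res.x) < 1e-6
        assert abs(fit.log_likelihood_ + res.fun) < 1e-8

    def test_matches_lifelines_with_heavy_ties(self, small_cfg):
        lifelines = pytest.importorskip("lifelines")
        cfg = SimConfig(n_lines=15, lineages_per_line=12, seed=21,
                        time_mode="discrete")
        lines = generate_line_fitness(cfg)
        rec, _ = generate_lineage_histories(lines, cfg)
        axes = derive_axes(lines)
        fit = fit_cox_ph(rec, axes)
        df = rec.merge(axes[["line_id", "antagonism", "concordance"]], on="line_id")
        cph = lifelines.CoxPHFitter().fit(
            df[["time", "event", "antagonism", "concordance"]], "time", "event")
        np.testing.assert_allclose(fit.coef_, cph.params_.values, atol=1e-6)
        np.testing.assert_allclose(fit.se_, cph.standard_errors_.values, atol=1e-6)
        assert abs(fit.log_likelihood_ - cph.log_likelihood_) < 1e-6

    def test_high_risk_group_gets_positive_coefficient(self):
        rng = np.random.default_rng(1)
        g = np.repeat([0.0, 1.0], 60)
        t = np.where(g == 1, rng.exponential(1.0, 120), rng.exponential(5.0, 120))
        event = t <= 4.0
        t = np.minimum(t, 4.0)
        fit = CoxPH().fit(g[:, None], np.column_stack([t, event]))
        assert fit.coef_[0] > 0.5

    def test_breslow_equals_efron_without_ties(self, small_dataset):
        # continuous-time records are tie-free, where the two approximations
        # coincide exactly
        rec, axes = small_dataset["records"], small_dataset["axes"]
        f_e = fit_cox_ph(rec, axes, ties="efron")
        f_b = fit_cox_ph(rec, axes, ties="breslow")
        np.testing.assert_allclose(f_b.coef_, f_e.coef_, atol=1e-9)
        assert abs(f_b.log_likelihood_ - f_e.log_likelihood_) < 1e-9

    def test_covariate_scaling_scales_coefficient_inversely(self, small_dataset):
        rec, axes = small_dataset["records"], small_dataset["axes"]
        f1 = fit_cox_ph(rec, axes)
        scaled = axes.assign(antagonism=axes["antagonism"] * 4.0)
        f2 = fit_cox_ph(rec, scaled)
        assert abs(f2.coef_[0] - f1.coef_[0] / 4.0) < 1e-7
        assert abs(f2.log_likelihood_ - f1.log_likelihood_) < 1e-8

    def test_reparameterization_is_exact_linear_map(self, small_dataset):
        rec, axes = small_dataset["records"], small_dataset["axes"]
        f_ac = fit_cox_ph(rec, axes, covariate_cols=["antagonism", "concordance"])
        f_mf = fit_cox_ph(rec, axes, covariate_cols=["male_std", "female_std"])
        assert abs(f_ac.log_likelihood_ - f_mf.log_likelihood_) < 1e-6
        ba, bc = f_ac.coef_
        bm_pred, bf_pred = (ba + bc) / SQRT2, (bc - ba) / SQRT2
        np.testing.assert_allclose(f_mf.coef_, [bm_pred, bf_pred], atol=1e-6)

    def test_collinear_covariates_named_in_error(self, small_dataset):
        rec, axes = small_dataset["records"], small_dataset["axes"]
        axes = axes.assign(antagonism_copy=axes["antagonism"])
        with pytest.raises(SingularInformationError) as exc:
            fit_cox_ph(rec, axes, covariate_cols=["antagonism", "antagonism_copy"])
        assert "antagonism" in str(exc.value)

    def test_no_events_rejected(self):
        df = pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": [0, 0, 0],
                           "x": [0.1, 0.2, 0.3]})
        with pytest.raises(DegenerateInputError):
            CoxPH().fit(df[["x"]], df[["time", "event"]])

    def test_null_covariate_recovers_zero_on_average(self):
        # covariate independent of the generating hazard
        coefs = []
        for rep in range(60):
            rng = np.random.default_rng(500 + rep)
            n = 150
            t = rng.exponential(2.0, n)
            event = t <= 5.0
            t = np.minimum(t, 5.0)
            x = rng.normal(size=n)
            fit = CoxPH().fit(x[:, None], np.column_stack([t, event]))
            coefs.append(fit.coef_[0])
        assert abs(np.mean(coefs)) < 3 * np.std(coefs) / np.sqrt(len(coefs)) + 0.02


class TestCoxFrailty:
    def test_sigma2_zero_equals_standard_cox(self, small_dataset):
        rec, axes = small_dataset["records"], small_dataset["axes"]
        plain = fit_cox_ph(rec, axes)
        frail = fit_cox_frailty(rec, axes, sigma2=0.0)
        np.testing.assert_allclose(frail.coef_, plain.coef_, atol=1e-10)
        assert frail.frailty_variance_ == 0.0
        assert abs(frail.log_likelihood_ - plain.log_likelihood_) < 1e-10

    def test_gradient_matches_finite_differences(self, small_dataset):
        from inbrex._partial_likelihood import PartialLikelihood
        rec, axes = small_dataset["records"], small_dataset["axes"]
        df = rec.merge(axes[["line_id", "antagonism", "concordance"]], on="line_id")
        X = df[["antagonism", "concordance"]].to_numpy()
        pl = PartialLikelihood(df["time"], df["event"], X)
        beta = np.array([0.3, -0.2])
        ll, grad, info = pl.loglik_grad_info(beta)
        eps = 1e-6
        for j in range(2):
            e = np.zeros(2)
            e[j] = eps
            num = (pl.loglik(beta + e) - pl.loglik(beta - e)) / (2 * eps)
            assert abs(num - grad[j]) < 1e-4
            numh = (pl.loglik_grad(beta + e)[1][j]
                    - pl.loglik_grad(beta - e)[1][j]) / (2 * eps)
            assert abs(-numh - info[j, j]) < 1e-3

    def test_frailty_variance_recovery_smoke(self):
        # quick version of the recovery experiment (full scale in acceptance)
        s2 = []
        for rep in range(15):
            cfg = SimConfig(seed=7000 + rep)
            lines = generate_line_fitness(cfg)
            rec, _ = generate_lineage_histories(lines, cfg)
            fit = fit_cox_frailty(rec, derive_axes(lines))
            s2.append(fit.frailty_variance_)
        assert abs(np.mean(s2) - 0.14) < 0.07

    def test_random_intercepts_recover_planted_frailties(self):
        cfg = SimConfig(seed=77, frailty_variance=0.5)
        lines = generate_line_fitness(cfg)
        rec, truth = generate_lineage_histories(lines, cfg)
        null_fit = fit_cox_frailty(rec, covariates=None, covariate_cols=[])
        b = extract_line_random_intercepts(null_fit)
        planted = truth.set_index("line_id")["frailty"]
        rho = stats.spearmanr(b.reindex(planted.index), planted).statistic
        assert rho > 0.7
        assert abs(b.mean()) < 0.1

    def test_no_heterogeneity_estimates_zero_variance(self):
        cfg = SimConfig(seed=5, frailty_variance=0.0, beta_antagonism=0.0,
                        beta_concordance=0.0)
        lines = generate_line_fitness(cfg)
        rec, _ = generate_lineage_histories(lines, cfg)
        fit = fit_cox_frailty(rec, covariates=None, covariate_cols=[])
        assert fit.frailty_variance_ < 0.02
        if fit.frailty_variance_ == 0.0:
            assert fit.boundary_
            assert (fit.random_effects_ == 0).all()

    def test_requires_groups(self, small_dataset):
        rec, axes = small_dataset["records"], small_dataset["axes"]
        df = rec.merge(axes[["line_id", "antagonism"]], on="line_id")
        with pytest.raises(ValueError, match="groups"):
            CoxFrailty().fit(df[["antagonism"]], df[["time", "event"]])


class TestModelComparison:
    def test_aic_of_model_vs_itself_is_zero(self, small_dataset):
        rec, axes = small_dataset["records"], small_dataset["axes"]
        fit = fit_cox_frailty(rec, axes)
        assert compare_aic(fit, fit) == 0.0

    def test_planted_effect_beats_null_and_mismatch_rejected(self, small_dataset):
        rec, axes = small_dataset["records"], small_dataset["axes"]
        fit = fit_cox_frailty(rec, axes)
        null = fit_cox_frailty(rec, covariates=None, covariate_cols=[])
        assert compare_aic(fit, null) > 0.0
        other = rec.iloc[:-5]
        null_other = fit_cox_frailty(other, covariates=None, covariate_cols=[])
        with pytest.raises(MismatchedDataError):
            compare_aic(fit, null_other)

    def test_noise_covariate_gains_little_aic(self):
        deltas = []
        for rep in range(30):
            cfg = SimConfig(n_lines=15, lineages_per_line=12, seed=9000 + rep,
                            beta_antagonism=0.0, beta_concordance=0.0,
                            frailty_variance=0.0)
            lines = generate_line_fitness(cfg)
            rec, _ = generate_lineage_histories(lines, cfg)
            axes = derive_axes(lines)
            fit = fit_cox_ph(rec, axes, covariate_cols=["antagonism"])
            # null fixed-effects model: AIC = -2*ll0 (zero parameters)
            delta = (-2.0 * fit.null_log_likelihood_) - fit.aic_
            deltas.append(delta)
        assert np.mean(deltas) <= 2.0

    def test_lrt_identical_models(self, small_dataset):
        rec, axes = small_dataset["records"], small_dataset["axes"]
        fit = fit_cox_ph(rec, axes)
        assert lrt(fit, fit) == (0.0, 0, 1.0)

    def test_lrt_rejects_non_nested(self, small_dataset):
        rec, axes = small_dataset["records"], small_dataset["axes"]
        f1 = fit_cox_ph(rec, axes, covariate_cols=["antagonism"])
        f2 = fit_cox_ph(rec, axes, covariate_cols=["concordance"])
        with pytest.raises(NotNestedError):
            lrt(f1, f2)

    def test_lrt_detects_planted_interaction(self):
        pvals = []
        for rep in range(20):
            rng = np.random.default_rng(1300 + rep)
            cfg = SimConfig(n_lines=20, lineages_per_line=15, seed=1300 + rep,
                            frailty_variance=0.0)
            lines = generate_line_fitness(cfg)
            axes = derive_axes(lines)
            eta = (0.2 * axes["antagonism"] - 0.14 * axes["concordance"]
                   + 0.8 * axes["antagonism"] * axes["concordance"]).to_numpy()
            rate = cfg.baseline_hazard * np.exp(np.repeat(eta, cfg.lineages_per_line))
            t = rng.exponential(1.0 / rate)
            rec = pd.DataFrame({
                "line_id": np.repeat(axes["line_id"].to_numpy(), cfg.lineages_per_line),
                "time": np.minimum(t, 10.0), "event": t <= 10.0})
            f0 = fit_cox_ph(rec, axes, covariate_cols=["antagonism", "concordance"])
            f1 = fit_cox_ph(rec, axes, covariate_cols=[
                "antagonism", "concordance", "antagonism:concordance"])
            pvals.append(lrt(f0, f1)[2])
        assert np.median(pvals) < 0.05


class TestOutlierScreen:
    def _planted_outlier_data(self, seed=3, shift=2.5, n_lines=12,
                              lineages_per_line=10):
        cfg = SimConfig(n_lines=n_lines, lineages_per_line=lineages_per_line,
                        seed=seed, frailty_variance=0.0)
        lines = generate_line_fitness(cfg)
        axes = derive_axes(lines)
        # plant one extreme male-benefit line (>3 SD on antagonism) whose
        # hazard is strongly elevated beyond what the common slope predicts
        a = axes["antagonism"].to_numpy().copy()
        a[0] = a[1:].mean() + 3.5 * a[1:].std(ddof=1)
        axes["antagonism"] = a
        eta = 0.2 * a
        eta[0] += shift
        rng = np.random.default_rng(seed)
        rate = cfg.baseline_hazard * np.exp(np.repeat(eta, lineages_per_line))
        t = rng.exponential(1.0 / rate)
        rec = pd.DataFrame({
            "line_id": np.repeat(axes["line_id"].to_numpy(), lineages_per_line),
            "lineage_id": np.arange(len(t)),
            "time": np.minimum(t, 10.0), "event": t <= 10.0})
        return rec, axes

    def test_planted_extreme_line_tops_line_influence(self):
        rec, axes = self._planted_outlier_data(seed=200, n_lines=41,
                                               lineages_per_line=20)
        screen = dfbeta_outlier_screen(rec, axes,
                                       covariate_cols=["antagonism", "concordance"])
        assert screen.line_influence.index[0] == axes.loc[0, "line_id"]
        assert screen.line_influence["influence_score"].iloc[0] > 1.5

    def test_duplicated_rows_dilute_influence(self):
        rec, axes = self._planted_outlier_data()
        screen1 = dfbeta_outlier_screen(rec, axes, covariate_cols=["antagonism"])
        dup = pd.concat([rec, rec], ignore_index=True)
        screen2 = dfbeta_outlier_screen(dup, axes, covariate_cols=["antagonism"])
        d1 = screen1.deltas["antagonism"].abs().max()
        d2 = screen2.deltas["antagonism"].abs().max()
        assert d2 < d1

    def test_exchangeable_lines_rarely_form_clusters(self):
        n_clean = 0
        reps = 20
        for rep in range(reps):
            cfg = SimConfig(n_lines=12, lineages_per_line=10, seed=4000 + rep,
                            beta_antagonism=0.0, beta_concordance=0.0,
                            frailty_variance=0.0)
            lines = generate_line_fitness(cfg)
            rec, _ = generate_lineage_histories(lines, cfg)
            screen = dfbeta_outlier_screen(rec, derive_axes(lines),
                                           covariate_cols=["antagonism",
                                                           "concordance"])
            n_clean += len(screen.cluster_lines) == 0
        assert n_clean >= 0.9 * reps
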