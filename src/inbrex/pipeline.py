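"""End-to-end orchestration: simulate/load -> axes -> survival fits ->
influence screen -> forecasts -> follow-up, assembled into a run report.

The report is a plain nested dict (JSON-serializable, reproducible
bit-identically from the same config and inputs) whose blocks mirror the
result objects of the analysis: coefficient tables for both covariate
parameterizations, interaction likelihood-ratio tests, delta-AIC against the
null frailty model, the influence screen summary, per-line random-intercept
extinction risks, demographic forecasts against the observed extinction
proportion, and follow-up test statistics.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from ._version import __version__ as _version
from .axes import derive_axes
from .followup import select_extreme_lines, test_zero_rates, fit_offspring_lmm
from .forecasts import (
    project_first_generation_extinction,
    simulate_fecundity_extinction,
)
from .simulate import (
    SimConfig,
    generate_fecundities,
    generate_followup_data,
    generate_line_fitness,
    generate_lineage_histories,
)
from .survival import (
    compare_aic,
    dfbeta_outlier_screen,
    extract_line_random_intercepts,
    fit_cox_frailty,
    lrt,
)

log = logging.getLogger("inbrex.pipeline")

__all__ = ["run_pipeline"]


def _coef_block(fit):
    s = fit.summary()
    return {
        "coefficients": {
            name: {"coef": round(float(s.loc[name, "coef"]), 10),
                   "se": round(float(s.loc[name, "se"]), 10),
                   "z": round(float(s.loc[name, "z"]), 10),
                   "p": round(float(s.loc[name, "p"]), 10)}
            for name in s.index
        },
        "frailty_variance": round(float(fit.frailty_variance_), 10),
        "integrated_loglik": round(float(fit.log_likelihood_), 10),
        "aic": round(float(fit.aic_), 10),
        "converged": bool(fit.converged_),
    }


def _fit_block(records, axes, cols, null_fit):
    """Frailty fit + interaction LRT + delta-AIC for one parameterization."""
    fit = fit_cox_frailty(records, axes, covariate_cols=list(cols))
    inter = f"{cols[0]}:{cols[1]}"
    fit_inter = fit_cox_frailty(records, axes, covariate_cols=list(cols) + [inter])
    chi2, df, p = lrt(fit, fit_inter)
    block = _coef_block(fit)
    block["interaction_lrt"] = {"chi_square": round(chi2, 10), "df": df,
                                "p": round(p, 10)}
    block["delta_aic_vs_null"] = round(compare_aic(fit, null_fit), 10)
    return fit, block


def run_pipeline(config: SimConfig | None = None, out_dir=None,
                 simulate: bool = True, inputs: dict | None = None,
                 forecast_replicates: int = 2000) -> dict:
    """Run every analysis stage and return the report dict.

    Parameters
    ----------
    config : SimConfig (required when ``simulate=True``; its seed drives all
        randomness, so the same config regenerates an identical report).
    out_dir : optional directory for report.json and stage CSVs.
    simulate : generate all inputs from ``config``; otherwise ``inputs`` must
        map 'line_fitness', 'records', 'fecundity' (and optionally
        'followup') to DataFrames.
    forecast_replicates : Monte-Carlo trajectories per line for the
        fecundity-only forecast.
    """
    config = config or SimConfig()
    report = {"config": config.to_dict(), "version": _version, "stages": {}}

    # -- stage: inputs -----------------------------------------------------
    if simulate:
        log.info("stage inputs: simulating from seed %s", config.seed)
        line_fitness = generate_line_fitness(config)
        records, truth = generate_lineage_histories(line_fitness, config)
        fecundity = generate_fecundities(line_fitness, config)
    else:
        if not inputs or not {"line_fitness", "records", "fecundity"} <= set(inputs):
            raise ValueError("inputs must provide line_fitness, records, fecundity")
        line_fitness, records = inputs["line_fitness"], inputs["records"]
        fecundity = inputs["fecundity"]
        truth = None

    def _stage(name, fn):
        log.info("stage %s", name)
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    # -- stage: axes -------------------------------------------------------
    axes = _stage("axes", lambda: derive_axes(line_fitness))

    # -- stage: survival ---------------------------------------------------
    def _survival():
        null_fit = fit_cox_frailty(records, covariates=None, covariate_cols=[])
        _, block_ac = _fit_block(records, axes, ("antagonism", "concordance"), null_fit)
        _, block_fm = _fit_block(records, axes, ("female_std", "male_std"), null_fit)
        intercepts = extract_line_random_intercepts(null_fit)
        return null_fit, block_ac, block_fm, intercepts

    null_fit, block_ac, block_fm, intercepts = _stage("survival", _survival)
    observed = float(records["event"].mean())
    report["stages"]["survival"] = {
        "antagonism_concordance": block_ac,
        "female_male": block_fm,
        "null_frailty_variance": round(float(null_fit.frailty_variance_), 10),
        "observed_extinction_proportion": round(observed, 10),
        "random_intercepts": {k: round(float(v), 10)
                              for k, v in intercepts.items()},
    }

    # -- stage: influence screen ------------------------------------------
    def _influence():
        screen = dfbeta_outlier_screen(records, axes,
                                       covariate_cols=["antagonism", "concordance"])
        # exclusion candidates: lines with a majority of records flagged,
        # ranked by normalized line-level influence
        candidates = [ln for ln in screen.line_influence.index
                      if ln in screen.cluster_lines]
        out = {"n_flagged_records": int(len(screen.flagged)),
               "flagged_records_by_line": {str(k): int(v)
                                           for k, v in screen.by_line.items()},
               "line_influence_ranking": [str(x) for x in
                                          screen.line_influence.index[:5]],
               "thresholds": {k: round(float(v), 10)
                              for k, v in screen.thresholds.items()}}
        if candidates:
            top = candidates[0]
            keep_fit = line_fitness[line_fitness["line_id"] != top]
            keep_rec = records[records["line_id"] != top]
            axes_excl = derive_axes(keep_fit)   # derived axes recomputed
            null_excl = fit_cox_frailty(keep_rec, covariates=None, covariate_cols=[])
            _, block_excl = _fit_block(keep_rec, axes_excl,
                                       ("antagonism", "concordance"), null_excl)
            out["excluded_line"] = str(top)
            out["antagonism_concordance_excluding_outlier"] = block_excl
            out["n_lines_after_exclusion"] = int(keep_fit.shape[0])
        return out

    report["stages"]["influence"] = _stage("influence", _influence)

    # -- stage: forecasts --------------------------------------------------
    def _forecasts():
        sim = simulate_fecundity_extinction(
            fecundity, generations=config.max_generations,
            lineages_per_line=config.lineages_per_line,
            replicates=forecast_replicates, seed=config.seed + 90001)
        first = records.assign(extinct_g1=(records["event"])
                               & (records["time"] <= 1.0))
        per_line = (first.groupby("line_id")["extinct_g1"]
                    .agg(extinct="sum", total="size").reset_index())
        proj = project_first_generation_extinction(
            per_line, generations=config.max_generations, mode="geometric")
        proj_lin = project_first_generation_extinction(
            per_line, generations=config.max_generations, mode="linear")
        return {
            "fecundity_simulation": round(sim.overall, 10),
            "first_generation_projection_geometric": round(proj.overall, 10),
            "first_generation_projection_linear": round(proj_lin.overall, 10),
            "observed_extinction_proportion": round(observed, 10),
            "forecast_replicates": forecast_replicates,
            "compounding_default": "geometric",
        }

    report["stages"]["forecasts"] = _stage("forecasts", _forecasts)

    # -- stage: follow-up --------------------------------------------------
    def _followup():
        sel = select_extreme_lines(
            axes.set_index("line_id")["antagonism"], intercepts, n_extreme=3)
        followup = (inputs or {}).get("followup")
        if followup is None and simulate:
            followup = generate_followup_data(
                {"male_benefit": sel.top, "female_benefit": sel.bottom}, config)
        out = {"extreme_lines": {"male_benefit": [str(x) for x in sel.top],
                                 "female_benefit": [str(x) for x in sel.bottom]},
               "pc1_loadings": [round(float(v), 10) for v in sel.loadings]}
        if followup is not None:
            chi2, df, p = test_zero_rates(followup)
            out["zero_rate_test"] = {"chi_square": round(chi2, 10), "df": df,
                                     "p": round(p, 10)}
            lmm = fit_offspring_lmm(followup)
            out["offspring_lmm"] = {
                "chi_square": round(lmm.chi_square, 10), "df": lmm.df,
                "p": round(lmm.p, 10),
                "category_effect": round(lmm.category_effect, 10),
                "variance_components": {k: round(float(v), 10)
                                        for k, v in lmm.variance_components.items()},
                "n": lmm.n,
            }
        return out

    report["stages"]["followup"] = _stage("followup", _followup)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        axes.to_csv(out_dir / "axes.csv", index=False)
        records.to_csv(out_dir / "records.csv", index=False)
        fecundity.to_csv(out_dir / "fecundity.csv", index=False)
        if truth is not None:
            truth.to_csv(out_dir / "truth.csv", index=False)
        (out_dir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n")
        log.info("report written to %s", out_dir / "report.json")
    return report
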