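"""Proportional-hazards models of lineage extinction.

Two estimators in the scikit-learn idiom:

* :class:`CoxPH` — standard Cox proportional hazards (fixed effects only).
* :class:`CoxFrailty` — mixed-effects Cox with a Gaussian random intercept
  per group (shared log-normal frailty), the model used to quantify
  per-isofemale-line heterogeneity in extinction risk.

The frailty model maximizes the Laplace-approximate integrated partial
likelihood: an inner penalized Newton-Raphson over (fixed coefficients,
per-group effects b) with Gaussian penalty b'b/(2 sigma^2), and an outer
bounded one-dimensional search over the frailty variance sigma^2.  With q
groups and information block I_bb for b at the joint mode,

    ILL(s2) = lpl(beta, b) - b'b/(2 s2) - 1/2 log det(I_q + s2 * I_bb),

which tends to the fixed-effects partial log-likelihood as s2 -> 0.  Ties are
handled by the Efron approximation by default (Breslow optional), important
because discrete generation times produce heavy ties.

Module-level functions (`fit_cox_ph`, `fit_cox_frailty`,
`dfbeta_outlier_screen`, `compare_aic`, `lrt`,
`extract_line_random_intercepts`) are thin wrappers over the estimators,
operating on lineage-record / covariate-table DataFrames.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from ._partial_likelihood import PartialLikelihood, newton_raphson
from .exceptions import MismatchedDataError, NotNestedError

__all__ = [
    "CoxPH",
    "CoxFrailty",
    "fit_cox_ph",
    "fit_cox_frailty",
    "dfbeta_outlier_screen",
    "compare_aic",
    "lrt",
    "extract_line_random_intercepts",
    "OutlierScreenResult",
]


# ---------------------------------------------------------------------------
# helpers

def _check_y(y):
    """Coerce survival outcome to (times, events).

    Accepts a DataFrame with 'time'/'event' columns, a structured array with
    two fields, an (n, 2) array [time, event], or a (times, events) pair.
    """
    if isinstance(y, pd.DataFrame):
        return y["time"].to_numpy(float), y["event"].to_numpy().astype(bool)
    if isinstance(y, tuple) and len(y) == 2:
        return np.asarray(y[0], float), np.asarray(y[1]).astype(bool)
    arr = np.asarray(y)
    if arr.dtype.names is not None and len(arr.dtype.names) == 2:
        a, b = arr.dtype.names
        # scikit-survival convention puts the event flag first
        if arr[a].dtype == bool:
            return arr[b].astype(float), arr[a].astype(bool)
        return arr[a].astype(float), arr[b].astype(bool)
    arr = np.atleast_2d(np.asarray(arr, float))
    if arr.shape[1] != 2:
        raise ValueError("y must provide a time and an event column")
    return arr[:, 0], arr[:, 1].astype(bool)


def _check_X(X, n=None):
    """Return (matrix, column names); X may be None for a null model."""
    if X is None:
        if n is None:
            raise ValueError("X=None requires n")
        return np.empty((n, 0)), []
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(float), list(X.columns)
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] == 1 and n is not None and n != 1:
        X = X.T
    return X, [f"x{i}" for i in range(X.shape[1])]


def _records_signature(times, events):
    order = np.lexsort((events, times))
    h = hashlib.sha1()
    h.update(np.round(np.asarray(times, float)[order], 10).tobytes())
    h.update(np.asarray(events)[order].astype(np.uint8).tobytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# estimators

class CoxPH(BaseEstimator):
    """Cox proportional-hazards model (fixed effects, no frailty).

    Parameters
    ----------
    ties : 'efron' (default) or 'breslow'.
    tol : convergence tolerance on the change in log partial likelihood.
    max_iter : Newton-Raphson iteration cap.
    """

    def __init__(self, ties: str = "efron", tol: float = 1e-8, max_iter: int = 100):
        self.ties = ties
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y, beta0=None):
        times, events = _check_y(y)
        Xm, names = _check_X(X, n=times.shape[0])
        if Xm.shape[1] == 0:
            raise ValueError("CoxPH requires at least one covariate; "
                             "use CoxFrailty for a null (frailty-only) model")
        pl = PartialLikelihood(times, events, Xm, ties=self.ties)
        res = newton_raphson(pl, beta0=beta0, tol=self.tol,
                             max_iter=self.max_iter, column_names=names)
        cov = np.linalg.inv(res["info"])
        self.coef_ = res["beta"]
        self.se_ = np.sqrt(np.diag(cov))
        self.zvalues_ = self.coef_ / self.se_
        self.pvalues_ = 2.0 * stats.norm.sf(np.abs(self.zvalues_))
        self.covariance_ = cov
        self.log_likelihood_ = res["loglik"]
        self.null_log_likelihood_ = pl.loglik(np.zeros(Xm.shape[1]))
        self.df_model_ = Xm.shape[1]
        self.aic_ = -2.0 * self.log_likelihood_ + 2.0 * self.df_model_
        self.converged_ = res["converged"]
        self.n_iter_ = res["n_iter"]
        self.feature_names_in_ = names
        self.param_names_ = list(names)
        self.n_ = times.shape[0]
        self.n_events_ = int(events.sum())
        self._signature = _records_signature(times, events)
        return self

    def summary(self) -> pd.DataFrame:
        """Coefficient table: Coef., s.e., z, P."""
        return pd.DataFrame(
            {"coef": self.coef_, "se": self.se_,
             "z": self.zvalues_, "p": self.pvalues_},
            index=self.feature_names_in_,
        )


class CoxFrailty(BaseEstimator):
    """Mixed-effects Cox model with a Gaussian per-group random intercept.

    Parameters
    ----------
    ties : 'efron' (default) or 'breslow'.
    sigma2 : float or None
        If None (default), the frailty variance is estimated by maximizing
        the Laplace-approximate integrated partial likelihood over
        ``sigma2_bounds``.  A fixed value (including 0) skips the outer
        search; ``sigma2=0`` reduces exactly to :class:`CoxPH`.
    sigma2_bounds : (low, high) search interval for the variance.
    inner_tol : penalized Newton-Raphson convergence tolerance.
    outer_tol : absolute tolerance of the bounded search over sigma2.

    Attributes (after fit)
    ----------------------
    coef_, se_, zvalues_, pvalues_ : fixed-effect estimates and Wald tests.
    frailty_variance_ : estimated (or fixed) variance of the Gaussian
        random intercept on the log-hazard scale.
    random_effects_ : pd.Series of predicted per-group effects (the posterior
        modes), indexed by group label.
    log_likelihood_ : integrated (Laplace) log partial likelihood.
    null_log_likelihood_ : partial log-likelihood at a zero linear predictor.
    aic_ : -2 * log_likelihood_ + 2 * df_model_ where df_model_ counts the
        fixed effects plus one for an *estimated* frailty variance.
    boundary_ : True when the variance was driven to the lower bound and
        reported as 0.
    """

    def __init__(self, ties: str = "efron", sigma2=None,
                 sigma2_bounds=(0.0, 10.0), inner_tol: float = 1e-8,
                 outer_tol: float = 1e-4, max_iter: int = 100):
        self.ties = ties
        self.sigma2 = sigma2
        self.sigma2_bounds = sigma2_bounds
        self.inner_tol = inner_tol
        self.outer_tol = outer_tol
        self.max_iter = max_iter

    # -- internal ----------------------------------------------------------

    def _inner(self, pl, p, q, s2, names, beta0=None):
        pen = np.zeros(p + q)
        if q:
            pen[p:] = 1.0 / s2 if s2 > 0 else np.inf
        res = newton_raphson(pl, penalty_diag=pen, beta0=beta0,
                             tol=self.inner_tol, max_iter=self.max_iter,
                             column_names=names)
        return res, pen

    @staticmethod
    def _ill(res, p, q, s2):
        b = res["beta"][p:]
        Ibb = res["info"][p:, p:]
        _, ld = np.linalg.slogdet(np.eye(q) + s2 * Ibb)
        return res["loglik"] - float(b @ b) / (2.0 * s2) - 0.5 * ld

    def fit(self, X, y, groups=None):
        times, events = _check_y(y)
        n = times.shape[0]
        Z, names = _check_X(X, n=n)
        p = Z.shape[1]
        if groups is None:
            raise ValueError("groups (e.g. line_id per record) is required")
        groups = np.asarray(groups)
        if groups.shape[0] != n:
            raise ValueError("groups length mismatch")
        levels, gidx = np.unique(groups, return_inverse=True)
        q = levels.shape[0]
        G = np.zeros((n, q))
        G[np.arange(n), gidx] = 1.0
        design = np.hstack([Z, G])
        all_names = names + [f"frailty[{lv}]" for lv in levels]
        pl = PartialLikelihood(times, events, design, ties=self.ties)

        estimated = self.sigma2 is None
        state = {"beta": None}

        def neg_ill(s2):
            res, _ = self._inner(pl, p, q, s2, all_names, beta0=state["beta"])
            state["beta"] = res["beta"]
            state["res"] = res
            return -self._ill(res, p, q, s2)

        boundary = False
        if estimated:
            lo, hi = self.sigma2_bounds
            lo_eff = max(lo, 1e-6)
            opt = optimize.minimize_scalar(
                neg_ill, bounds=(lo_eff, hi), method="bounded",
                options={"xatol": self.outer_tol})
            s2_hat = float(opt.x)
            ill_hat = -float(opt.fun)
            # compare against the sigma2 = 0 limit (plain fixed-effects fit)
            if p:
                res0 = newton_raphson(
                    PartialLikelihood(times, events, Z, ties=self.ties),
                    tol=self.inner_tol, max_iter=self.max_iter,
                    column_names=names)
                ill0 = res0["loglik"]
            else:
                # null model limit: eta = 0 everywhere
                ill0 = PartialLikelihood(times, events, np.zeros((n, 1)),
                                         ties=self.ties).loglik(np.zeros(1))
            at_lower = s2_hat - lo_eff <= 2.0 * self.outer_tol
            if ill0 >= ill_hat - 1e-8 or (at_lower and ill0 >= ill_hat - 1e-4):
                s2_hat, boundary = 0.0, True
                if at_lower:
                    warnings.warn("frailty variance driven to the lower bound; "
                                  "reporting 0", RuntimeWarning)
        else:
            s2_hat = float(self.sigma2)

        if s2_hat == 0.0:
            # exact fixed-effects limit
            if p:
                res = newton_raphson(pl_fixed := PartialLikelihood(
                    times, events, Z, ties=self.ties),
                    tol=self.inner_tol, max_iter=self.max_iter,
                    column_names=names)
                cov = np.linalg.inv(res["info"])
                self.coef_ = res["beta"]
                self.covariance_ = cov
                self.log_likelihood_ = res["loglik"]
                self.converged_ = res["converged"]
                null_ll = pl_fixed.loglik(np.zeros(p))
            else:
                self.coef_ = np.zeros(0)
                self.covariance_ = np.zeros((0, 0))
                self.log_likelihood_ = PartialLikelihood(
                    times, events, np.zeros((n, 1)),
                    ties=self.ties).loglik(np.zeros(1))
                self.converged_ = True
                null_ll = self.log_likelihood_
            b_hat = np.zeros(q)
        else:
            res, pen = self._inner(pl, p, q, s2_hat, all_names,
                                   beta0=state.get("beta"))
            H = res["info"] + np.diag(pen)
            cov_full = np.linalg.inv(H)
            cov = cov_full[:p, :p]
            self.coef_ = res["beta"][:p]
            self.covariance_ = cov
            self.log_likelihood_ = self._ill(res, p, q, s2_hat)
            self.converged_ = res["converged"]
            b_hat = res["beta"][p:]
            null_ll = pl.loglik(np.zeros(p + q))

        self.se_ = np.sqrt(np.diag(self.covariance_)) if p else np.zeros(0)
        with np.errstate(divide="ignore", invalid="ignore"):
            self.zvalues_ = np.where(self.se_ > 0, self.coef_ / self.se_, np.nan)
        self.pvalues_ = 2.0 * stats.norm.sf(np.abs(self.zvalues_))
        self.frailty_variance_ = s2_hat
        self.boundary_ = boundary
        self.random_effects_ = pd.Series(b_hat, index=pd.Index(levels, name="group"),
                                         name="random_intercept")
        self.null_log_likelihood_ = null_ll
        self.df_model_ = p + (1 if estimated else 0)
        self.aic_ = -2.0 * self.log_likelihood_ + 2.0 * self.df_model_
        self.feature_names_in_ = names
        self.param_names_ = list(names) + (["frailty_variance"] if estimated else [])
        self.n_ = n
        self.n_events_ = int(events.sum())
        self._signature = _records_signature(times, events)
        return self

    def summary(self) -> pd.DataFrame:
        """Fixed-effect table (Coef., s.e., z, P); frailty variance is in
        ``frailty_variance_``."""
        return pd.DataFrame(
            {"coef": self.coef_, "se": self.se_,
             "z": self.zvalues_, "p": self.pvalues_},
            index=self.feature_names_in_,
        )


# ---------------------------------------------------------------------------
# DataFrame-level operations

def _build_design(records: pd.DataFrame, covariates: pd.DataFrame | None,
                  covariate_cols):
    """Merge lineage records with a line-keyed covariate table.

    ``covariate_cols`` entries may be plain column names or 'a:b' products
    (interaction terms).
    """
    req = {"line_id", "time", "event"}
    missing = req - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    if covariates is not None:
        if "line_id" not in covariates.columns:
            raise ValueError("covariate table must have a line_id column")
        unknown = set(records["line_id"]) - set(covariates["line_id"])
        if unknown:
            raise ValueError(f"lineages reference unknown lines: {sorted(unknown)[:5]}")
        merged = records.merge(covariates, on="line_id", how="left",
                               validate="many_to_one")
    else:
        merged = records.copy()
    cols = list(covariate_cols) if covariate_cols else []
    X = pd.DataFrame(index=merged.index)
    for c in cols:
        if ":" in c:
            a, b = c.split(":", 1)
            X[c] = merged[a] * merged[b]
        else:
            X[c] = merged[c]
    return merged, X


def _default_cols(covariates: pd.DataFrame):
    if covariates is None:
        return []
    if {"antagonism", "concordance"} <= set(covariates.columns):
        return ["antagonism", "concordance"]
    return [c for c in covariates.columns
            if c != "line_id" and pd.api.types.is_numeric_dtype(covariates[c])]


def fit_cox_ph(records: pd.DataFrame, covariates: pd.DataFrame | None = None,
               covariate_cols=None, ties: str = "efron") -> CoxPH:
    """Standard Cox PH fit of lineage extinction on line-level covariates."""
    if covariate_cols is None:
        covariate_cols = _default_cols(covariates)
    merged, X = _build_design(records, covariates, covariate_cols)
    model = CoxPH(ties=ties)
    return model.fit(X, merged[["time", "event"]])


def fit_cox_frailty(records: pd.DataFrame, covariates: pd.DataFrame | None = None,
                    covariate_cols=None, grouping: str = "line_id",
                    ties: str = "efron", sigma2=None) -> CoxFrailty:
    """Mixed-effects Cox fit with a Gaussian random intercept per ``grouping``.

    Pass ``covariates=None, covariate_cols=[]`` for the null (frailty-only)
    model used to extract per-line extinction-risk intercepts.
    """
    if covariate_cols is None:
        covariate_cols = _default_cols(covariates)
    merged, X = _build_design(records, covariates, covariate_cols)
    model = CoxFrailty(ties=ties, sigma2=sigma2)
    return model.fit(X if len(covariate_cols) else None,
                     merged[["time", "event"]], groups=merged[grouping])


@dataclass
class OutlierScreenResult:
    """Leave-one-out influence screen output.

    Record-level flags use the mean + k*sd rule on the |dfbeta| distribution.
    Because the influence of a whole-line cluster is diluted across its
    records (each leave-one-out refit keeps the line's remaining records),
    the screen also aggregates influence per line: ``line_influence`` ranks
    lines by their mean |dfbeta| normalized by the across-line median, which
    is where a disproportionately influential line stands out.
    ``cluster_lines`` lists lines with a majority of their records flagged.
    """
    deltas: pd.DataFrame          # per-record coefficient deltas + flag
    thresholds: pd.Series         # mean + k*sd of |delta| per coefficient
    flagged: pd.DataFrame = field(default=None)
    by_line: pd.Series = field(default=None)
    line_influence: pd.DataFrame = field(default=None)
    cluster_lines: list = field(default_factory=list)

    def __post_init__(self):
        cols = list(self.thresholds.index)
        flag = np.zeros(len(self.deltas), dtype=bool)
        for c in cols:
            flag |= self.deltas[c].abs() > self.thresholds[c]
        self.deltas = self.deltas.assign(flagged=flag)
        self.flagged = self.deltas[self.deltas["flagged"]]
        self.by_line = (self.flagged.groupby("line_id").size()
                        .sort_values(ascending=False))
        if "line_id" in self.deltas.columns:
            g = self.deltas.groupby("line_id")
            m = g[cols].apply(lambda x: x.abs().mean())
            score = pd.Series(0.0, index=m.index)
            for c in cols:
                med = m[c].median()
                score = np.maximum(score, m[c] / med if med > 0 else m[c])
            info = m.assign(influence_score=score,
                            n_records=g.size(),
                            n_flagged=g["flagged"].sum())
            self.line_influence = info.sort_values("influence_score",
                                                   ascending=False)
            majority = info["n_flagged"] >= 0.5 * info["n_records"]
            self.cluster_lines = list(info.index[majority])


def dfbeta_outlier_screen(records: pd.DataFrame, covariates: pd.DataFrame,
                          covariate_cols=None, k: float = 3.0,
                          ties: str = "efron") -> OutlierScreenResult:
    """Exact leave-one-out influence screen on a standard Cox fit.

    For each record the model is refit without it and the change in each
    coefficient (full-fit minus leave-one-out) recorded.  Records whose
    |delta| exceeds mean + k*sd of the absolute-delta distribution for any
    coefficient are flagged, and flags are tallied per line: a cluster of
    flagged records from one line marks that line as a candidate outlier.
    Refits that fail to converge yield missing deltas and the screen
    continues.
    """
    if covariate_cols is None:
        covariate_cols = _default_cols(covariates)
    merged, X = _build_design(records, covariates, covariate_cols)
    times = merged["time"].to_numpy(float)
    events = merged["event"].to_numpy().astype(bool)
    Xm = X.to_numpy(float)
    full = CoxPH(ties=ties).fit(X, merged[["time", "event"]])
    n = len(merged)
    deltas = np.full((n, Xm.shape[1]), np.nan)
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        keep[i] = False
        try:
            pl = PartialLikelihood(times[keep], events[keep], Xm[keep], ties=ties)
            res = newton_raphson(pl, beta0=full.coef_, tol=1e-8,
                                 column_names=covariate_cols)
            if res["converged"]:
                deltas[i] = full.coef_ - res["beta"]
        except Exception:
            pass  # nonconvergent / degenerate exclusion: delta stays missing
        keep[i] = True
    ddf = pd.DataFrame(deltas, columns=covariate_cols, index=merged.index)
    absd = ddf.abs()
    thresholds = absd.mean() + k * absd.std(ddof=1)
    id_cols = [c for c in ("line_id", "lineage_id") if c in merged.columns]
    out = pd.concat([merged[id_cols], ddf], axis=1)
    return OutlierScreenResult(deltas=out, thresholds=thresholds)


def compare_aic(fit, null_fit) -> float:
    """AIC difference, null minus fitted; positive favors the fitted model."""
    if getattr(fit, "_signature", None) != getattr(null_fit, "_signature", None):
        raise MismatchedDataError("fits were not computed on the same records")
    return float(null_fit.aic_ - fit.aic_)


def lrt(nested_fit, full_fit):
    """Likelihood-ratio test between nested fits.

    Returns (chi_square, df, p).  Nesting is checked on parameter-name sets;
    identical parameter sets give chi2 = 0 treated with p = 1.
    """
    if getattr(nested_fit, "_signature", None) != getattr(full_fit, "_signature", None):
        raise MismatchedDataError("fits were not computed on the same records")
    small = set(nested_fit.param_names_)
    big = set(full_fit.param_names_)
    if not small <= big:
        raise NotNestedError(
            f"parameters {sorted(small - big)} of the nested model are absent "
            "from the full model")
    df = len(big) - len(small)
    chi2 = max(0.0, 2.0 * (full_fit.log_likelihood_ - nested_fit.log_likelihood_))
    if df == 0:
        return 0.0, 0, 1.0
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def extract_line_random_intercepts(null_frailty_fit: CoxFrailty) -> pd.Series:
    """Per-line extinction-risk scores from a null (no-covariate) frailty fit.

    The predicted Gaussian random intercepts are approximately centered on 0;
    positive values mark lines whose lineages went extinct faster than the
    panel average.
    """
    if len(getattr(null_frailty_fit, "coef_", [0])) != 0:
        raise ValueError("expected a null model (no fixed covariates)")
    return null_frailty_fit.random_effects_.copy()
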