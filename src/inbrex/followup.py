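"""Follow-up assay statistics and extreme-line selection.

After the inbreeding experiment, fecundity/fertility assays compare
descendants of the most male-benefit/high-extinction lines against the most
female-benefit/low-extinction lines.  Offspring counts are zero-inflated:
the zero rate is compared between categories with a Pearson chi-square, the
zeros are then excluded and the remaining (approximately normal) counts
analysed with a linear mixed model with crossed/nested random effects (line,
lineage within line, assay date) and fixed effects for category and base
population cohort, the category effect tested by ML likelihood ratio.

Extreme lines are the most-positive and most-negative scorers on the first
principal component of the standardized (antagonism, extinction-risk) pair —
the diagonal of the bivariate relation between sexual antagonism and the
per-line random-intercept extinction risk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateInputError

__all__ = [
    "test_zero_rates",
    "fit_offspring_lmm",
    "select_extreme_lines",
    "OffspringLmmResult",
    "ExtremeLineSelection",
]


def test_zero_rates(records: pd.DataFrame, category_col: str = "category",
                    offspring_col: str = "offspring"):
    """Pearson chi-square (no continuity correction) on zero/nonzero x category.

    Returns (chi_square, df, p).  Raises on an empty margin (a category with
    no records, or no zeros / no nonzeros anywhere): the table is untestable.
    """
    cats = records[category_col]
    zero = records[offspring_col].to_numpy() == 0
    table = pd.crosstab(cats, zero)
    if table.shape != (2, 2) or (table.to_numpy().sum(axis=0) == 0).any() \
            or (table.to_numpy().sum(axis=1) == 0).any():
        raise DegenerateInputError(
            "zero-rate test needs a 2x2 table with all margins > 0; got\n"
            f"{table}")
    chi2, p, df, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    return float(chi2), int(df), float(p)


@dataclass
class OffspringLmmResult:
    """Category test and variance components from the offspring LMM."""
    chi_square: float
    df: int
    p: float
    category_effect: float
    fixed_effects: pd.Series
    variance_components: pd.Series
    dropped_components: list = field(default_factory=list)
    n: int = 0


def _fit_mixedlm(df, fixed_rhs, vc_names, reml=False):
    """ML MixedLM with one trivial grouping and variance components for each
    random factor (single-group trick for crossed random effects).

    Gradient optimizers fail on these likelihoods often enough to corrupt
    likelihood-ratio statistics, so the fit falls back to Powell and keeps
    whichever converged solution has the higher likelihood.
    """
    import statsmodels.formula.api as smf

    if not vc_names:
        # every random component dropped: plain fixed-effects linear model
        res = smf.ols(f"offspring ~ {fixed_rhs}", data=df).fit()
        res.vcomp = np.empty(0)
        return res

    vcf = {name: f"0 + C({name})" for name in vc_names}
    df = df.copy()
    df["_one"] = 1
    # re_formula="0": no random intercept for the artificial single group —
    # it would be confounded with the fixed intercept and destabilize the fit
    model = smf.mixedlm(f"offspring ~ {fixed_rhs}", data=df, groups="_one",
                        re_formula="0", vc_formula=vcf if vcf else None)
    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("lbfgs", "powell"):
            try:
                res = model.fit(reml=reml, method=method, maxiter=300)
            except Exception:
                continue
            if np.isfinite(res.llf) and (best is None or res.llf > best.llf):
                best = res
            # no early exit: gradient fits that report convergence still end
            # at inferior optima often enough to corrupt LRT statistics
    if best is None:
        raise RuntimeError("mixed-model fit failed with every optimizer")
    return best


def fit_offspring_lmm(records: pd.DataFrame,
                      response_col: str = "offspring") -> OffspringLmmResult:
    """Mixed-model test of the category effect on nonzero offspring counts.

    Zeros are excluded first (they are analysed separately by
    :func:`test_zero_rates`).  Model: offspring ~ category + base_cohort with
    random intercepts for line, lineage-within-line and assay date; the
    category effect is a likelihood ratio between ML fits with and without
    category (1 df).  A singular random-effects component (variance estimated
    at ~0) is dropped with a logged warning and the model refit.
    """
    df = records.loc[records[response_col] > 0].copy()
    if df.empty:
        raise DegenerateInputError("no nonzero offspring records")
    if df["category"].nunique() < 2:
        raise DegenerateInputError("need at least 2 category levels")
    df = df.rename(columns={response_col: "offspring"})
    df["offspring"] = df["offspring"].astype(float)
    df["lineage_in_line"] = (df["line_id"].astype(str) + "/"
                             + df["lineage_id"].astype(str))
    vc = [c for c in ("line_id", "lineage_in_line", "assay_date")
          if df[c].nunique() > 1]
    fixed_full = "C(category)"
    if "base_cohort" in df.columns and df["base_cohort"].nunique() > 1:
        fixed_full += " + C(base_cohort)"
    fixed_null = fixed_full.replace("C(category)", "1", 1)

    # Full and null must share one random-effects specification: a variance
    # estimated at the zero boundary is a valid ML solution, so components
    # are dropped only when the fit itself fails, and then from both models.
    dropped = []
    while True:
        try:
            full = _fit_mixedlm(df, fixed_full, vc)
            null = _fit_mixedlm(df, fixed_null, vc)
            break
        except RuntimeError:
            if not vc:
                raise
            worst = vc[-1]
            warnings.warn(f"singular random-effect component {worst!r} dropped",
                          RuntimeWarning)
            dropped.append(worst)
            vc = [c for c in vc if c != worst]
    chi2 = max(0.0, 2.0 * (full.llf - null.llf))
    p = float(stats.chi2.sf(chi2, 1))
    fe = pd.Series(np.asarray(getattr(full, "fe_params", full.params)),
                   index=list(full.model.exog_names), name="estimate")
    cat_terms = [ix for ix in fe.index if ix.startswith("C(category)")]
    cat_effect = float(fe[cat_terms[0]]) if cat_terms else np.nan
    vcomp = pd.Series(full.vcomp, index=vc, dtype=float) if vc else pd.Series(dtype=float)
    vcomp["residual"] = float(full.scale)
    return OffspringLmmResult(
        chi_square=float(chi2), df=1, p=p, category_effect=cat_effect,
        fixed_effects=fe, variance_components=vcomp,
        dropped_components=dropped, n=len(df),
    )


@dataclass
class ExtremeLineSelection:
    """PC1 scores over (antagonism, extinction risk) with the extreme sets."""
    scores: pd.Series             # PC1 score per line, descending
    top: list                     # most-positive (male-benefit/high-extinction)
    bottom: list                  # most-negative (female-benefit/low-extinction)
    loadings: np.ndarray = None


def select_extreme_lines(antagonism: pd.Series, extinction_risk: pd.Series,
                         n_extreme: int = 3) -> ExtremeLineSelection:
    """Rank lines on PC1 of standardized (antagonism, extinction risk).

    Both scores are standardized, the first eigenvector of their 2x2
    correlation matrix taken as PC1 and oriented so that positive PC1
    correlates positively with antagonism; the ``n_extreme`` most-positive
    and most-negative lines are returned.  If one score is constant, PC1
    degenerates to the standardized other score.
    """
    a = pd.Series(antagonism).astype(float)
    e = pd.Series(extinction_risk).astype(float)
    e = e.reindex(a.index)
    if a.isna().any() or e.isna().any():
        raise ValueError("both scores must be available for every line")
    if len(a) < 2 * n_extreme:
        raise DegenerateInputError(
            f"need at least {2 * n_extreme} lines for {n_extreme}+{n_extreme} extremes")
    sa, se = a.std(ddof=1), e.std(ddof=1)
    za = (a - a.mean()) / sa if sa > 0 else a * 0.0
    ze = (e - e.mean()) / se if se > 0 else e * 0.0
    if sa == 0 and se == 0:
        raise DegenerateInputError("both scores are constant")
    if sa == 0 or se == 0:
        scores = za + ze          # the non-degenerate standardized axis
        v = np.array([1.0, 0.0]) if se == 0 else np.array([0.0, 1.0])
    else:
        r = float(np.corrcoef(za, ze)[0, 1])
        C = np.array([[1.0, r], [r, 1.0]])
        evals, evecs = np.linalg.eigh(C)
        v = evecs[:, np.argmax(evals)]
        if v[0] < 0:
            v = -v
        scores = za * v[0] + ze * v[1]
    scores = scores.sort_values(ascending=False)
    scores.name = "pc1_score"
    return ExtremeLineSelection(
        scores=scores,
        top=list(scores.index[:n_extreme]),
        bottom=list(scores.index[-n_extreme:][::-1]),
        loadings=v,
    )
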