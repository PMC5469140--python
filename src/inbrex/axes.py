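"""Derived antagonism/concordance axes from sex-specific line-mean fitness.

Line means of male and female lifetime offspring production are log
transformed and variance-standardized (zero mean, unit sample variance)
within each sex.  The coordinate system is then rotated clockwise by 45 deg,
giving two orthogonal derived axes:

* ``antagonism``  = (male_std - female_std) / sqrt(2) — separates
  male-benefit/female-detriment genotypes (positive side) from
  female-benefit/male-detriment genotypes (negative side);
* ``concordance`` = (male_std + female_std) / sqrt(2) — separates generally
  high-fitness from generally low-fitness genotypes.

The rotation is orthonormal (an isometry), so per-line squared length is
preserved and the inverse map is exact.  The derived axes are *not*
re-standardized by default; pass ``restandardize=True`` to scale each derived
axis back to unit sample variance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import DegenerateInputError, DomainError

_SQRT2 = np.sqrt(2.0)


def standardize_log_fitness(raw: np.ndarray | pd.Series) -> np.ndarray:
    """Natural-log transform then center/scale to sample variance 1 (ddof=1).

    Parameters
    ----------
    raw : array-like of positive fitness means, one entry per line.

    Raises
    ------
    DomainError
        If any value is non-positive (the log transform is undefined).
    DegenerateInputError
        If fewer than 3 lines are given or the log values have zero variance.
    """
    x = np.asarray(raw, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D array of per-line fitness means")
    if x.size < 2:
        raise DegenerateInputError("need at least 2 lines to standardize")
    if not np.all(np.isfinite(x)):
        raise DomainError("fitness means must be finite")
    if np.any(x <= 0):
        raise DomainError("fitness means must be strictly positive for the log transform")
    logx = np.log(x)
    sd = logx.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("zero variance in log fitness; cannot standardize")
    return (logx - logx.mean()) / sd


def rotate_axes(male_std, female_std):
    """Clockwise 45 deg rotation of standardized (male, female) fitness.

    Returns ``(antagonism, concordance)`` where
    ``antagonism = (male - female)/sqrt(2)`` and
    ``concordance = (male + female)/sqrt(2)``.  A line with higher
    standardized male than female fitness gets positive antagonism.
    """
    m = np.asarray(male_std, dtype=float)
    f = np.asarray(female_std, dtype=float)
    return (m - f) / _SQRT2, (m + f) / _SQRT2


def inverse_rotate_axes(antagonism, concordance):
    """Exact inverse of :func:`rotate_axes`."""
    a = np.asarray(antagonism, dtype=float)
    c = np.asarray(concordance, dtype=float)
    return (a + c) / _SQRT2, (c - a) / _SQRT2


class AntagonismConcordance(BaseEstimator, TransformerMixin):
    """Transformer mapping raw (male, female) line-mean fitness to derived axes.

    Parameters
    ----------
    restandardize : bool, default False
        If True, rescale each derived axis to unit sample variance after the
        rotation.  The default keeps the pure rotation, under which the
        coefficient map between the two Cox parameterizations is the exact
        inverse rotation.
    log : bool, default True
        Apply the natural-log transform before standardizing.  Disable only
        for inputs that are already on a log-like scale.

    Attributes
    ----------
    log_mean_ : ndarray of shape (2,)
        Per-sex mean of log fitness (male, female).
    log_sd_ : ndarray of shape (2,)
        Per-sex sample standard deviation (ddof=1) of log fitness.
    derived_sd_ : ndarray of shape (2,)
        Sample SDs of (antagonism, concordance) on the training lines; used
        only when ``restandardize=True``.
    """

    def __init__(self, restandardize: bool = False, log: bool = True):
        self.restandardize = restandardize
        self.log = log

    def _coerce(self, X):
        if isinstance(X, pd.DataFrame):
            cols = [c for c in ("male_fitness", "female_fitness") if c in X.columns]
            if len(cols) == 2:
                X = X[cols].to_numpy(dtype=float)
            else:
                X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("expected n_lines x 2 array of (male, female) fitness")
        return X

    def fit(self, X, y=None):
        X = self._coerce(X)
        if X.shape[0] < 3:
            raise DegenerateInputError("need at least 3 lines")
        if not np.all(np.isfinite(X)):
            raise DomainError("fitness means must be finite")
        if self.log:
            if np.any(X <= 0):
                raise DomainError("fitness means must be strictly positive")
            L = np.log(X)
        else:
            L = X
        sd = L.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise DegenerateInputError("zero variance in at least one sex")
        self.log_mean_ = L.mean(axis=0)
        self.log_sd_ = sd
        S = (L - self.log_mean_) / self.log_sd_
        a, c = rotate_axes(S[:, 0], S[:, 1])
        dsd = np.array([a.std(ddof=1), c.std(ddof=1)])
        if self.restandardize and np.any(dsd == 0):
            raise DegenerateInputError("zero variance on a derived axis; cannot re-standardize")
        self.derived_sd_ = dsd
        self.n_features_in_ = 2
        return self

    def transform(self, X):
        X = self._coerce(X)
        L = np.log(X) if self.log else X
        S = (L - self.log_mean_) / self.log_sd_
        a, c = rotate_axes(S[:, 0], S[:, 1])
        out = np.column_stack([a, c])
        if self.restandardize:
            out = out / self.derived_sd_
        return out

    def standardized(self, X):
        """Per-sex standardized log fitness (the pre-rotation coordinates)."""
        X = self._coerce(X)
        L = np.log(X) if self.log else X
        return (L - self.log_mean_) / self.log_sd_

    def get_feature_names_out(self, input_features=None):
        return np.array(["antagonism", "concordance"])


def derive_axes(table: pd.DataFrame, restandardize: bool = False) -> pd.DataFrame:
    """Full per-line axes table from raw fitness means.

    Parameters
    ----------
    table : DataFrame with columns ``line_id``, ``male_fitness``,
        ``female_fitness`` (raw mean lifetime offspring, strictly positive).
    restandardize : rescale derived axes to unit variance (default False).

    Returns
    -------
    DataFrame with the input columns plus ``male_std``, ``female_std``,
    ``antagonism`` and ``concordance``.
    """
    required = {"line_id", "male_fitness", "female_fitness"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    tf = AntagonismConcordance(restandardize=restandardize).fit(table)
    S = tf.standardized(table)
    D = tf.transform(table)
    out = table.copy()
    out["male_std"] = S[:, 0]
    out["female_std"] = S[:, 1]
    out["antagonism"] = D[:, 0]
    out["concordance"] = D[:, 1]
    return out
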