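"""Extinction expected *without* continued inbreeding.

Two forecasts isolate the purely demographic component of lineage extinction
in a single-pair breeding design, where each generation is parented by one
full-sib pair:

* a Monte-Carlo simulation driven only by female fecundity — a lineage fails
  a generation when its single female leaves fewer than two offspring or
  offspring of only one sex (no pair can be formed);
* a projection of each line's first-generation extinction rate forward,
  either compounded geometrically (default) or linearly.

For a degenerate fecundity of exactly n offspring every generation the
per-generation survival probability is 1 - 2^(1-n) (both sexes present among
n independent fair coin flips, n >= 2), so the G-generation extinction
probability has the closed form 1 - (1 - 2^(1-n))^G, used to validate the
simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, DomainError

__all__ = [
    "ForecastResult",
    "simulate_fecundity_extinction",
    "project_first_generation_extinction",
    "degenerate_extinction_probability",
]


@dataclass
class ForecastResult:
    """Per-line and overall expected extinction proportions.

    ``per_line`` maps line_id -> expected proportion of its lineages extinct
    by the forecast horizon; ``overall`` is the lineage-weighted mean.
    ``by_generation`` (overall cumulative proportion per generation) is
    non-decreasing.
    """
    per_line: pd.Series
    overall: float
    by_generation: pd.Series = None
    generations: int = 10
    n_replicates: int = None
    seed: int = None
    mode: str = "simulation"
    meta: dict = field(default_factory=dict)


def degenerate_extinction_probability(n: int, generations: int) -> float:
    """Closed-form extinction probability for constant brood size ``n``."""
    if n < 0:
        raise DomainError("brood size must be non-negative")
    survive = 0.0 if n < 2 else 1.0 - 2.0 ** (1 - n)
    return 1.0 - survive ** generations


def simulate_fecundity_extinction(fecundity, generations: int = 10,
                                  lineages_per_line: int = 20,
                                  replicates: int = 1000,
                                  sex_ratio: float = 0.5,
                                  seed=None) -> ForecastResult:
    """Monte-Carlo fecundity-only extinction forecast.

    Parameters
    ----------
    fecundity : DataFrame with columns ``line_id`` and ``offspring_count``
        (per-female lifetime offspring samples), or a mapping
        line_id -> array of counts.
    generations : forecast horizon (single-pair matings per generation).
    lineages_per_line : lineages founded per line (weighting only; the
        per-line extinction probability itself is estimated from
        ``replicates`` independent lineage trajectories).
    replicates : Monte-Carlo lineage trajectories per line.
    sex_ratio : probability an offspring is male (default 1/2); exposed for
        sensitivity analysis.
    seed : RNG seed.

    Each generation an offspring count is resampled with replacement from the
    line's fecundity samples and offspring sexes drawn independently; the
    lineage survives iff at least one offspring of each sex emerged.
    Fecundity draws are iid across generations — deliberately excluding any
    inbreeding effect, which is the point of the forecast.
    """
    if generations < 1 or replicates < 1:
        raise ValueError("generations and replicates must be >= 1")
    if not 0.0 < sex_ratio < 1.0:
        raise DomainError("sex_ratio must be in (0, 1)")
    if isinstance(fecundity, pd.DataFrame):
        groups = {k: v["offspring_count"].to_numpy()
                  for k, v in fecundity.groupby("line_id", sort=True)}
    else:
        groups = {k: np.asarray(v) for k, v in fecundity.items()}
    rng = np.random.default_rng(seed)
    per_line = {}
    cum = np.zeros(generations)
    n_lines = len(groups)
    if n_lines == 0:
        raise DegenerateInputError("empty fecundity table")
    for line, samples in groups.items():
        samples = np.asarray(samples, dtype=np.int64)
        if samples.size == 0:
            raise DegenerateInputError(f"no fecundity samples for line {line!r}")
        if np.any(samples < 0):
            raise DomainError("offspring counts must be non-negative")
        counts = rng.choice(samples, size=(replicates, generations), replace=True)
        males = rng.binomial(counts, sex_ratio)
        ok = (counts >= 2) & (males >= 1) & (males < counts)
        alive = np.cumprod(ok, axis=1).astype(bool)
        extinct_by_g = 1.0 - alive.mean(axis=0)          # cumulative, per gen
        per_line[line] = float(extinct_by_g[-1])
        cum += extinct_by_g
    per_line = pd.Series(per_line, name="extinction_proportion").sort_index()
    per_line.index.name = "line_id"
    by_gen = pd.Series(cum / n_lines, index=pd.RangeIndex(1, generations + 1,
                                                          name="generation"))
    return ForecastResult(
        per_line=per_line,
        overall=float(per_line.mean()),
        by_generation=by_gen,
        generations=generations,
        n_replicates=replicates,
        seed=seed,
        mode="simulation",
        meta={"lineages_per_line": lineages_per_line, "sex_ratio": sex_ratio},
    )


def project_first_generation_extinction(per_line_first_gen: pd.DataFrame,
                                        generations: int = 10,
                                        mode: str = "geometric") -> ForecastResult:
    """Project first-generation extinction rates over ``generations``.

    ``per_line_first_gen`` needs columns ``line_id``, ``extinct``, ``total``
    (lineage counts in the first generation).  With p1 = extinct/total:

    * geometric (default): 1 - (1 - p1)^G — the first-generation hazard
      repeated independently each generation;
    * linear: min(1, G * p1).

    The geometric projection never exceeds the linear one.  The overall value
    is the lineage-weighted mean of per-line projections.
    """
    if mode not in ("geometric", "linear"):
        raise ValueError("mode must be 'geometric' or 'linear'")
    if generations < 1:
        raise ValueError("generations must be >= 1")
    df = per_line_first_gen
    req = {"line_id", "extinct", "total"}
    if not req <= set(df.columns):
        raise ValueError(f"need columns {sorted(req)}")
    extinct = df["extinct"].to_numpy(float)
    total = df["total"].to_numpy(float)
    if np.any(total <= 0):
        raise DegenerateInputError("every line needs total > 0 first-generation lineages")
    if np.any(extinct > total) or np.any(extinct < 0):
        raise DomainError("extinct counts must lie in [0, total]")
    p1 = extinct / total
    if mode == "geometric":
        proj = 1.0 - (1.0 - p1) ** generations
    else:
        proj = np.minimum(1.0, generations * p1)
    per_line = pd.Series(proj, index=pd.Index(df["line_id"], name="line_id"),
                         name="extinction_proportion")
    overall = float(np.sum(proj * total) / np.sum(total))
    return ForecastResult(
        per_line=per_line,
        overall=overall,
        by_generation=None,
        generations=generations,
        mode=f"projection-{mode}",
        meta={"compounding": mode},
    )
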