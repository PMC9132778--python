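"""Post-stratification weighting by raking (iterative proportional fitting).

Raking adjusts unit weights so that the weighted marginal distribution of
each calibration variable matches a target margin, cycling over the margins
until all of them agree within tolerance.  Weights are renormalised to sum
to the sample size, so a weight of 1 means "counts as itself".

The calibration variables of the survey are country, World Bank income
level, WHO region, facility level and facility type.  With ~90 country
categories, one-response countries make raking numerically fragile, so
countries with fewer than ``min_country_count`` responses are pooled into a
single category before the country margin is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MarginSpec",
    "WeightedSample",
    "RakingError",
    "rake",
    "margins_from_frame",
    "margins_from_table",
    "pool_sparse_categories",
    "weight_diagnostics",
]

DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 100
POOLED_LABEL = "__pooled__"


class RakingError(RuntimeError):
    """Raking failed structurally or did not converge."""

    def __init__(self, message: str, margin_errors: dict | None = None):
        super().__init__(message)
        self.margin_errors = margin_errors or {}


@dataclass(frozen=True)
class MarginSpec:
    """Target proportions for one calibration variable."""

    variable: str
    targets: dict[str, float]

    def __post_init__(self):
        total = sum(self.targets.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"margin '{self.variable}': target proportions sum to {total!r},"
                " expected 1")
        if any(p < 0 for p in self.targets.values()):
            raise ValueError(f"margin '{self.variable}': negative target proportion")


@dataclass
class WeightedSample:
    """Selected responses with their post-stratification weights."""

    response_ids: pd.Index
    weights: pd.Series  # indexed like the sample, sums to n
    strata: pd.DataFrame
    iterations: int
    max_margin_error: float
    converged: bool
    margin_errors: dict[str, float] = field(default_factory=dict)


def margins_from_frame(frame: pd.DataFrame, variables) -> list[MarginSpec]:
    """Empirical margins of *frame* (e.g. a truth registry) as raking targets."""
    specs = []
    for var in variables:
        props = frame[var].value_counts(normalize=True)
        specs.append(MarginSpec(var, {str(k): float(v) for k, v in props.items()}))
    return specs


def margins_from_table(table: pd.DataFrame) -> list[MarginSpec]:
    """Build MarginSpecs from a long table (variable, category, target_proportion)."""
    specs = []
    for var, grp in table.groupby("variable", sort=True):
        specs.append(MarginSpec(str(var), {
            str(r["category"]): float(r["target_proportion"])
            for _, r in grp.iterrows()}))
    return specs


def pool_sparse_categories(sample: pd.DataFrame, margin: MarginSpec,
                           min_count: int = 2) -> tuple[pd.Series, MarginSpec]:
    """Pool categories observed fewer than *min_count* times into one.

    Returns the recoded sample column and the margin with the pooled
    categories' targets summed.  Target categories never observed at all are
    pooled too (their mass would otherwise be unreachable).
    """
    counts = sample[margin.variable].astype(str).value_counts()
    observed = set(counts.index)
    sparse = {c for c, n in counts.items() if n < min_count}
    # target categories with no observations at all cannot receive weight:
    # drop them and renormalise the remaining targets
    unreachable = {c for c in margin.targets if c not in observed}
    if not sparse and not unreachable:
        return sample[margin.variable].astype(str), margin
    col = sample[margin.variable].astype(str)
    col = col.where(~col.isin(sparse), POOLED_LABEL)
    targets = {c: p for c, p in margin.targets.items()
               if c not in sparse and c not in unreachable}
    pooled_mass = sum(p for c, p in margin.targets.items() if c in sparse)
    if (col == POOLED_LABEL).any():
        targets[POOLED_LABEL] = pooled_mass
    total = sum(targets.values())
    if total <= 0:
        raise RakingError(
            f"margin '{margin.variable}': no positive target mass remains "
            "after dropping unreachable categories")
    targets = {c: p / total for c, p in targets.items()}
    return col, MarginSpec(margin.variable, targets)


def _margin_error(col: pd.Series, w: np.ndarray, targets: dict[str, float]) -> float:
    props = pd.Series(w, index=col.index).groupby(col).sum() / w.sum()
    err = 0.0
    for cat, t in targets.items():
        err = max(err, abs(float(props.get(cat, 0.0)) - t))
    return err


def rake(sample: pd.DataFrame, margins: list[MarginSpec],
         max_iter: int = DEFAULT_MAX_ITER, tol: float = DEFAULT_TOL,
         min_country_count: int = 2,
         initial_weights: np.ndarray | None = None) -> WeightedSample:
    """Iteratively proportional-fit weights to the target margins.

    Parameters
    ----------
    sample
        One row per selected response; must contain every margin variable.
    margins
        Target margins; categories must cover all observed values.
    max_iter, tol
        Stop when the largest absolute margin error drops below *tol*,
        else raise :class:`RakingError` after *max_iter* cycles.
    min_country_count
        Pooling threshold applied to the ``country_code`` margin only.
    initial_weights
        Optional starting weights (e.g. design weights); default uniform.

    Raises
    ------
    RakingError
        On structural infeasibility (observed category with zero target,
        or non-zero target with no observations) or non-convergence; the
        exception carries the last per-margin error vector.
    """
    n = len(sample)
    if n == 0:
        raise RakingError("empty sample")
    cols: dict[str, pd.Series] = {}
    specs: list[MarginSpec] = []
    for m in margins:
        if m.variable not in sample.columns:
            raise RakingError(f"margin variable '{m.variable}' not in sample")
        if m.variable == "country_code" and min_country_count > 1:
            col, m = pool_sparse_categories(sample, m, min_country_count)
        else:
            col = sample[m.variable].astype(str)
        observed = set(col.unique())
        uncovered = observed - set(m.targets)
        if uncovered:
            raise RakingError(
                f"margin '{m.variable}': observed categories {sorted(uncovered)} "
                "missing from targets")
        zero_target = {c for c in observed if m.targets.get(c, 0.0) == 0.0}
        if zero_target:
            raise RakingError(
                f"margin '{m.variable}': categories {sorted(zero_target)} observed "
                "but have zero target (drop those rows or amend the margin)")
        empty_positive = {c for c, t in m.targets.items()
                          if t > 0 and c not in observed}
        if empty_positive:
            raise RakingError(
                f"margin '{m.variable}': categories {sorted(empty_positive)} have "
                "positive target but no observations (structurally infeasible)")
        cols[m.variable] = col.reset_index(drop=True)
        specs.append(m)

    w = (np.ones(n) if initial_weights is None
         else np.asarray(initial_weights, dtype=float).copy())
    if (w <= 0).any() or not np.isfinite(w).all():
        raise RakingError("initial weights must be positive and finite")

    errors: dict[str, float] = {}
    for iteration in range(1, max_iter + 1):
        for m in specs:
            col = cols[m.variable]
            totals = pd.Series(w).groupby(col).sum()
            wsum = w.sum()
            factor = col.map(
                lambda c, t=m.targets, s=totals, W=wsum: t[c] * W / s[c]
            ).to_numpy(float)
            w = w * factor
        errors = {m.variable: _margin_error(cols[m.variable], w, m.targets)
                  for m in specs}
        max_err = max(errors.values())
        if max_err < tol:
            w = w * (n / w.sum())
            return WeightedSample(
                response_ids=sample.index,
                weights=pd.Series(w, index=sample.index, name="weight"),
                strata=sample[[m.variable for m in margins]].copy(),
                iterations=iteration, max_margin_error=max_err,
                converged=True, margin_errors=errors)
    raise RakingError(
        f"raking did not converge in {max_iter} iterations "
        f"(max margin error {max(errors.values()):.3g})", errors)


def weight_diagnostics(weights: pd.Series | np.ndarray) -> dict:
    """Effective sample size, coefficient of variation and weight range.

    ``n_eff = (sum w)^2 / sum w^2`` — the equal-weight sample size with the
    same variance; always at most n.
    """
    w = np.asarray(weights, dtype=float)
    s, s2 = w.sum(), (w ** 2).sum()
    return {
        "n": int(w.size),
        "n_eff": float(s ** 2 / s2),
        "cv": float(w.std(ddof=0) / w.mean()),
        "min_weight": float(w.min()),
        "max_weight": float(w.max()),
    }
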