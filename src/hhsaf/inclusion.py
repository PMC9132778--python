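"""Selection steps 1 and 3: element completeness and the per-capita ventile.

Step 1 keeps every response that fully completed at least one element of the
instrument.  Step 3 improves representativeness: for each responding country
the ratio of unique responses per 100 000 inhabitants is computed, and all
responses from countries whose ratio falls in the lowest ventile (5%) of the
*response-level* ratio distribution are excluded — whole countries only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "apply_step1",
    "compute_ratios",
    "ventile_cutoff",
    "apply_step3",
]

PER_CAPITA_BASE = 100_000


def apply_step1(responses: pd.DataFrame, scores: pd.DataFrame) -> pd.DataFrame:
    """Retain responses with at least one fully completed element."""
    complete_cols = [c for c in scores.columns if c.startswith("complete_")]
    keep = scores[complete_cols].any(axis=1)
    return responses.loc[keep.values].copy()


def compute_ratios(unique_responses: pd.DataFrame,
                   country_table: pd.DataFrame) -> pd.DataFrame:
    """Responses per 100 000 inhabitants for every responding country.

    Countries with a missing or non-positive population are flagged
    (``ratio`` NaN) and take no part in the ventile ranking.
    """
    counts = (unique_responses.groupby("country_code").size()
              .rename("n_responses").reset_index())
    pop = country_table.set_index("country_code")["population"]
    counts["population"] = counts["country_code"].map(pop)
    ok = counts["population"].notna() & (counts["population"] > 0)
    counts["ratio"] = np.where(
        ok, counts["n_responses"] / counts["population"] * PER_CAPITA_BASE, np.nan)
    return counts


def ventile_cutoff(unique_responses: pd.DataFrame, ratios: pd.DataFrame,
                   fraction: float = 0.05) -> float:
    """Lower empirical quantile of the response-level ratio distribution.

    Every response carries its country's ratio; the cutoff is the sorted
    value at index ``ceil(fraction * n) - 1`` (lower empirical quantile).
    """
    if ratios.empty:
        raise ValueError("no country ratios available")
    if not 0 < fraction < 0.5:
        raise ValueError("ventile fraction must lie in (0, 0.5)")
    ratio_map = ratios.set_index("country_code")["ratio"]
    per_response = unique_responses["country_code"].map(ratio_map).dropna()
    values = np.sort(per_response.to_numpy(float))
    k = max(math.ceil(fraction * len(values)) - 1, 0)
    return float(values[k])


@dataclass(frozen=True)
class Step3Result:
    retained: pd.DataFrame
    excluded_countries: pd.DataFrame  # country_code, n_responses, ratio


def apply_step3(unique_responses: pd.DataFrame, ratios: pd.DataFrame,
                cutoff: float) -> Step3Result:
    """Exclude whole countries with ratio strictly below the cutoff.

    Ties at the cutoff are retained, keeping the excluded share at or below
    the ventile fraction.  Countries without a computable ratio are retained
    (they never enter the ranking).
    """
    below = ratios[ratios["ratio"] < cutoff]
    excluded_codes = set(below["country_code"])
    mask = unique_responses["country_code"].isin(excluded_codes)
    excluded_table = (below[["country_code", "n_responses", "ratio"]]
                      .sort_values("ratio").reset_index(drop=True))
    return Step3Result(retained=unique_responses.loc[~mask].copy(),
                       excluded_countries=excluded_table)
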