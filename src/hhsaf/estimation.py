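"""Weighted estimation: descriptive summaries, score drivers, wave change.

Four estimators live here.

* Weighted quantiles — the reported medians and IQRs are weighted; the
  convention is the cumulative-weight step function: the quantile at q is
  the smallest value whose cumulative normalised weight reaches q, with the
  midpoint of the straddling values when the cumulative weight hits q
  exactly.  With equal weights this reduces to the ordinary sample quantile
  of the same convention.

* A weighted generalised estimating equation (GEE) with identity link and
  cluster-robust (sandwich) standard errors quantifies drivers of the total
  score; countries are the clusters and post-stratification weights enter
  the estimating equations.  Reference categories: high income, Africa, no
  national coordination, primary level, public funding.

* A Box-Cox profile log-likelihood over lambda in [-2, 2] checks the
  adequacy of the linear (untransformed, lambda = 1) specification.

* The paired wave comparison reports the median of within-facility score
  differences (not the difference of medians) with a two-sided Wilcoxon
  signed-rank test: zero differences are dropped, midranks handle ties, the
  null distribution is exact (dynamic programming) up to n = 25 pairs and a
  normal approximation with continuity correction beyond.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import FACILITY_LEVELS, FACILITY_TYPES, INCOME_LEVELS, WHO_REGIONS
from .instrument import ELEMENT_IDS, LEVELS

__all__ = [
    "weighted_quantile",
    "summarise",
    "level_distribution",
    "fit_gee",
    "GeeResult",
    "boxcox_check",
    "BoxCoxResult",
    "signed_rank_test",
    "paired_compare",
]

_TIE_EPS = 1e-12

DEFAULT_COVARIATES = {
    "income_level": ("high", INCOME_LEVELS),
    "who_region": ("africa", WHO_REGIONS),
    "nationally_coordinated": (False, (False, True)),
    "facility_level": ("primary", FACILITY_LEVELS),
    "facility_type": ("public", FACILITY_TYPES),
}


# ---------------------------------------------------------------------------
# weighted quantiles and descriptive summaries

def weighted_quantile(values, weights, q: float) -> float:
    """Quantile of *values* under non-negative *weights* at level q in [0,1]."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0:
        raise ValueError("weighted_quantile of empty input")
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must lie in [0, 1]")
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    order = np.argsort(v, kind="mergesort")
    v, w = v[order], w[order]
    cw = np.cumsum(w) / w.sum()
    if q == 0.0:
        return float(v[0])
    k = int(np.searchsorted(cw, q - _TIE_EPS, side="left"))
    k = min(k, v.size - 1)
    if abs(cw[k] - q) <= _TIE_EPS and k < v.size - 1:
        return float((v[k] + v[k + 1]) / 2.0)
    return float(v[k])


def _wq_triplet(values, weights):
    return (weighted_quantile(values, weights, 0.25),
            weighted_quantile(values, weights, 0.5),
            weighted_quantile(values, weights, 0.75))


def summarise(scores: pd.DataFrame, weights: pd.Series,
              strata_variables: list[str] | None = None,
              meta: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-stratum weighted medians and IQRs, per element and for the total.

    Parameters
    ----------
    scores
        Output of :func:`hhsaf.instrument.score_responses` (aligned index).
    weights
        Post-stratification weights aligned with *scores*.
    strata_variables
        Metadata columns to stratify on (each level is one row); an
        "overall" block is always emitted first.
    meta
        Frame holding the strata variables (aligned index); required when
        *strata_variables* is given.

    Element summaries use every response with that element complete; total
    summaries use complete surveys only.  Empty strata yield rows with n=0
    and missing statistics.
    """
    measures = [(f"score_{el}", el) for el in ELEMENT_IDS] + [
        ("total_score", "total")]

    def rows_for(label_var, label, mask):
        out = []
        for col, name in measures:
            sel = mask & scores[col].notna()
            vals = scores.loc[sel, col].astype(float)
            w = weights.loc[sel.index[sel]]
            if len(vals) == 0:
                out.append({"stratum_variable": label_var, "stratum": label,
                            "measure": name, "n": 0, "nw": 0.0,
                            "q25": np.nan, "median": np.nan, "q75": np.nan})
                continue
            q25, med, q75 = _wq_triplet(vals.to_numpy(), w.to_numpy())
            out.append({"stratum_variable": label_var, "stratum": label,
                        "measure": name, "n": int(len(vals)),
                        "nw": float(w.sum()),
                        "q25": q25, "median": med, "q75": q75})
        return out

    all_mask = pd.Series(True, index=scores.index)
    rows = rows_for("overall", "overall", all_mask)
    for var in (strata_variables or []):
        if meta is None:
            raise ValueError("strata_variables given but no metadata frame")
        for level in pd.unique(meta[var].dropna()):
            rows += rows_for(var, str(level), meta[var] == level)
    return pd.DataFrame(rows)


def level_distribution(scores: pd.DataFrame, weights: pd.Series) -> pd.DataFrame:
    """Weighted counts (nw) and proportions of the four implementation levels.

    Complete surveys only.  Weighted counts are rounded to integers with
    round-half-even; proportions are computed on the unrounded weights and
    sum to 1.
    """
    complete = scores["total_score"].notna()
    lv = scores.loc[complete, "level"]
    w = weights.loc[lv.index]
    total_w = float(w.sum())
    rows = []
    for level in LEVELS:
        wsum = float(w[lv == level].sum())
        rows.append({
            "level": level,
            "n": int((lv == level).sum()),
            "nw": int(np.round(wsum)),  # round-half-even
            "proportion": wsum / total_w if total_w > 0 else np.nan,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# GEE drivers model

@dataclass
class GeeResult:
    """Coefficient table of the weighted cluster-robust GEE."""

    table: pd.DataFrame  # term, estimate, ci_low, ci_high, p_value
    references: dict[str, str]
    cluster_variable: str
    n_used: int
    n_clusters: int
    cov_struct: str
    cov_type: str = "bias_reduced"


def _build_design(data: pd.DataFrame, covariates: dict) -> tuple[pd.DataFrame, dict]:
    X = pd.DataFrame(index=data.index)
    X["intercept"] = 1.0
    refs = {}
    for var, (ref, categories) in covariates.items():
        refs[var] = str(ref)
        col = data[var]
        observed = list(pd.unique(col.dropna()))
        cats = [c for c in categories if c in observed or c == ref]
        for cat in cats:
            if cat == ref:
                continue
            X[f"{var}[{cat}]"] = (col == cat).astype(float)
    return X, refs


def fit_gee(data: pd.DataFrame, outcome: str = "total_score",
            covariates: dict | None = None, cluster: str = "country_code",
            weights: pd.Series | None = None,
            cov_struct: str = "exchangeable",
            cov_type: str = "bias_reduced") -> GeeResult:
    """Weighted GEE for the total score with cluster-robust errors.

    Parameters
    ----------
    data
        Complete surveys with the outcome, covariates and cluster variable.
    covariates
        Map ``variable -> (reference_category, ordered_categories)``;
        defaults to income level (ref high), WHO region (ref Africa),
        national coordination (ref no), facility level (ref primary) and
        facility type (ref public).
    weights
        Post-stratification weights entering the estimating equations;
        uniform when omitted.
    cov_struct
        ``"exchangeable"`` (default) or ``"independence"`` working
        correlation; the sandwich covariance is robust to either choice.
    cov_type
        Sandwich flavour: ``"bias_reduced"`` (Mancl-DeRouen small-sample
        correction; default — with ~90 country clusters the uncorrected
        sandwich is anti-conservative for country-level covariates) or
        ``"robust"``.  The bias-reduced form is only defined for unweighted
        estimating equations; when *weights* are supplied the fit falls back
        to the plain robust sandwich and reports that in ``cov_type``.

    Raises
    ------
    ValueError
        For a singular design (listing the aliased terms) or fewer than two
        clusters.
    """
    covariates = covariates or DEFAULT_COVARIATES
    work = data.dropna(subset=[outcome, cluster, *covariates]).copy()
    y = work[outcome].astype(float)
    X, refs = _build_design(work, covariates)
    groups = work[cluster].astype(str)
    if groups.nunique() < 2:
        raise ValueError("GEE requires at least two clusters")

    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        aliased = []
        keep: list[str] = []
        for c in X.columns:
            trial = X[keep + [c]].to_numpy()
            if np.linalg.matrix_rank(trial) == len(keep) + 1:
                keep.append(c)
            else:
                aliased.append(c)
        raise ValueError(f"singular design; aliased terms: {aliased}")

    w = (None if weights is None
         else np.asarray(weights.loc[work.index], dtype=float))
    if w is not None and cov_type == "bias_reduced":
        cov_type = "robust"  # bias-reduced sandwich undefined with weights
    cs = {"exchangeable": sm.cov_struct.Exchangeable,
          "independence": sm.cov_struct.Independence}[cov_struct]()
    model = sm.GEE(y, X, groups=groups, weights=w,
                   family=sm.families.Gaussian(), cov_struct=cs)
    res = model.fit(maxiter=100, cov_type=cov_type)
    from scipy.stats import norm
    est = np.asarray(res.params)
    se = np.asarray(res.standard_errors(cov_type=cov_type))
    z975 = norm.ppf(0.975)
    with np.errstate(divide="ignore", invalid="ignore"):
        pvals = 2.0 * norm.sf(np.abs(est / se))
    table = pd.DataFrame({
        "term": X.columns,
        "estimate": est,
        "ci_low": est - z975 * se,
        "ci_high": est + z975 * se,
        "p_value": pvals,
    })
    table = table[table["term"] != "intercept"].reset_index(drop=True)
    return GeeResult(table=table, references=refs, cluster_variable=cluster,
                     n_used=int(len(work)), n_clusters=int(groups.nunique()),
                     cov_struct=cov_struct, cov_type=cov_type)


# ---------------------------------------------------------------------------
# Box-Cox adequacy check

@dataclass
class BoxCoxResult:
    lambda_hat: float
    ci_low: float
    ci_high: float
    adequate: bool  # lambda = 1 inside the 95% profile-likelihood interval
    shift: float
    grid: np.ndarray
    loglik: np.ndarray


def boxcox_check(y, X=None, grid_step: float = 0.01) -> BoxCoxResult:
    """Profile the Box-Cox transform of a linear model over lambda in [-2, 2].

    For each lambda the outcome is transformed, the linear model refitted by
    least squares, and the profile log-likelihood (including the Jacobian
    term) evaluated; the 95% interval keeps every lambda within 1.92
    log-likelihood units of the maximum.  Non-positive outcomes are shifted
    by ``1 - min(y)`` first; the shift is reported.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    shift = 0.0
    if y.min() <= 0:
        shift = 1.0 - y.min()
        y = y + shift
    if X is None:
        X = np.ones((n, 1))
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if not np.any(np.ptp(X, axis=0) == 0):  # ensure an intercept column
            X = np.column_stack([np.ones(n), X])
    log_y = np.log(y)
    sum_log = log_y.sum()
    grid = np.arange(-2.0, 2.0 + grid_step / 2, grid_step)
    ll = np.empty_like(grid)
    for i, lam in enumerate(grid):
        z = log_y if abs(lam) < 1e-12 else (np.power(y, lam) - 1.0) / lam
        beta, *_ = np.linalg.lstsq(X, z, rcond=None)
        rss = float(np.sum((z - X @ beta) ** 2))
        ll[i] = -0.5 * n * np.log(rss / n) + (lam - 1.0) * sum_log
    i_max = int(np.argmax(ll))
    cut = ll[i_max] - 1.9207  # chi2(1, 0.95) / 2
    inside = grid[ll >= cut]
    return BoxCoxResult(
        lambda_hat=float(grid[i_max]),
        ci_low=float(inside.min()), ci_high=float(inside.max()),
        adequate=bool(inside.min() <= 1.0 <= inside.max()),
        shift=shift, grid=grid, loglik=ll)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank and the paired wave comparison

def _exact_signed_rank_p(ranks: np.ndarray, w_obs: float) -> float:
    """Exact two-sided p for the signed-rank statistic with midranks.

    Doubling the (possibly half-integer) midranks gives integers, so the
    null distribution of 2*W+ is enumerated by dynamic programming over all
    2^n sign assignments; the distribution is symmetric about its mean.
    """
    r2 = np.round(ranks * 2).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    counts /= counts.sum()
    support = np.arange(total + 1)
    mean = total / 2.0
    dev = abs(2.0 * w_obs - mean)
    return float(counts[np.abs(support - mean) >= dev - 1e-9].sum())


def signed_rank_test(differences, exact_max_n: int = 25) -> dict:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (classical procedure); ties among absolute
    differences receive midranks.  Exact DP null for up to *exact_max_n*
    non-zero pairs, normal approximation with continuity correction and tie
    variance beyond.  Returns ``statistic`` (W+, sum of positive ranks),
    ``p_value`` (NaN when no non-zero differences remain) and ``n_nonzero``.
    """
    d = np.asarray(differences, dtype=float)
    d = d[~np.isnan(d)]
    d = d[d != 0]
    n = d.size
    if n == 0:
        return {"statistic": np.nan, "p_value": np.nan, "n_nonzero": 0}
    from scipy.stats import rankdata, norm
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        p = _exact_signed_rank_p(ranks, w_plus)
    else:
        mean = ranks.sum() / 2.0
        var = float((ranks ** 2).sum()) / 4.0
        dev = abs(w_plus - mean)
        z = max(dev - 0.5, 0.0) / np.sqrt(var)
        p = float(min(1.0, 2.0 * norm.sf(z)))
    return {"statistic": w_plus, "p_value": p, "n_nonzero": int(n)}


def paired_compare(pairs: pd.DataFrame, strata: list[str] | None = None) -> pd.DataFrame:
    """Compare paired facility scores between two survey waves.

    *pairs* has one row per facility with ``total_1`` and ``total_2`` (the
    earlier and later wave) and optional stratum columns.  Reports, overall
    and per stratum level: n, the median score of each wave, the median and
    IQR of the *paired differences* (which is not the difference of the
    medians), and the two-sided signed-rank p-value.  Strata with no pairs
    yield missing statistics; when every difference is zero the test is not
    applicable and the p-value is missing.
    """
    work = pairs.copy()
    work["difference"] = work["total_2"].astype(float) - work["total_1"].astype(float)

    def row_for(label_var, label, sub):
        if len(sub) == 0:
            return {"stratum_variable": label_var, "stratum": label, "n": 0,
                    "median_1": np.nan, "median_2": np.nan,
                    "median_diff": np.nan, "diff_q25": np.nan,
                    "diff_q75": np.nan, "p_value": np.nan, "note": "no pairs"}
        d = sub["difference"].to_numpy(float)
        test = signed_rank_test(d)
        note = "" if test["n_nonzero"] > 0 else "all differences zero; test not applicable"
        return {
            "stratum_variable": label_var, "stratum": label, "n": int(len(sub)),
            "median_1": float(np.median(sub["total_1"])),
            "median_2": float(np.median(sub["total_2"])),
            "median_diff": float(np.median(d)),
            "diff_q25": float(np.percentile(d, 25)),
            "diff_q75": float(np.percentile(d, 75)),
            "p_value": test["p_value"],
            "note": note,
        }

    rows = [row_for("overall", "overall", work)]
    for var in (strata or []):
        for level in pd.unique(work[var].dropna()):
            rows.append(row_for(var, str(level), work[work[var] == level]))
    return pd.DataFrame(rows)
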