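"""End-to-end orchestration: score -> step 1 -> dedup -> step 3 -> rake ->
estimate (-> wave comparison), with a run manifest for reproducibility.

The manifest records the record count at every selection stage (mirroring
the survey's selection flowchart), the excluded-country table, the raking
convergence report, the software version and the seed, so that a rerun with
the same configuration is verifiably identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .dedup import (DEFAULT_NAME_THRESHOLD, DEFAULT_RADIUS_KM,
                    cluster_responses, clusters_to_frame, match_waves)
from .estimation import (boxcox_check, fit_gee, level_distribution,
                         paired_compare, summarise)
from .inclusion import apply_step1, apply_step3, compute_ratios, ventile_cutoff
from .instrument import bundled_instrument, load_instrument, score_responses
from .io import read_country_table, read_margins, read_responses
from .weighting import margins_from_table, rake, weight_diagnostics

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline",
           "member_state_coverage", "WHO_MEMBER_STATES"]

WHO_MEMBER_STATES = 194

DEFAULT_STRATA = ["who_region", "income_level", "nationally_coordinated",
                  "facility_type", "facility_level"]


@dataclass
class PipelineConfig:
    responses_path: str
    country_table_path: str
    margins_path: str | None = None
    instrument_path: str | None = None  # bundled instrument when None
    wave1_responses_path: str | None = None  # enables the wave comparison
    radius_km: float = DEFAULT_RADIUS_KM
    name_threshold: float = DEFAULT_NAME_THRESHOLD
    ventile_fraction: float = 0.05
    raking_tol: float = 1e-6
    raking_max_iter: int = 100
    min_country_count: int = 2
    gee_cov_struct: str = "exchangeable"
    seed: int = 0
    output_dir: str = "hhsaf_output"

    def __post_init__(self):
        if not 0 < self.ventile_fraction < 0.5:
            raise ValueError("ventile_fraction must lie in (0, 0.5)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)


@dataclass
class RunManifest:
    config: dict
    counts: dict = field(default_factory=dict)
    excluded_countries: list = field(default_factory=list)
    raking: dict = field(default_factory=dict)
    weight_summary: dict = field(default_factory=dict)
    member_state_coverage_pct: int | None = None
    version: str = __version__
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True, default=str)


def member_state_coverage(n_countries: int,
                          member_state_count: int = WHO_MEMBER_STATES) -> int:
    """Percentage of WHO Member States represented, to the nearest integer."""
    if member_state_count <= 0:
        raise ValueError("member_state_count must be positive")
    return int(round(100.0 * n_countries / member_state_count))


def _stage(log, name, n_in, n_out):
    if log is not None:
        log(f"[{name}] {n_in} -> {n_out} responses")


def run_pipeline(config: PipelineConfig, log=None) -> RunManifest:
    """Execute all stages and write the output tables and manifest.

    Outputs written under ``config.output_dir``: ``scored.csv`` (responses
    with element/total scores), ``clusters.csv``, ``selected.csv`` (unique
    responses after step 3, with weights), ``excluded_countries.csv``,
    ``summary.csv``, ``levels.csv``, ``gee.csv``, ``boxcox.json``,
    ``wave_comparison.csv`` (when a first-wave file is configured) and
    ``manifest.json``.  Any stage failure aborts with the stage name.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=dict(config.__dict__), seed=config.seed)

    instrument = (bundled_instrument() if config.instrument_path is None
                  else load_instrument(config.instrument_path))
    responses = read_responses(config.responses_path)
    countries = read_country_table(config.country_table_path)
    manifest.counts["raw"] = int(len(responses))

    # stage: scoring
    scores = score_responses(responses, instrument)
    pd.concat([responses, scores], axis=1).to_csv(out / "scored.csv", index=False)

    # stage: step 1 — at least one complete element
    step1 = apply_step1(responses, scores)
    manifest.counts["step1_complete_element"] = int(len(step1))
    _stage(log, "step1", len(responses), len(step1))

    # stage: step 2 — geospatial deduplication
    clusters = cluster_responses(step1, scores.loc[step1.index], instrument,
                                 radius_km=config.radius_km,
                                 name_threshold=config.name_threshold)
    cframe = clusters_to_frame(clusters)
    cframe.to_csv(out / "clusters.csv", index=False)
    rep_ids = {c.representative_id for c in clusters}
    unique = step1[step1["response_id"].astype(str).isin(rep_ids)].copy()
    manifest.counts["step2_unique_facilities"] = int(len(unique))
    _stage(log, "step2", len(step1), len(unique))

    # stage: step 3 — lowest-ventile per-capita exclusion
    ratios = compute_ratios(unique, countries)
    cutoff = ventile_cutoff(unique, ratios, fraction=config.ventile_fraction)
    step3 = apply_step3(unique, ratios, cutoff)
    retained = step3.retained
    manifest.counts["step3_after_ventile"] = int(len(retained))
    manifest.excluded_countries = step3.excluded_countries.to_dict("records")
    step3.excluded_countries.to_csv(out / "excluded_countries.csv", index=False)
    manifest.member_state_coverage_pct = member_state_coverage(
        retained["country_code"].nunique())
    _stage(log, "step3", len(unique), len(retained))

    # stage: raking
    if config.margins_path is not None:
        margins = margins_from_table(read_margins(config.margins_path))
    else:
        margins = margins_from_table(_default_margins(retained))
    weighted = rake(retained, margins, max_iter=config.raking_max_iter,
                    tol=config.raking_tol,
                    min_country_count=config.min_country_count)
    manifest.raking = {"iterations": weighted.iterations,
                       "max_margin_error": weighted.max_margin_error,
                       "converged": weighted.converged}
    manifest.weight_summary = weight_diagnostics(weighted.weights)
    retained = retained.assign(weight=weighted.weights)
    retained.to_csv(out / "selected.csv", index=False)
    _stage(log, "rake", len(retained), len(retained))

    # stage: estimation
    ret_scores = scores.loc[retained.index]
    summary = summarise(ret_scores, weighted.weights,
                        strata_variables=DEFAULT_STRATA, meta=retained)
    summary.to_csv(out / "summary.csv", index=False)
    levels = level_distribution(ret_scores, weighted.weights)
    levels.to_csv(out / "levels.csv", index=False)

    complete = ret_scores["total_score"].notna()
    gee_data = retained.loc[complete.values].copy()
    gee_data["total_score"] = ret_scores.loc[complete, "total_score"].astype(float).values
    gee = fit_gee(gee_data, weights=weighted.weights.loc[gee_data.index],
                  cov_struct=config.gee_cov_struct)
    gee.table.to_csv(out / "gee.csv", index=False)
    bc = boxcox_check(gee_data["total_score"].to_numpy())
    (out / "boxcox.json").write_text(json.dumps({
        "lambda_hat": bc.lambda_hat, "ci_low": bc.ci_low,
        "ci_high": bc.ci_high, "adequate": bc.adequate, "shift": bc.shift}))
    _stage(log, "estimate", len(gee_data), len(gee.table))

    # stage: wave comparison (optional)
    if config.wave1_responses_path is not None:
        _compare_waves(config, instrument, retained, ret_scores, out, log)

    (out / "manifest.json").write_text(manifest.to_json())
    return manifest


def _default_margins(sample: pd.DataFrame) -> pd.DataFrame:
    """Fallback margins equal to the sample's own proportions (unit weights)."""
    rows = []
    for var in ["country_code", "income_level", "who_region",
                "facility_level", "facility_type"]:
        props = sample[var].astype(str).value_counts(normalize=True)
        rows += [{"variable": var, "category": k, "target_proportion": v}
                 for k, v in props.items()]
    return pd.DataFrame(rows)


def _compare_waves(config, instrument, retained2, scores2, out, log):
    wave1 = read_responses(config.wave1_responses_path)
    scores1 = score_responses(wave1, instrument)
    step1_w1 = apply_step1(wave1, scores1)
    clusters1 = cluster_responses(step1_w1, scores1.loc[step1_w1.index],
                                  instrument, radius_km=config.radius_km,
                                  name_threshold=config.name_threshold)
    rep1 = {c.representative_id for c in clusters1}
    unique1 = step1_w1[step1_w1["response_id"].astype(str).isin(rep1)]

    matches = match_waves(unique1, retained2, radius_km=config.radius_km,
                          name_threshold=config.name_threshold)
    s1 = scores1.set_axis(wave1["response_id"].astype(str))["total_score"]
    s2 = scores2.set_axis(retained2["response_id"].astype(str))["total_score"]
    meta2 = retained2.set_index(retained2["response_id"].astype(str))
    pairs = pd.DataFrame({
        "facility_id": matches["response_id_2"],
        "total_1": matches["response_id_1"].map(s1),
        "total_2": matches["response_id_2"].map(s2),
        "income_level": matches["response_id_2"].map(meta2["income_level"]),
        "who_region": matches["response_id_2"].map(meta2["who_region"]),
    }).dropna(subset=["total_1", "total_2"])
    comparison = paired_compare(pairs, strata=["who_region", "income_level"])
    comparison.to_csv(out / "wave_comparison.csv", index=False)
    _stage(log, "compare", len(matches), len(pairs))
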