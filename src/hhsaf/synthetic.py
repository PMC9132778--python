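"""Synthetic survey generator with known ground truth.

The real survey microdata are not shared, so every downstream stage is
exercised on simulated data whose statistical structure mirrors the study:
~90-100 countries spread over the six WHO regions and four World Bank income
levels, a few thousand responses, duplicated submissions per facility with
geographic jitter, ~5% partially completed questionnaires, an income-graded
total-score distribution, and two survey waves sharing a subset of
facilities.

Indicator answers are produced from a latent facility-quality scalar
``f`` in [0, 1]: for each indicator the target points are ``f * max_points``
and the answer is drawn from the two options straddling that target with
probabilities that make the expected points *exactly* equal the target.
Consequently the expected total score of a facility is exactly
``500 * E[f]``, and configured stratum effects (income gradient, private
funding premium, ...) translate linearly into expected total scores — the
property the parameter-recovery tests rely on.  Facility-level noise on
``f`` is a symmetrically truncated Gaussian (truncated at the distance to
the nearer boundary, capped at 3 sd) so that the stratum means stay exact
even near the score ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .instrument import InstrumentSpec, bundled_instrument
from .io import FACILITY_LEVELS, FACILITY_TYPES, INCOME_LEVELS, WHO_REGIONS

__all__ = ["CountryProfile", "GenerationConfig", "SyntheticTruth",
           "generate_dataset", "generate_waves", "generate_countries"]

TOTAL_MAX = 500.0

# Default stratum effects in points, on the scale of the total score.
DEFAULT_INCOME_EFFECTS = {
    "high": 0.0, "upper_middle": -20.0, "lower_middle": -76.0, "low": -138.0}
DEFAULT_TYPE_EFFECTS = {"public": 0.0, "private": 80.0, "other": 62.0}
DEFAULT_LEVEL_EFFECTS = {"primary": 0.0, "secondary": -33.0, "tertiary": 0.0,
                         "other": 13.0}

_INCOME_COUNTRY_PROBS = {"low": 0.15, "lower_middle": 0.25,
                         "upper_middle": 0.30, "high": 0.30}
_TYPE_PROBS = {"public": 0.756, "private": 0.206, "other": 0.038}
_LEVEL_PROBS = {"primary": 0.391, "secondary": 0.281, "tertiary": 0.226,
                "other": 0.102}

_NAME_A = ("Saint", "Royal", "Central", "Regional", "National", "District",
           "Community", "University", "Memorial", "General", "Provincial",
           "Metropolitan", "Eastern", "Western", "Northern", "Southern",
           "Riverside", "Lakeside", "Highland", "Valley", "Harbour", "Summit",
           "Unity", "Mercy")
_NAME_B = ("Anna", "Lucia", "Marien", "Gabriel", "Joseph", "Clara", "Helena",
           "Vincent", "Theresa", "Michael", "Agnes", "Benedict", "Cecilia",
           "Dominic", "Elias", "Felix", "Irene", "Jonas", "Katarina", "Leon",
           "Magda", "Noor", "Oscar", "Petra", "Rafael", "Sana", "Tomas",
           "Vera", "Yusuf", "Zara")
_NAME_KIND = ("Hospital", "Clinic", "Medical Centre", "Health Centre")


@dataclass(frozen=True)
class CountryProfile:
    country_code: str
    who_region: str
    income_level: str
    population: int
    n_facilities: int
    participation_rate: float = 1.0
    centre_lat: float = 0.0
    centre_lon: float = 0.0


@dataclass(frozen=True)
class GenerationConfig:
    """Knobs of the generator; defaults emulate the 2019 survey's scale.

    ``baseline_mean`` is the expected total score of the reference stratum
    (high income, public, primary, not nationally coordinated); stratum
    effects shift it additively.  ``score_sd`` is the facility-level spread
    of true scores within a stratum, in points.
    """

    n_countries: int = 96
    n_responses_target: int = 3500
    countries: tuple[CountryProfile, ...] | None = None
    income_effects: dict = field(default_factory=lambda: dict(DEFAULT_INCOME_EFFECTS))
    facility_type_effect: float = 80.0
    facility_type_effects: dict | None = None
    facility_level_effects: dict = field(
        default_factory=lambda: dict(DEFAULT_LEVEL_EFFECTS))
    coordination_effect: float = 0.0
    baseline_mean: float = 380.0
    score_sd: float = 50.0
    duplicate_rate: float = 0.12
    jitter_km: float = 0.2
    partial_rate: float = 0.05
    #: response probability per stratum; 1.0 everywhere by default so the
    #: response set is a census of the registry.  Override (e.g. lower
    #: participation for low-income countries or private facilities) to make
    #: post-stratification weighting do real work.
    participation_by_income: dict = field(
        default_factory=lambda: {k: 1.0 for k in INCOME_LEVELS})
    participation_by_type: dict = field(
        default_factory=lambda: {k: 1.0 for k in FACILITY_TYPES})
    wave_overlap: int = 190
    wave_drift_mean: float = 0.0
    wave_drift_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("duplicate_rate", "partial_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.jitter_km < 0:
            raise ValueError("jitter_km must be non-negative")
        if self.wave_overlap < 0:
            raise ValueError("wave_overlap must be non-negative")

    def type_effects(self) -> dict:
        if self.facility_type_effects is not None:
            return dict(self.facility_type_effects)
        eff = dict(DEFAULT_TYPE_EFFECTS)
        eff["private"] = float(self.facility_type_effect)
        return eff


@dataclass
class SyntheticTruth:
    """Ground truth: unique facilities, their true scores, duplicate map."""

    facilities: pd.DataFrame  # one row per true facility
    duplicate_map: pd.Series  # response_id -> facility_id
    config: GenerationConfig


def generate_countries(config: GenerationConfig, rng: np.random.Generator
                       ) -> list[CountryProfile]:
    """Country registry: region and income mix, populations, facility counts.

    Populations are log-normal (median ~10 M); per-country facility counts
    are log-normal and skewed, independent of population, which naturally
    yields a wide responses-per-capita range with a thin lower ventile, as
    observed in global convenience samples.
    """
    if config.countries is not None:
        return list(config.countries)
    n = config.n_countries
    regions = [WHO_REGIONS[i % len(WHO_REGIONS)] for i in range(n)]
    incomes = rng.choice(list(_INCOME_COUNTRY_PROBS),
                         p=list(_INCOME_COUNTRY_PROBS.values()), size=n)
    pops = np.exp(rng.normal(16.1, 1.4, size=n)).astype(int) + 100_000
    raw = np.exp(rng.normal(0.0, 1.1, size=n))
    # a duplicated facility submits 1 + Geometric(1/2) responses (mean 2 extra)
    counts = np.maximum(1, np.round(raw / raw.sum() * config.n_responses_target
                                    / (1 + 2.0 * config.duplicate_rate))).astype(int)
    lats = rng.uniform(-55, 65, size=n)
    lons = rng.uniform(-175, 175, size=n)
    return [
        CountryProfile(
            country_code=f"C{i:03d}", who_region=regions[i],
            income_level=str(incomes[i]), population=int(pops[i]),
            n_facilities=int(counts[i]), centre_lat=float(lats[i]),
            centre_lon=float(lons[i]))
        for i in range(n)
    ]


def _truncated_noise(rng, mu, sigma):
    """Symmetric truncated-Gaussian noise keeping mu + noise inside [0, 1].

    Truncation is symmetric about zero, so E[mu + noise] = mu exactly.
    """
    mu = np.asarray(mu, dtype=float)
    if sigma <= 0:
        return np.zeros_like(mu)
    c = np.minimum(np.minimum(mu, 1.0 - mu) / sigma, 3.0)
    c = np.maximum(c, 0.0)
    z = rng.normal(size=mu.shape)
    # resample out-of-band draws; a few rounds suffice for c >= 0.3
    for _ in range(64):
        bad = np.abs(z) > c
        if not bad.any():
            break
        z[bad] = rng.normal(size=int(bad.sum()))
    z = np.clip(z, -c, c)
    return z * sigma


def _draw_answers(rng: np.random.Generator, f: np.ndarray,
                  instrument: InstrumentSpec) -> pd.DataFrame:
    """Draw option labels so that E[points | f] = f * max_points per indicator."""
    n = f.size
    answers = {}
    for ind in instrument.indicators:
        labels = [lab for lab, _ in ind.answer_options]
        pts = np.array([p for _, p in ind.answer_options], dtype=float)
        order = np.argsort(pts, kind="mergesort")
        pts, labels = pts[order], [labels[i] for i in order]
        s = np.clip(f, 0.0, 1.0) * pts[-1]
        j = np.clip(np.searchsorted(pts, s, side="right") - 1, 0, pts.size - 2)
        lo, hi = pts[j], pts[j + 1]
        p_up = np.where(hi > lo, (s - lo) / np.where(hi > lo, hi - lo, 1.0), 0.0)
        at_top = s >= pts[-1] - 1e-12
        choose_hi = rng.random(n) < p_up
        idx = np.where(at_top, pts.size - 1, j + choose_hi.astype(int))
        answers[ind.indicator_id] = np.array(labels, dtype=object)[idx]
    return pd.DataFrame(answers)


def _facility_registry(config, countries, rng):
    rows = []
    fid = 0
    for c in countries:
        for _ in range(c.n_facilities):
            lat = float(np.clip(c.centre_lat + rng.normal(0, 1.2), -89.5, 89.5))
            lon = float(((c.centre_lon + rng.normal(0, 1.2)) + 180) % 360 - 180)
            name = (f"{_NAME_A[rng.integers(len(_NAME_A))]} "
                    f"{_NAME_B[rng.integers(len(_NAME_B))]} "
                    f"{_NAME_KIND[rng.integers(len(_NAME_KIND))]}")
            rows.append({
                "facility_id": f"F{fid:05d}",
                "country_code": c.country_code,
                "who_region": c.who_region,
                "income_level": c.income_level,
                "population": c.population,
                "latitude": lat, "longitude": lon,
                "facility_name": name,
            })
            fid += 1
    fac = pd.DataFrame(rows)
    n = len(fac)
    fac["facility_type"] = rng.choice(list(_TYPE_PROBS),
                                      p=list(_TYPE_PROBS.values()), size=n)
    fac["facility_level"] = rng.choice(list(_LEVEL_PROBS),
                                       p=list(_LEVEL_PROBS.values()), size=n)
    coord_countries = {c.country_code for c in countries
                       if rng.random() < 0.35}
    fac["nationally_coordinated"] = fac["country_code"].isin(coord_countries)

    type_eff = config.type_effects()
    level_eff = config.facility_level_effects
    mean_total = (config.baseline_mean
                  + fac["income_level"].map(config.income_effects).astype(float)
                  + fac["facility_type"].map(type_eff).astype(float)
                  + fac["facility_level"].map(level_eff).astype(float)
                  + np.where(fac["nationally_coordinated"],
                             config.coordination_effect, 0.0))
    mu = np.clip(mean_total.to_numpy() / TOTAL_MAX, 0.02, 0.98)
    f = mu + _truncated_noise(rng, mu, config.score_sd / TOTAL_MAX)
    fac["true_quality"] = f
    fac["true_expected_total"] = f * TOTAL_MAX
    return fac


def _jitter_coords(rng, lat, lon, jitter_km, max_factor=2.0):
    """Isotropic Gaussian jitter in km, truncated at max_factor * jitter_km."""
    if jitter_km <= 0:
        return lat, lon
    r = np.abs(rng.normal(0, jitter_km, size=np.shape(lat)))
    r = np.minimum(r, max_factor * jitter_km)
    theta = rng.uniform(0, 2 * np.pi, size=np.shape(lat))
    dlat = (r * np.sin(theta)) / 111.195
    dlon = (r * np.cos(theta)) / (111.195 * np.maximum(
        np.cos(np.radians(lat)), 0.05))
    return lat + dlat, lon + dlon


def _name_variant(rng, name: str) -> str:
    u = rng.random()
    if u < 0.5:
        return name
    if u < 0.7:
        return name.lower()
    if u < 0.85:
        return name + " - Main Campus"
    return name.replace(" Hospital", "").replace(" Clinic", "")


def _responses_for_facilities(fac, config, instrument, rng, wave_label,
                              id_prefix, base_year):
    """Expand the registry into responses (duplicates, jitter, partials)."""
    extra = rng.geometric(0.5, size=len(fac)) * (
        rng.random(len(fac)) < config.duplicate_rate)
    rows = []
    rid = 0
    for pos, (_, f) in enumerate(fac.iterrows()):
        n_resp = 1 + int(extra[pos])
        for k in range(n_resp):
            if k == 0:
                lat, lon = f["latitude"], f["longitude"]
                name = f["facility_name"]
            else:
                lat, lon = _jitter_coords(rng, f["latitude"], f["longitude"],
                                          config.jitter_km)
                lat, lon = float(lat), float(lon)
                name = _name_variant(rng, f["facility_name"])
            day = int(rng.integers(0, 350))
            rows.append({
                "response_id": f"{id_prefix}{rid:05d}",
                "facility_id": f["facility_id"],
                "facility_name": name,
                "country_code": f["country_code"],
                "who_region": f["who_region"],
                "income_level": f["income_level"],
                "facility_type": f["facility_type"],
                "facility_level": f["facility_level"],
                "latitude": float(lat), "longitude": float(lon),
                "submitted_at": (pd.Timestamp(f"{base_year}-01-16")
                                 + pd.Timedelta(days=day)),
                "nationally_coordinated": bool(f["nationally_coordinated"]),
                "wave_label": wave_label,
            })
            rid += 1
    resp = pd.DataFrame(rows)

    f_per_resp = fac.set_index("facility_id").loc[
        resp["facility_id"], "true_quality"].to_numpy()
    answers = _draw_answers(rng, f_per_resp, instrument)
    answers.index = resp.index

    # partially completed surveys: keep 1-4 complete elements, blank the rest
    partial = rng.random(len(resp)) < config.partial_rate
    for i in np.nonzero(partial)[0]:
        n_keep = int(rng.integers(1, 5))
        keep = set(rng.choice([el.element_id for el in instrument.elements],
                              size=n_keep, replace=False))
        for el in instrument.elements:
            if el.element_id not in keep:
                answers.loc[answers.index[i], list(el.indicator_ids)] = np.nan
    return pd.concat([resp, answers], axis=1)


def generate_dataset(config: GenerationConfig,
                     instrument: InstrumentSpec | None = None):
    """Generate one survey wave.

    Returns
    -------
    (responses, countries, truth)
        *responses* in the CSV layout the scoring engine reads (metadata plus
        one option-label column per indicator; the helper ``facility_id``
        column is part of the truth, callers writing survey CSVs should drop
        it); *countries* with code, name, population, region and income;
        *truth* the facility registry and the response -> facility map.
    """
    instrument = instrument or bundled_instrument()
    rng = np.random.default_rng(config.seed)
    countries = generate_countries(config, rng)
    fac = _facility_registry(config, countries, rng)
    p = (fac["income_level"].map(config.participation_by_income).astype(float)
         * fac["facility_type"].map(config.participation_by_type).astype(float))
    fac["responded"] = rng.random(len(fac)) < p
    resp = _responses_for_facilities(fac[fac["responded"]], config, instrument,
                                     rng, wave_label="2019", id_prefix="r",
                                     base_year=2019)
    country_table = pd.DataFrame([{
        "country_code": c.country_code, "name": f"Country {c.country_code}",
        "population": c.population, "who_region": c.who_region,
        "income_level": c.income_level} for c in countries])
    truth = SyntheticTruth(
        facilities=fac,
        duplicate_map=resp.set_index("response_id")["facility_id"],
        config=config)
    return resp, country_table, truth


def generate_waves(config: GenerationConfig,
                   instrument: InstrumentSpec | None = None,
                   n_wave1_facilities: int = 800):
    """Generate two survey waves sharing ``wave_overlap`` facilities.

    Wave 1 (2015) draws ``n_wave1_facilities`` facilities, of which the
    first ``wave_overlap`` also answer in wave 2 (2019) at unchanged true
    locations.  Between waves each shared facility's quality drifts by
    ``Normal(wave_drift_mean, wave_drift_sd)`` points.

    Returns ``(wave1_responses, wave2_responses, countries, truth)``; the
    truth registry flags wave membership per facility.
    """
    instrument = instrument or bundled_instrument()
    rng = np.random.default_rng(config.seed)
    countries = generate_countries(config, rng)
    fac = _facility_registry(config, countries, rng)
    if config.wave_overlap > min(n_wave1_facilities, len(fac)):
        raise ValueError(
            f"wave_overlap={config.wave_overlap} exceeds available facilities")

    order = rng.permutation(len(fac))
    wave1_idx = order[:n_wave1_facilities]
    overlap_idx = wave1_idx[:config.wave_overlap]
    fac = fac.copy()
    fac["in_wave1"] = False
    fac.iloc[wave1_idx, fac.columns.get_loc("in_wave1")] = True
    fac["in_wave2"] = True
    only_w1 = np.setdiff1d(wave1_idx, overlap_idx)
    fac.iloc[only_w1, fac.columns.get_loc("in_wave2")] = False

    fac1 = fac[fac["in_wave1"]].copy()
    resp1 = _responses_for_facilities(fac1, config, instrument, rng,
                                      wave_label="2015", id_prefix="a",
                                      base_year=2015)

    fac2 = fac[fac["in_wave2"]].copy()
    drift_pts = rng.normal(config.wave_drift_mean, config.wave_drift_sd,
                           size=len(fac2)) if config.wave_drift_sd > 0 else \
        np.full(len(fac2), config.wave_drift_mean)
    shared = fac2["in_wave1"].to_numpy()
    fac2["true_quality"] = np.clip(
        fac2["true_quality"] + np.where(shared, drift_pts, 0.0) / TOTAL_MAX,
        0.0, 1.0)
    fac2["true_expected_total"] = fac2["true_quality"] * TOTAL_MAX
    resp2 = _responses_for_facilities(fac2, config, instrument, rng,
                                      wave_label="2019", id_prefix="b",
                                      base_year=2019)

    fac.loc[fac2.index, "true_quality_wave2"] = fac2["true_quality"]
    dup = pd.concat([resp1.set_index("response_id")["facility_id"],
                     resp2.set_index("response_id")["facility_id"]])
    truth = SyntheticTruth(facilities=fac, duplicate_map=dup, config=config)
    country_table = pd.DataFrame([{
        "country_code": c.country_code, "name": f"Country {c.country_code}",
        "population": c.population, "who_region": c.who_region,
        "income_level": c.income_level} for c in countries])
    return resp1, resp2, country_table, truth
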