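"""HHSAF instrument: loading, validation, scoring and level classification.

The Hand Hygiene Self-Assessment Framework (HHSAF) is a facility
self-assessment of hand hygiene programme implementation.  It comprises 27
indicators, each worth 10-50 points at its maximum answer option, grouped
into the five elements of the WHO Multimodal Hand Hygiene Improvement
Strategy (System Change, Training and Education, Evaluation and Feedback,
Reminders in the Workplace, Institutional Safety Climate).  Each element is
worth exactly 100 points, the total 500, and the total maps onto four
implementation levels: inadequate (0-125), basic (126-250), intermediate
(251-375) and advanced (376-500).

An element is scored only when *all* of its indicators are answered;
partially answered elements are reported as missing, never as zero.  The
total score and implementation level exist only for fully complete surveys.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

__all__ = [
    "ELEMENT_IDS",
    "LEVELS",
    "LEVEL_BANDS",
    "IndicatorSpec",
    "ElementSpec",
    "InstrumentSpec",
    "InstrumentValidationError",
    "load_instrument",
    "bundled_instrument",
    "classify_level",
    "is_element_complete",
    "score_response",
    "score_responses",
]

ELEMENT_IDS = (
    "system_change",
    "training_education",
    "evaluation_feedback",
    "reminders_workplace",
    "safety_climate",
)

#: Implementation levels with their closed total-score bands.
LEVEL_BANDS = {
    "inadequate": (0, 125),
    "basic": (126, 250),
    "intermediate": (251, 375),
    "advanced": (376, 500),
}
LEVELS = tuple(LEVEL_BANDS)

N_ELEMENTS = 5
N_INDICATORS = 27
ELEMENT_MAX = 100
TOTAL_MAX = 500
INDICATOR_MAX_RANGE = (10, 50)


class InstrumentValidationError(ValueError):
    """An instrument document violates a structural rule of the HHSAF."""


@dataclass(frozen=True)
class IndicatorSpec:
    """One questionnaire indicator with its ordered answer options."""

    indicator_id: str
    element_id: str
    question_text: str
    answer_options: tuple[tuple[str, int], ...]  # (label, points), ascending

    @property
    def option_points(self) -> dict[str, int]:
        return dict(self.answer_options)

    @property
    def max_points(self) -> int:
        return max(p for _, p in self.answer_options)


@dataclass(frozen=True)
class ElementSpec:
    """One 100-point element grouping several indicators."""

    element_id: str
    indicator_ids: tuple[str, ...]


@dataclass(frozen=True)
class InstrumentSpec:
    """The full instrument: five elements, 27 indicators, 500 points."""

    elements: tuple[ElementSpec, ...]
    indicators: tuple[IndicatorSpec, ...]
    version_label: str
    _by_id: Mapping[str, IndicatorSpec] = field(repr=False, default=None)

    def __post_init__(self):
        object.__setattr__(
            self, "_by_id", {ind.indicator_id: ind for ind in self.indicators}
        )

    def indicator(self, indicator_id: str) -> IndicatorSpec:
        return self._by_id[indicator_id]

    def element(self, element_id: str) -> ElementSpec:
        for el in self.elements:
            if el.element_id == element_id:
                return el
        raise KeyError(element_id)

    @property
    def indicator_ids(self) -> tuple[str, ...]:
        return tuple(ind.indicator_id for ind in self.indicators)

    @property
    def max_total(self) -> int:
        return sum(ind.max_points for ind in self.indicators)


def _validate(elements, indicators, version_label) -> InstrumentSpec:
    if len(elements) != N_ELEMENTS:
        raise InstrumentValidationError(
            f"instrument must define exactly {N_ELEMENTS} elements, "
            f"found {len(elements)}"
        )
    if len(indicators) != N_INDICATORS:
        raise InstrumentValidationError(
            f"instrument must define exactly {N_INDICATORS} indicators, "
            f"found {len(indicators)}"
        )
    ids = [ind.indicator_id for ind in indicators]
    if len(set(ids)) != len(ids):
        raise InstrumentValidationError("duplicate indicator ids")
    if len({el.element_id for el in elements}) != len(elements):
        raise InstrumentValidationError("duplicate element ids")

    by_element: dict[str, list[IndicatorSpec]] = {}
    for ind in indicators:
        lo, hi = INDICATOR_MAX_RANGE
        for label, pts in ind.answer_options:
            if not 0 <= pts <= hi:
                raise InstrumentValidationError(
                    f"indicator {ind.indicator_id}: option '{label}' has "
                    f"points {pts} outside [0, {hi}]"
                )
        if not lo <= ind.max_points <= hi:
            raise InstrumentValidationError(
                f"indicator {ind.indicator_id}: maximum option points "
                f"{ind.max_points} outside [{lo}, {hi}]"
            )
        by_element.setdefault(ind.element_id, []).append(ind)

    for el in elements:
        members = by_element.get(el.element_id, [])
        if tuple(ind.indicator_id for ind in members) != el.indicator_ids:
            raise InstrumentValidationError(
                f"element {el.element_id}: indicator membership inconsistent"
            )
        el_max = sum(ind.max_points for ind in members)
        if el_max != ELEMENT_MAX:
            raise InstrumentValidationError(
                f"element {el.element_id}: maximum points sum to {el_max}, "
                f"expected {ELEMENT_MAX}"
            )
    spec = InstrumentSpec(tuple(elements), tuple(indicators), version_label)
    if spec.max_total != TOTAL_MAX:
        raise InstrumentValidationError(
            f"instrument maximum total is {spec.max_total}, expected {TOTAL_MAX}"
        )
    return spec


def load_instrument(spec_source) -> InstrumentSpec:
    """Load and validate an instrument specification.

    Parameters
    ----------
    spec_source
        Path to a YAML document, or an already-parsed mapping with keys
        ``version_label`` and ``elements`` (each element carrying its
        ``indicators`` with ordered ``options``).

    Returns
    -------
    InstrumentSpec
        Validated instrument; structural violations raise
        :class:`InstrumentValidationError` naming the offending rule.
    """
    if isinstance(spec_source, (str, Path)):
        with open(spec_source, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = spec_source
    if not isinstance(doc, dict) or "elements" not in doc:
        raise InstrumentValidationError("document has no 'elements' section")

    elements: list[ElementSpec] = []
    indicators: list[IndicatorSpec] = []
    for el in doc["elements"]:
        el_id = str(el["element_id"])
        ind_ids = []
        for ind in el.get("indicators", []):
            options = tuple(
                (str(opt["label"]), int(opt["points"])) for opt in ind["options"]
            )
            indicators.append(
                IndicatorSpec(
                    indicator_id=str(ind["indicator_id"]),
                    element_id=el_id,
                    question_text=str(ind.get("question", "")),
                    answer_options=options,
                )
            )
            ind_ids.append(str(ind["indicator_id"]))
        elements.append(ElementSpec(element_id=el_id, indicator_ids=tuple(ind_ids)))
    return _validate(elements, indicators, str(doc.get("version_label", "unversioned")))


def bundled_instrument() -> InstrumentSpec:
    """Load the packaged structural encoding of the 2010 HHSAF tool."""
    ref = resources.files("hhsaf.data").joinpath("hhsaf_structure.yaml")
    with ref.open("r", encoding="utf-8") as fh:
        return load_instrument(yaml.safe_load(fh))


def classify_level(total_score: int) -> str:
    """Map a total score in [0, 500] onto its implementation level."""
    if not 0 <= total_score <= TOTAL_MAX:
        raise ValueError(f"total score {total_score} outside [0, {TOTAL_MAX}]")
    for level, (lo, hi) in LEVEL_BANDS.items():
        if lo <= total_score <= hi:
            return level
    raise AssertionError("level bands do not partition [0, 500]")


def is_element_complete(answers: Mapping[str, str], element: ElementSpec,
                        instrument: InstrumentSpec) -> bool:
    """True iff every indicator of *element* carries a valid answer."""
    for ind_id in element.indicator_ids:
        label = answers.get(ind_id)
        if label is None or label not in instrument.indicator(ind_id).option_points:
            return False
    return True


def score_response(answers: Mapping[str, str], instrument: InstrumentSpec) -> dict:
    """Score one response against the instrument.

    Parameters
    ----------
    answers
        Map ``indicator_id -> option_label``; absent keys are unanswered.
    instrument
        A validated :class:`InstrumentSpec`.

    Returns
    -------
    dict
        ``element_scores`` (element_id -> int or None), ``element_complete``
        (element_id -> bool), ``total_score`` (int or None; present iff all
        five elements are complete) and ``level`` (str or None).

    Raises
    ------
    ValueError
        If an answer references an unknown indicator or option label.
    """
    known = set(instrument.indicator_ids)
    for ind_id, label in answers.items():
        if ind_id not in known:
            raise ValueError(f"unknown indicator id '{ind_id}'")
        if label not in instrument.indicator(ind_id).option_points:
            raise ValueError(
                f"indicator {ind_id}: unknown option label '{label}'"
            )

    element_scores: dict[str, int | None] = {}
    element_complete: dict[str, bool] = {}
    for el in instrument.elements:
        complete = is_element_complete(answers, el, instrument)
        element_complete[el.element_id] = complete
        if complete:
            element_scores[el.element_id] = sum(
                instrument.indicator(i).option_points[answers[i]]
                for i in el.indicator_ids
            )
        else:
            element_scores[el.element_id] = None

    if all(element_complete.values()):
        total = sum(element_scores.values())
        level = classify_level(total)
    else:
        total, level = None, None
    return {
        "element_scores": element_scores,
        "element_complete": element_complete,
        "total_score": total,
        "level": level,
    }


def score_responses(responses: pd.DataFrame, instrument: InstrumentSpec) -> pd.DataFrame:
    """Score a table of responses (one row each, indicator columns hold labels).

    Missing answers are empty/NaN cells.  Returns a frame indexed like the
    input with one ``score_<element>`` and ``complete_<element>`` column per
    element plus ``total_score`` and ``level`` (nullable).
    """
    out = pd.DataFrame(index=responses.index)
    all_complete = pd.Series(True, index=responses.index)
    total = pd.Series(0, index=responses.index, dtype="float64")
    for el in instrument.elements:
        el_score = pd.Series(0, index=responses.index, dtype="float64")
        el_complete = pd.Series(True, index=responses.index)
        for ind_id in el.indicator_ids:
            pts_map = instrument.indicator(ind_id).option_points
            if ind_id in responses.columns:
                col = responses[ind_id]
                answered = col.notna() & (col.astype("string") != "")
                bad = answered & ~col.isin(list(pts_map))
                if bad.any():
                    ridx = responses.index[bad][0]
                    raise ValueError(
                        f"indicator {ind_id}: unknown option label "
                        f"'{responses.loc[ridx, ind_id]}' (row {ridx})"
                    )
                pts = col.map(pts_map)
            else:
                answered = pd.Series(False, index=responses.index)
                pts = pd.Series(float("nan"), index=responses.index)
            el_complete &= answered
            el_score = el_score.add(pts, fill_value=0.0)
        out[f"score_{el.element_id}"] = el_score.where(el_complete).astype("Int64")
        out[f"complete_{el.element_id}"] = el_complete
        all_complete &= el_complete
        total = total.add(el_score.where(el_complete), fill_value=0.0)

    out["total_score"] = total.where(all_complete).astype("Int64")
    out["level"] = out["total_score"].map(
        lambda t: classify_level(int(t)) if pd.notna(t) else pd.NA
    )
    return out
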