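"""Screening strategy configurations.

Two base arms are compared: AI-assisted reading (AI-DM), in which an AI
system triages every exam and only the ~30% of exams with intermediate or
elevated AI scores receive a second human reading, and conventional
double reading (cDM), in which every exam is read by two radiologists.
Four one-way scenario variants of the AI-assisted arm probe alternative
triage thresholds and an outsourced reading cost:

* S1 — double human reading only for the highest AI score decile
  (double-read share 0.10), detection unchanged;
* S2 — single human reading for all exams, detection reduced 3%;
* S3 — no human reading for low scores, single reading for high scores
  (human-read share 0.30), detection reduced 9%;
* S4 — base-case reading policy with all human reading outsourced at a
  unit cost of EUR 4.8 per reading (AI arm only).

Detection multipliers feed back into the interval-cancer derivation: the
total number of cancers is anchored on the conventional arm, so reduced
screen detection surfaces as additional interval cancers.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

from .params import (
    AGE_BANDS,
    CostParams,
    ParameterError,
    ScreeningParams,
    default_cost_params,
    default_screening_params,
    expected_readings_per_exam,
)

__all__ = ["StrategyConfig", "make_base_aidm", "make_base_cdm", "make_scenario",
           "SCENARIO_IDS"]

SCENARIO_IDS = ("S1", "S2", "S3", "S4")


@dataclass(frozen=True)
class StrategyConfig:
    """One screening arm's reading policy, detection risks, and unit costs."""

    name: str
    double_read_share: float
    human_read_share: float
    uses_ai: bool
    detection_multiplier: float
    reading_unit_cost: float
    detection_biennial: Mapping[str, float]  # per age band, per attended screen
    interval_annual: Mapping[str, float]  # per age band, per year
    conference_prop: float
    recall_props: Mapping[str, float]  # per age band, per attended screen
    screening_ages: tuple

    def __post_init__(self) -> None:
        if not 0 <= self.double_read_share <= self.human_read_share <= 1:
            raise ParameterError("need 0 <= double_read_share <= human_read_share <= 1")
        if not 0 < self.detection_multiplier <= 1:
            raise ParameterError("detection multiplier must lie in (0,1]")
        for band in AGE_BANDS:
            if band not in self.detection_biennial or band not in self.interval_annual:
                raise ParameterError(f"missing age band {band}")

    @property
    def human_readings_per_exam(self) -> float:
        """Expected human readings per exam including consensus conferences."""
        return expected_readings_per_exam(
            self.double_read_share, self.conference_prop, self.human_read_share
        )

    def age_band(self, age: int) -> str:
        return "40_54" if age < 55 else "55_74"


def _build(
    name: str,
    arm: str,
    screening: ScreeningParams,
    costs: CostParams,
    *,
    double_read_share: float,
    human_read_share: float,
    uses_ai: bool,
    detection_multiplier: float = 1.0,
    reading_unit_cost: float | None = None,
) -> StrategyConfig:
    base_detect = screening.detection_biennial(arm)
    detect = {b: v * detection_multiplier for b, v in base_detect.items()}
    conf = (
        screening.prop_conference_aidm if arm == "aidm" else screening.prop_conference_cdm
    ).mean
    return StrategyConfig(
        name=name,
        double_read_share=double_read_share,
        human_read_share=human_read_share,
        uses_ai=uses_ai,
        detection_multiplier=detection_multiplier,
        reading_unit_cost=(
            costs.screen_reading_unit if reading_unit_cost is None else reading_unit_cost
        ),
        detection_biennial=detect,
        interval_annual=screening.interval_annual(detect),
        conference_prop=conf,
        recall_props={
            "40_54": screening.prop_recall_40_54.mean,
            "55_74": screening.prop_recall_55_74.mean,
        },
        screening_ages=screening.screening_ages,
    )


def make_base_aidm(
    screening: ScreeningParams | None = None, costs: CostParams | None = None
) -> StrategyConfig:
    """Base-case AI-assisted arm: 30% double reading, AI licence per exam."""
    screening = screening or default_screening_params()
    costs = costs or default_cost_params()
    return _build(
        "AI-DM", "aidm", screening, costs,
        double_read_share=screening.prop_double_read_aidm,
        human_read_share=1.0, uses_ai=True,
    )


def make_base_cdm(
    screening: ScreeningParams | None = None, costs: CostParams | None = None
) -> StrategyConfig:
    """Conventional comparator: universal double human reading, no AI."""
    screening = screening or default_screening_params()
    costs = costs or default_cost_params()
    return _build(
        "cDM", "cdm", screening, costs,
        double_read_share=screening.prop_double_read_cdm,
        human_read_share=1.0, uses_ai=False,
    )


def make_scenario(
    scenario_id: str,
    screening: ScreeningParams | None = None,
    costs: CostParams | None = None,
) -> StrategyConfig:
    """One of the four AI-assisted scenario variants (S1..S4)."""
    screening = screening or default_screening_params()
    costs = costs or default_cost_params()
    sid = scenario_id.upper()
    if sid == "S1":
        # double reading only for the top AI-score decile
        return _build("AI-DM S1", "aidm", screening, costs,
                      double_read_share=0.10, human_read_share=1.0, uses_ai=True)
    if sid == "S2":
        return _build("AI-DM S2", "aidm", screening, costs,
                      double_read_share=0.0, human_read_share=1.0, uses_ai=True,
                      detection_multiplier=0.97)
    if sid == "S3":
        return _build("AI-DM S3", "aidm", screening, costs,
                      double_read_share=0.0, human_read_share=0.30, uses_ai=True,
                      detection_multiplier=0.91)
    if sid == "S4":
        return _build("AI-DM S4", "aidm", screening, costs,
                      double_read_share=screening.prop_double_read_aidm,
                      human_read_share=1.0, uses_ai=True,
                      reading_unit_cost=costs.external_reading_unit)
    raise ParameterError(f"unknown scenario id {scenario_id!r}; expected S1..S4")
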