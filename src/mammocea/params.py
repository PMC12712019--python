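"""Model parameters, sampling distributions, and derivation rules.

The screening programme is parameterised by three groups of inputs:

* screening-related proportions and risks (reading policy, conference and
  recall proportions, biennial cancer-detection risk) with Beta
  distributions where the underlying counts are known;
* unit costs in 2023 EUR, with Gamma distributions for the two costs that
  are themselves derived quantities (screen reading, consensus conference);
* cancer natural-history inputs: stage distributions at detection by mode
  (screen-detected, interval, post-screening) and age band, and annual
  schedules of distant-metastasis risk, breast-cancer death risk, cost and
  quality-of-life decrement indexed by years since the event.

Derivation rules implemented here:

* ``beta_mean`` — point estimate of a Beta-distributed proportion;
* ``derive_age_detection`` — split the overall biennial detection risk into
  age bands with multiplicative factors (0.53 for ages 40-54, 1.40 for
  55-74);
* ``derive_interval_risk`` — interval-cancer risk by subtraction: total
  cancers are the conventional-arm screen detections inflated by the
  interval share, and whatever a strategy does not detect at screen
  surfaces as interval cancer (halved to an annual risk);
* ``reading_unit_cost`` — radiologist hourly cost divided by reading
  throughput.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

__all__ = [
    "ParameterError",
    "DerivationError",
    "BetaParam",
    "GammaParam",
    "ScreeningParams",
    "CostParams",
    "StageDistribution",
    "TunnelSchedule",
    "CancerParams",
    "EconomicSettings",
    "beta_mean",
    "derive_age_detection",
    "derive_interval_risk",
    "reading_unit_cost",
    "expected_readings_per_exam",
    "load_table1",
    "load_table2",
    "default_screening_params",
    "default_cost_params",
    "default_cancer_params",
]

STAGES = ("0", "I", "II", "III", "IV")
AGE_BANDS = ("40_54", "55_74")
MAX_TUNNEL = 9


class ParameterError(ValueError):
    """Invalid parameter value or distribution specification."""


class DerivationError(ValueError):
    """A derivation rule produced a value outside its admissible range."""


@dataclass(frozen=True)
class BetaParam:
    """Beta(alpha, beta) distribution for a proportion."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ParameterError(
                f"Beta shapes must be positive, got ({self.alpha}, {self.beta})"
            )

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @classmethod
    def from_mean_cv(cls, mean: float, cv: float) -> "BetaParam":
        """Method-of-moments Beta for a given mean and coefficient of variation."""
        if not 0 < mean < 1:
            raise ParameterError(f"Beta mean must lie in (0,1), got {mean}")
        if cv <= 0:
            raise ParameterError(f"cv must be positive, got {cv}")
        var = (cv * mean) ** 2
        nu = mean * (1 - mean) / var - 1.0
        if nu <= 0:
            raise ParameterError("variance too large for a Beta distribution")
        return cls(mean * nu, (1 - mean) * nu)


@dataclass(frozen=True)
class GammaParam:
    """Gamma distribution for a cost, specified by mean and SD (EUR).

    ``sd == 0`` denotes a degenerate (fixed) cost.
    """

    mean: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise ParameterError(f"Gamma mean must be positive, got {self.mean}")
        if self.sd < 0:
            raise ParameterError(f"Gamma sd must be non-negative, got {self.sd}")

    @property
    def shape(self) -> float:
        if self.sd == 0:
            raise ParameterError("degenerate Gamma has no shape parameter")
        return (self.mean / self.sd) ** 2

    @property
    def scale(self) -> float:
        return self.sd**2 / self.mean


def beta_mean(p: BetaParam) -> float:
    """Mean alpha/(alpha+beta) of a Beta-distributed proportion."""
    return p.mean


def derive_age_detection(overall: float, factor: float) -> float:
    """Age-band biennial detection risk as ``overall * factor``.

    The overall screen-detection risk is split into the 40-54 band
    (47% lower, factor 0.53) and the 55-74 band (40% higher, factor 1.40).
    """
    if not 0 < overall < 1:
        raise ParameterError(f"overall detection must lie in (0,1), got {overall}")
    if factor <= 0:
        raise ParameterError(f"factor must be positive, got {factor}")
    out = overall * factor
    if not 0 < out < 1:
        raise DerivationError(f"age-band detection {out} outside (0,1)")
    return out


def derive_interval_risk(
    cdm_detect_age: float,
    strat_detect_age: float,
    interval_share: float,
    clamp: bool = False,
) -> float:
    """Annual interval-cancer risk for a strategy, by subtraction.

    Total biennial cancer risk in an age band is the conventional arm's
    screen-detection risk inflated by the interval share
    (``total = cdm / (1 - share)``); the strategy's interval cancers are the
    remainder ``total - strat``, halved to an annual risk. The total is
    anchored on the conventional arm, so a strategy that detects more at
    screen has fewer interval cancers, never more cancers overall.

    With ``clamp`` the risk is floored at zero instead of raising — used in
    probabilistic sampling, where independent detection draws for the two
    arms can transiently imply a negative remainder.
    """
    if not 0 <= interval_share < 1:
        raise ParameterError(f"interval share must lie in [0,1), got {interval_share}")
    total = cdm_detect_age / (1.0 - interval_share)
    biennial = total - strat_detect_age
    if biennial < -1e-12 and not clamp:
        raise DerivationError(
            "strategy detects more cancers than the total implied by the "
            f"conventional arm ({strat_detect_age} > {total})"
        )
    return max(biennial, 0.0) / 2.0


def reading_unit_cost(hourly: float, reads_per_hour: float) -> float:
    """Screen-reading unit cost: hourly radiologist cost / exams per hour.

    Reported to one decimal, matching how the unit cost enters the model.
    """
    if hourly <= 0 or reads_per_hour <= 0:
        raise ParameterError("hourly cost and throughput must be positive")
    return round(hourly / reads_per_hour, 1)


def expected_readings_per_exam(
    double_read_share: float,
    conference_rate: float,
    human_read_share: float = 1.0,
) -> float:
    """Expected human readings per screening exam.

    Singly read exams take one reading, doubly read exams two, and each
    consensus conference consumes two further reader-units.
    """
    for name, v in [
        ("double_read_share", double_read_share),
        ("conference_rate", conference_rate),
        ("human_read_share", human_read_share),
    ]:
        if not 0 <= v <= 1:
            raise ParameterError(f"{name} must lie in [0,1], got {v}")
    single_share = human_read_share - double_read_share
    if single_share < 0:
        raise ParameterError("double_read_share exceeds human_read_share")
    return single_share * 1.0 + double_read_share * 2.0 + conference_rate * 2.0


@dataclass(frozen=True)
class ScreeningParams:
    """Screening proportions and detection risks for both arms.

    Biennial detection risks are per attended screen; interval risks are
    annual. The 55-74 band detection is carried as printed in the source
    table; the 40-54 band follows from the 0.53 multiplier on the overall
    Beta mean.
    """

    prop_double_read_aidm: float = 0.30
    prop_double_read_cdm: float = 1.00
    prop_conference_aidm: BetaParam = BetaParam(1475, 35403)
    prop_conference_cdm: BetaParam = BetaParam(1404, 34590)
    prop_recall_40_54: BetaParam = BetaParam(4541, 125208)
    prop_recall_55_74: BetaParam = BetaParam(2341, 91297)
    detect_biennial_overall_aidm: BetaParam = BetaParam(222, 36169)
    detect_biennial_overall_cdm: BetaParam = BetaParam(203, 39576)
    detect_biennial_55_74_aidm: float = 0.0086
    detect_biennial_55_74_cdm: float = 0.0072
    age_factor_low: float = 0.53
    age_factor_high: float = 1.40
    interval_share: float = 0.295
    screening_ages: tuple = tuple(range(40, 76, 2))

    def __post_init__(self) -> None:
        if not self.age_factor_low < 1 < self.age_factor_high:
            raise ParameterError("age factors must bracket 1")
        if len(self.screening_ages) != 18:
            raise ParameterError("expected 18 biennial screening ages 40..74")
        for f in (
            self.prop_double_read_aidm,
            self.prop_double_read_cdm,
            self.detect_biennial_55_74_aidm,
            self.detect_biennial_55_74_cdm,
            self.interval_share,
        ):
            if not 0 <= f <= 1:
                raise ParameterError(f"fraction outside [0,1]: {f}")

    def detection_biennial(self, arm: str) -> dict:
        """Per-age-band biennial detection risk for ``arm`` ('aidm'|'cdm')."""
        if arm == "aidm":
            overall = self.detect_biennial_overall_aidm.mean
            high = self.detect_biennial_55_74_aidm
        elif arm == "cdm":
            overall = self.detect_biennial_overall_cdm.mean
            high = self.detect_biennial_55_74_cdm
        else:
            raise ParameterError(f"unknown arm {arm!r}")
        return {
            "40_54": derive_age_detection(overall, self.age_factor_low),
            "55_74": high,
        }

    def interval_annual(self, strat_detection: Mapping[str, float]) -> dict:
        """Per-age-band annual interval risk for a strategy's detection risks."""
        ref = self.detection_biennial("cdm")
        return {
            band: derive_interval_risk(
                ref[band], strat_detection[band], self.interval_share
            )
            for band in AGE_BANDS
        }


@dataclass(frozen=True)
class CostParams:
    """Unit costs in 2023 EUR."""

    invitation: float = 0.7
    mammography: float = 30.5
    radiologist_hourly: float = 79.0
    reads_per_hour: float = 29
    screen_reading_sd: float = 0.5
    ai_licence_per_exam: float = 1.9
    conference_unit: float = 5.4
    conference_sd: float = 1.1
    recall_unit: float = 370.8
    external_reading_unit: float = 4.8

    def __post_init__(self) -> None:
        for v in (
            self.invitation,
            self.mammography,
            self.radiologist_hourly,
            self.ai_licence_per_exam,
            self.conference_unit,
            self.recall_unit,
            self.external_reading_unit,
        ):
            if v < 0:
                raise ParameterError(f"costs must be non-negative, got {v}")
        if self.reads_per_hour <= 0:
            raise ParameterError("reads_per_hour must be positive")

    @property
    def screen_reading_unit(self) -> float:
        return reading_unit_cost(self.radiologist_hourly, self.reads_per_hour)


@dataclass(frozen=True)
class StageDistribution:
    """Stage distribution at detection for one mode and age band.

    ``mode`` is 'screening', 'interval' or 'post75'; probabilities cover
    stages 0, I, II, III, IV and are renormalised to sum to exactly one
    (printed tables round to 0.1 percentage points).
    """

    mode: str
    age_band: str
    probs: tuple  # aligned with STAGES

    def __post_init__(self) -> None:
        if len(self.probs) != len(STAGES):
            raise ParameterError("need one probability per stage")
        if any(p < 0 for p in self.probs):
            raise ParameterError("stage probabilities must be non-negative")
        s = sum(self.probs)
        if abs(s - 1.0) > 0.005:
            raise ParameterError(f"stage probabilities sum to {s}, expected ~1")
        object.__setattr__(self, "probs", tuple(p / s for p in self.probs))

    def prob(self, stage: str) -> float:
        return self.probs[STAGES.index(stage)]


@dataclass(frozen=True)
class TunnelSchedule:
    """Annual schedules for one stage, indexed by years since the event.

    Values are given for years 1..9; beyond year 9 the year-9 value is
    carried forward. Stage 0 by definition cannot progress to distant
    metastasis, so its metastasis risk is identically zero.
    """

    stage: str
    metastasis_risk_by_year: tuple
    cost_by_year: tuple
    qol_decrement_by_year: tuple
    bc_death_risk_by_year: tuple = ()  # metastatic (stage IV) only
    # Stage IV cost is applied for all years (no long-term data exists, so
    # the year-1 figure is carried); stage I-III follow-up costs cover only
    # the scheduled years and fall to zero beyond the horizon. Risks and
    # decrements always carry their last value forward.
    cost_carry_forward: bool = True

    def __post_init__(self) -> None:
        for name in ("metastasis_risk_by_year", "cost_by_year", "qol_decrement_by_year"):
            if len(getattr(self, name)) != MAX_TUNNEL:
                raise ParameterError(f"{name} must have {MAX_TUNNEL} entries")
        if self.bc_death_risk_by_year and len(self.bc_death_risk_by_year) != MAX_TUNNEL:
            raise ParameterError("bc_death_risk_by_year must have 9 entries")
        for r in (*self.metastasis_risk_by_year, *self.bc_death_risk_by_year):
            if not 0 <= r <= 1:
                raise ParameterError(f"annual risk outside [0,1]: {r}")
        if self.stage == "0" and any(r != 0 for r in self.metastasis_risk_by_year):
            raise ParameterError("stage 0 cannot lead to distant metastasis")

    def _carry(self, values: tuple, year: int) -> float:
        if year < 1:
            raise ParameterError(f"tunnel year must be >= 1, got {year}")
        return values[min(year, MAX_TUNNEL) - 1]

    def metastasis_risk(self, year: int) -> float:
        return self._carry(self.metastasis_risk_by_year, year)

    def bc_death_risk(self, year: int) -> float:
        if not self.bc_death_risk_by_year:
            return 0.0
        return self._carry(self.bc_death_risk_by_year, year)

    def cost(self, year: int) -> float:
        if year > MAX_TUNNEL and not self.cost_carry_forward:
            return 0.0
        return self._carry(self.cost_by_year, year)

    def qol_decrement(self, year: int) -> float:
        return self._carry(self.qol_decrement_by_year, year)


@dataclass(frozen=True)
class CancerParams:
    """Stage distributions and per-stage tunnel schedules."""

    stage_distributions: Mapping  # (mode, age_band) -> StageDistribution
    tunnels: Mapping  # stage -> TunnelSchedule

    def stage_dist(self, mode: str, age_band: str) -> StageDistribution:
        try:
            return self.stage_distributions[(mode, age_band)]
        except KeyError:
            raise ParameterError(f"no stage distribution for {(mode, age_band)}")

    def tunnel(self, stage: str) -> TunnelSchedule:
        return self.tunnels[stage]


@dataclass(frozen=True)
class EconomicSettings:
    """Analysis settings: discounting, WTP threshold, cohort and horizon."""

    discount_rate: float = 0.03
    wtp_threshold: float = 50_000.0
    cohort_size: float = 1000.0
    start_age: int = 40
    terminal_age: int = 110

    def __post_init__(self) -> None:
        if self.discount_rate < 0:
            raise ParameterError("discount rate must be non-negative")
        if self.cohort_size <= 0:
            raise ParameterError("cohort size must be positive")
        if self.terminal_age <= 74:
            raise ParameterError("terminal age must exceed the last screening age")

    def discount_factor(self, cycle: int) -> float:
        return (1.0 + self.discount_rate) ** (-cycle)


# ---------------------------------------------------------------------------
# Fixture loading


def _data_text(name: str) -> str:
    return resources.files("mammocea").joinpath("data", name).read_text()


def load_table1() -> dict:
    """Screening-related parameters as {(parameter, arm): row dict}."""
    out = {}
    for row in csv.DictReader(_data_text("table1_screening.csv").splitlines()):
        key = (row["parameter"], row["arm"])
        out[key] = {
            "value": float(row["value"]),
            "dist": row["dist"],
            "alpha": float(row["alpha"]) if row["alpha"] else None,
            "beta": float(row["beta"]) if row["beta"] else None,
            "sd": float(row["sd"]) if row["sd"] else None,
        }
    return out


def load_table2() -> dict:
    """Cancer-specific parameters grouped by block."""
    out: dict = {"stage_dist": {}, "metastasis_risk": {}, "bc_death_risk": {},
                 "cost": {}, "qol_decrement": {}}
    for row in csv.DictReader(_data_text("table2_cancer.csv").splitlines()):
        block, stage, value = row["block"], row["stage"], float(row["value"])
        if block == "stage_dist":
            mode, band = row["key"].split(":")
            out["stage_dist"].setdefault((mode, band), {})[stage] = value
        else:
            year = int(row["year"])
            out[block].setdefault(stage, {})[year] = value
    return out


def default_screening_params() -> ScreeningParams:
    """Screening parameters built from the packaged fixture table."""
    t1 = load_table1()

    def bp(name, arm):
        r = t1[(name, arm)]
        return BetaParam(r["alpha"], r["beta"])

    return ScreeningParams(
        prop_double_read_aidm=t1[("double_read_share", "aidm")]["value"],
        prop_double_read_cdm=t1[("double_read_share", "cdm")]["value"],
        prop_conference_aidm=bp("conference_prop", "aidm"),
        prop_conference_cdm=bp("conference_prop", "cdm"),
        prop_recall_40_54=bp("recall_prop_40_54", "both"),
        prop_recall_55_74=bp("recall_prop_55_74", "both"),
        detect_biennial_overall_aidm=bp("detect_biennial_overall", "aidm"),
        detect_biennial_overall_cdm=bp("detect_biennial_overall", "cdm"),
        detect_biennial_55_74_aidm=t1[("detect_biennial_55_74", "aidm")]["value"],
        detect_biennial_55_74_cdm=t1[("detect_biennial_55_74", "cdm")]["value"],
        age_factor_low=t1[("age_factor_40_54", "both")]["value"],
        age_factor_high=t1[("age_factor_55_74", "both")]["value"],
        interval_share=t1[("interval_share", "both")]["value"],
    )


def default_cost_params() -> CostParams:
    t1 = load_table1()
    return CostParams(
        invitation=t1[("cost_invitation", "both")]["value"],
        mammography=t1[("cost_mammography", "both")]["value"],
        radiologist_hourly=t1[("cost_radiologist_hour", "both")]["value"],
        reads_per_hour=t1[("reads_per_hour", "both")]["value"],
        screen_reading_sd=t1[("cost_screen_reading", "both")]["sd"],
        ai_licence_per_exam=t1[("cost_ai_licence", "both")]["value"],
        conference_unit=t1[("cost_conference", "both")]["value"],
        conference_sd=t1[("cost_conference", "both")]["sd"],
        recall_unit=t1[("cost_recall", "both")]["value"],
        external_reading_unit=t1[("cost_external_reading", "both")]["value"],
    )


def default_cancer_params() -> CancerParams:
    t2 = load_table2()
    dists = {}
    for (mode, band), by_stage in t2["stage_dist"].items():
        dists[(mode, band)] = StageDistribution(
            mode=mode, age_band=band, probs=tuple(by_stage[s] for s in STAGES)
        )

    def years(block, stage):
        d = t2[block].get(stage, {})
        return tuple(d.get(y, 0.0) for y in range(1, MAX_TUNNEL + 1))

    tunnels = {}
    for stage in STAGES:
        tunnels[stage] = TunnelSchedule(
            stage=stage,
            metastasis_risk_by_year=years("metastasis_risk", stage),
            cost_by_year=years("cost", stage),
            qol_decrement_by_year=years("qol_decrement", stage),
            bc_death_risk_by_year=years("bc_death_risk", stage) if stage == "IV" else (),
            cost_carry_forward=(stage == "IV"),
        )
    return CancerParams(stage_distributions=dists, tunnels=tunnels)
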