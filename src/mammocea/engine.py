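"""Markov cohort engine.

The cohort occupies a (state x tunnel-year) space:

* ``Healthy`` — eligible for screening invitations while aged 40-74;
* ``Cancer(stage, t)`` for stages 0, I, II, III and tunnel year t = 1..9 —
  time since diagnosis, so that metastasis risk, cost and quality-of-life
  decrement can depend on it; year-9 values carry forward indefinitely;
* ``Metastatic(t)`` for t = 1..9 — time since distant metastasis (stage IV),
  the only state with a cause-specific death risk;
* ``DeadBC`` and ``DeadOther`` — absorbing.

Cycles are annual. Within a cycle the event order is: screening (in
biennial screening years), other-cause death, spontaneous incidence
(interval cancer while 40-74, registry-based incidence from 75), distant
metastasis, breast-cancer death, payoff accrual, tunnel-year increment.
Payoffs accrue on the post-event occupancy before the tunnel increment, so
the year-1 cost and decrement apply in the diagnosis cycle. No half-cycle
correction is applied. Costs and QALYs are discounted at the annual rate
from cycle 0 (age 40); event counts are reported undiscounted.

Diagnosed individuals leave the screening pool: only ``Healthy`` occupants
attend screens and incur screening costs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lifetables import IncidenceCurve, LifeTable, UtilityCurve
from .params import (
    MAX_TUNNEL,
    STAGES,
    CancerParams,
    EconomicSettings,
    ParameterError,
)
from .strategies import StrategyConfig

__all__ = [
    "StateSpace",
    "build_state_space",
    "CohortState",
    "CycleTrace",
    "CEAResult",
    "IncrementalResult",
    "screening_event",
    "annual_transition",
    "accrue",
    "run_arm",
    "compare_arms",
    "break_even_age",
]

TUNNEL_STAGES = ("0", "I", "II", "III")  # pre-metastatic cancer tunnels

SCREEN_COST_CATEGORIES = (
    "invitation",
    "mammography",
    "human_reading",
    "ai",
    "conference",
    "recall_invitation",
    "recall_diagnostics",
)
CANCER_COST_CATEGORIES = tuple(f"stage_{s}" for s in STAGES)
COST_CATEGORIES = SCREEN_COST_CATEGORIES + CANCER_COST_CATEGORIES

COUNT_FIELDS = (
    "mammograms",
    "ai_readings",
    "human_readings",
    "conferences",
    "recalls",
    "new_screen_cancers",
    "new_interval_cancers",
    "new_post75_cancers",
)

_MASS_TOL = 1e-9


@dataclass(frozen=True)
class StateSpace:
    """Dense index over Healthy, cancer tunnels, metastatic tunnel, deaths."""

    max_tunnel: int

    @property
    def n_states(self) -> int:
        return 1 + len(TUNNEL_STAGES) * self.max_tunnel + self.max_tunnel + 2

    @property
    def healthy(self) -> int:
        return 0

    def cancer(self, stage: str, year: int) -> int:
        s = TUNNEL_STAGES.index(stage)
        year = min(year, self.max_tunnel)
        return 1 + s * self.max_tunnel + (year - 1)

    def metastatic(self, year: int) -> int:
        year = min(year, self.max_tunnel)
        return 1 + len(TUNNEL_STAGES) * self.max_tunnel + (year - 1)

    @property
    def dead_bc(self) -> int:
        return self.n_states - 2

    @property
    def dead_other(self) -> int:
        return self.n_states - 1

    def alive_indices(self) -> np.ndarray:
        return np.arange(0, self.n_states - 2)


def build_state_space(max_tunnel: int = MAX_TUNNEL) -> StateSpace:
    if max_tunnel < 1:
        raise ParameterError("max_tunnel must be >= 1")
    return StateSpace(max_tunnel)


@dataclass
class CohortState:
    """Occupancy mass (persons) across the state space at one cycle."""

    space: StateSpace
    occupancy: np.ndarray
    cycle: int = 0
    age: int = 40

    @classmethod
    def initial(cls, space: StateSpace, settings: EconomicSettings) -> "CohortState":
        occ = np.zeros(space.n_states)
        occ[space.healthy] = settings.cohort_size
        return cls(space, occ, cycle=0, age=settings.start_age)

    def check_mass(self, expected: float) -> None:
        total = float(self.occupancy.sum())
        if abs(total - expected) > _MASS_TOL * max(1.0, expected):
            raise RuntimeError(
                f"mass not conserved at age {self.age}: {total} != {expected}"
            )
        if self.occupancy.min() < -_MASS_TOL:
            raise RuntimeError(f"negative occupancy at age {self.age}")


@dataclass
class CycleTrace:
    """Per-cycle event counts (undiscounted) and discounted payoffs."""

    rows: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def total_cost(self) -> float:
        return float(sum(r["cost_total"] for r in self.rows))

    def total_qaly(self) -> float:
        return float(sum(r["qaly"] for r in self.rows))

    def cost_by_category(self) -> dict:
        out = {c: 0.0 for c in COST_CATEGORIES}
        for r in self.rows:
            for c in COST_CATEGORIES:
                out[c] += r[f"cost_{c}"]
        return out

    def counts(self) -> dict:
        out = {c: 0.0 for c in COUNT_FIELDS}
        for r in self.rows:
            for c in COUNT_FIELDS:
                out[c] += r[c]
        return out


@dataclass
class CEAResult:
    """Lifetime discounted totals for one arm."""

    name: str
    total_cost: float
    total_qaly: float
    cost_by_category: dict
    counts: dict
    trace: CycleTrace

    @property
    def screening_cost(self) -> float:
        return sum(self.cost_by_category[c] for c in SCREEN_COST_CATEGORIES)

    @property
    def cancer_cost(self) -> float:
        return sum(self.cost_by_category[c] for c in CANCER_COST_CATEGORIES)


@dataclass
class IncrementalResult:
    """Incremental statistics of arm ``a`` versus comparator ``b``."""

    a: CEAResult
    b: CEAResult
    incremental_cost: float
    incremental_qaly: float
    icer: float | None
    label: str
    break_even_age: int | None = None


def _empty_row(age: int, cycle: int) -> dict:
    row = {"age": age, "cycle": cycle}
    for c in COUNT_FIELDS:
        row[c] = 0.0
    for c in COST_CATEGORIES:
        row[f"cost_{c}"] = 0.0
    row["cost_total"] = 0.0
    row["cost_undiscounted"] = 0.0
    row["qaly"] = 0.0
    row["alive"] = 0.0
    return row


def screening_event(
    cohort: CohortState,
    arm: StrategyConfig,
    cancer: CancerParams,
    costs,
    row: dict,
    disc: float,
) -> None:
    """Apply one biennial screen to the Healthy occupants, in place.

    Detected mass leaves Healthy for the stage tunnels (year 1) using the
    age band's screen-detected stage distribution; detected stage IV enters
    the metastatic tunnel directly. Screening resource use (mammograms,
    readings, conferences, recalls) and costs accrue for all attendees.
    """
    sp = cohort.space
    if cohort.age not in arm.screening_ages:
        raise ParameterError(f"age {cohort.age} is not a screening age")
    band = arm.age_band(cohort.age)
    attendees = float(cohort.occupancy[sp.healthy])

    # resource use: every attendee is invited, imaged, and read
    conferences = arm.conference_prop * attendees
    recalls = arm.recall_props[band] * attendees
    human_reads = (arm.human_read_share + arm.double_read_share) * attendees
    human_reads += 2.0 * conferences
    row["mammograms"] += attendees
    row["ai_readings"] += attendees if arm.uses_ai else 0.0
    row["human_readings"] += human_reads
    row["conferences"] += conferences
    row["recalls"] += recalls

    add = {
        "invitation": costs.invitation * attendees,
        "mammography": costs.mammography * attendees,
        "human_reading": arm.reading_unit_cost * human_reads,
        "ai": (costs.ai_licence_per_exam * attendees) if arm.uses_ai else 0.0,
        "conference": costs.conference_unit * conferences,
        "recall_invitation": costs.invitation * recalls,
        "recall_diagnostics": costs.recall_unit * recalls,
    }
    for cat, v in add.items():
        row[f"cost_{cat}"] += v * disc
        row["cost_undiscounted"] += v

    # detection
    detected = arm.detection_biennial[band] * attendees
    if detected > 0:
        dist = cancer.stage_dist("screening", band)
        cohort.occupancy[sp.healthy] -= detected
        for stage in STAGES:
            mass = detected * dist.prob(stage)
            if stage == "IV":
                cohort.occupancy[sp.metastatic(1)] += mass
            else:
                cohort.occupancy[sp.cancer(stage, 1)] += mass
        row["new_screen_cancers"] += detected


def _spontaneous_incidence(
    cohort: CohortState,
    arm: StrategyConfig,
    cancer: CancerParams,
    inc75: IncidenceCurve,
    row: dict,
) -> None:
    """Interval cancer (ages 40-74) or registry incidence (75+) from Healthy."""
    sp = cohort.space
    age = cohort.age
    if age < 75:
        risk = arm.interval_annual[arm.age_band(age)]
        dist = cancer.stage_dist("interval", arm.age_band(age))
        count_field = "new_interval_cancers"
    else:
        risk = inc75.risk_at(age)
        dist = inc75.stage_probs
        count_field = "new_post75_cancers"
    new = cohort.occupancy[sp.healthy] * risk
    if new <= 0:
        return
    cohort.occupancy[sp.healthy] -= new
    for stage in STAGES:
        mass = new * dist.prob(stage)
        if stage == "IV":
            cohort.occupancy[sp.metastatic(1)] += mass
        else:
            cohort.occupancy[sp.cancer(stage, 1)] += mass
    row[count_field] += new


def annual_transition(
    cohort: CohortState,
    arm: StrategyConfig,
    cancer: CancerParams,
    lt: LifeTable,
    inc75: IncidenceCurve,
    row: dict,
) -> None:
    """One annual cycle of transitions, in place (no tunnel increment).

    Order: other-cause death, spontaneous incidence, distant metastasis,
    breast-cancer death. Substeps are sequential: mass that metastasises
    this cycle is exposed to the year-1 metastatic death risk in the same
    cycle.
    """
    sp = cohort.space
    occ = cohort.occupancy

    # other-cause mortality hits every alive state
    q = lt.qx_at(cohort.age)
    alive = sp.alive_indices()
    occ[sp.dead_other] += occ[alive].sum() * q
    occ[alive] *= 1.0 - q

    _spontaneous_incidence(cohort, arm, cancer, inc75, row)

    # distant metastasis from the stage tunnels
    new_met = 0.0
    for stage in TUNNEL_STAGES:
        sched = cancer.tunnel(stage)
        for t in range(1, sp.max_tunnel + 1):
            idx = sp.cancer(stage, t)
            flow = occ[idx] * sched.metastasis_risk(t)
            if flow:
                occ[idx] -= flow
                new_met += flow
    occ[sp.metastatic(1)] += new_met

    # breast-cancer death from the metastatic tunnel
    sched_iv = cancer.tunnel("IV")
    for t in range(1, sp.max_tunnel + 1):
        idx = sp.metastatic(t)
        flow = occ[idx] * sched_iv.bc_death_risk(t)
        if flow:
            occ[idx] -= flow
            occ[sp.dead_bc] += flow


def accrue(
    cohort: CohortState,
    cancer: CancerParams,
    settings: EconomicSettings,
    utilities: UtilityCurve,
    row: dict,
) -> None:
    """Accumulate this cycle's discounted cancer costs and QALYs into ``row``.

    Cycle cost is occupancy-weighted stage cost by tunnel year; cycle QALY
    is occupancy times (age utility minus the state's decrement), clamped
    at zero. Both are discounted by (1+r)^(-cycle).
    """
    sp = cohort.space
    occ = cohort.occupancy
    disc = settings.discount_factor(cohort.cycle)
    u = utilities.weight_at(cohort.age)

    qaly = occ[sp.healthy] * u
    for stage in TUNNEL_STAGES:
        sched = cancer.tunnel(stage)
        for t in range(1, sp.max_tunnel + 1):
            mass = occ[sp.cancer(stage, t)]
            if not mass:
                continue
            c = sched.cost(t)
            row[f"cost_stage_{stage}"] += mass * c * disc
            row["cost_undiscounted"] += mass * c
            qaly += mass * max(0.0, u - sched.qol_decrement(t))
    sched_iv = cancer.tunnel("IV")
    for t in range(1, sp.max_tunnel + 1):
        mass = occ[sp.metastatic(t)]
        if not mass:
            continue
        c = sched_iv.cost(t)
        row["cost_stage_IV"] += mass * c * disc
        row["cost_undiscounted"] += mass * c
        qaly += mass * max(0.0, u - sched_iv.qol_decrement(t))

    row["qaly"] += qaly * disc
    row["alive"] = float(occ[sp.alive_indices()].sum())


def _tunnel_increment(cohort: CohortState) -> None:
    """Advance tunnel years by one, capping at the last (carry-forward) year."""
    sp = cohort.space
    occ = cohort.occupancy
    m = sp.max_tunnel
    for stage in TUNNEL_STAGES:
        top = sp.cancer(stage, m)
        occ[top] += occ[top - 1] if m > 1 else 0.0
        for t in range(m - 1, 1, -1):
            occ[sp.cancer(stage, t)] = occ[sp.cancer(stage, t - 1)]
        if m > 1:
            occ[sp.cancer(stage, 1)] = 0.0
    top = sp.metastatic(m)
    occ[top] += occ[top - 1] if m > 1 else 0.0
    for t in range(m - 1, 1, -1):
        occ[sp.metastatic(t)] = occ[sp.metastatic(t - 1)]
    if m > 1:
        occ[sp.metastatic(1)] = 0.0


def run_arm(
    arm: StrategyConfig,
    cancer: CancerParams,
    lt: LifeTable,
    utilities: UtilityCurve,
    inc75: IncidenceCurve,
    settings: EconomicSettings,
    costs=None,
) -> CEAResult:
    """Propagate one arm's cohort over the lifetime horizon.

    Iterates annual cycles from the start age to the terminal age, applying
    the screening event in biennial screening years, then the annual
    transitions and payoff accrual. Mass conservation is checked every
    cycle at 1e-9 relative tolerance.
    """
    from .params import default_cost_params

    costs = costs or default_cost_params()
    # one extra tunnel slot beyond the 9 scheduled years: carried quantities
    # keep their year-9 values there, stage I-III follow-up costs end
    space = build_state_space(MAX_TUNNEL + 1)
    cohort = CohortState.initial(space, settings)
    trace = CycleTrace()
    for cycle, age in enumerate(
        range(settings.start_age, settings.terminal_age + 1)
    ):
        cohort.cycle, cohort.age = cycle, age
        row = _empty_row(age, cycle)
        disc = settings.discount_factor(cycle)
        if age in arm.screening_ages:
            screening_event(cohort, arm, cancer, costs, row, disc)
        annual_transition(cohort, arm, cancer, lt, inc75, row)
        accrue(cohort, cancer, settings, utilities, row)
        _tunnel_increment(cohort)
        for c in SCREEN_COST_CATEGORIES + CANCER_COST_CATEGORIES:
            row["cost_total"] += row[f"cost_{c}"]
        trace.rows.append(row)
        cohort.check_mass(settings.cohort_size)
    # close out: residual alive mass at the horizon is absorbed
    alive = space.alive_indices()
    cohort.occupancy[space.dead_other] += cohort.occupancy[alive].sum()
    cohort.occupancy[alive] = 0.0

    return CEAResult(
        name=arm.name,
        total_cost=trace.total_cost(),
        total_qaly=trace.total_qaly(),
        cost_by_category=trace.cost_by_category(),
        counts=trace.counts(),
        trace=trace,
    )


def compare_arms(a: CEAResult, b: CEAResult) -> IncrementalResult:
    """Incremental cost, QALYs, and ICER of arm ``a`` versus ``b``.

    A strategy that saves costs and gains QALYs is *dominant*; one that
    costs more and loses QALYs is *dominated*. The ICER is undefined when
    the QALY difference is zero.
    """
    d_cost = a.total_cost - b.total_cost
    d_qaly = a.total_qaly - b.total_qaly
    if d_qaly == 0:
        icer, label = None, "equal effectiveness (ICER undefined)"
    else:
        icer = d_cost / d_qaly
        if d_cost < 0 and d_qaly > 0:
            label = "dominant"
        elif d_cost > 0 and d_qaly < 0:
            label = "dominated"
        elif d_qaly > 0:
            label = "more effective, more costly"
        else:
            label = "less effective, less costly"
    return IncrementalResult(
        a=a, b=b,
        incremental_cost=d_cost,
        incremental_qaly=d_qaly,
        icer=icer,
        label=label,
        break_even_age=break_even_age(a.trace, b.trace),
    )


def break_even_age(trace_a: CycleTrace, trace_b: CycleTrace) -> int | None:
    """First age at which cumulative discounted incremental cost is <= 0.

    Cumulative totals are compared after each cycle; ties count (identical
    arms break even at the start age). Returns ``None`` if the comparator
    stays cheaper over the whole horizon.
    """
    if len(trace_a.rows) != len(trace_b.rows):
        raise ParameterError("traces must cover the same cycles")
    cum = 0.0
    for ra, rb in zip(trace_a.rows, trace_b.rows):
        if ra["age"] != rb["age"]:
            raise ParameterError("traces must be age-aligned")
        cum += ra["cost_total"] - rb["cost_total"]
        if cum <= 0:
            return int(ra["age"])
    return None
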