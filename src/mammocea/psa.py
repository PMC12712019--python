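"""Probabilistic sensitivity analysis.

Each Monte Carlo draw samples every distributed parameter from its
distribution, rebuilds both screening arms from the same draw, reruns the
cohort engine for each arm, and records the incremental cost and QALYs.
Draws are then classified on the cost-effectiveness plane:

* *dominant* — the AI-assisted arm saves costs and gains QALYs;
* *less effective* — it loses QALYs (at any cost);
* *more effective, more costly* — it gains QALYs at extra cost.

Parameters are sampled independently; per-draw values are shared between
arms wherever the parameter is common (stage costs, tunnel risks, recall
proportions), so that draw-to-draw differences reflect the strategies and
not sampling noise.

Distributions: proportions and detection risks use the Beta shapes from
their source counts. Tunnel risks (distant metastasis, metastatic death)
use Beta with the observed risk and the source cohort sizes (11,459 /
5,916 / 433 patients for stages I-III, 977 for the metastatic death
schedule). Quality-of-life decrements use method-of-moments Beta and
cancer costs method-of-moments Gamma, both with an assumed 20%
coefficient of variation (no dispersion is published for them); both CVs
are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .engine import run_arm
from .lifetables import IncidenceCurve, LifeTable, UtilityCurve
from .params import (
    MAX_TUNNEL,
    BetaParam,
    CancerParams,
    CostParams,
    EconomicSettings,
    GammaParam,
    ParameterError,
    ScreeningParams,
    TunnelSchedule,
    derive_age_detection,
    derive_interval_risk,
)
from .strategies import StrategyConfig

__all__ = ["PsaDraw", "PsaSummary", "sample_parameters", "run_psa",
           "plot_ce_plane", "plot_ceac"]

# source cohort sizes behind the tunnel risk estimates
RISK_SOURCE_N = {"I": 11459, "II": 5916, "III": 433, "IV": 977}

DEFAULT_WTP_GRID = tuple(range(0, 105_000, 5_000))


@dataclass(frozen=True)
class PsaDraw:
    """One sampled parameter set and its incremental outcome."""

    draw_index: int
    params: dict
    incremental_cost: float = float("nan")
    incremental_qaly: float = float("nan")


@dataclass
class PsaSummary:
    """Quadrant shares and acceptability curve over a WTP grid."""

    n_draws: int
    share_dominant: float
    share_less_effective: float
    share_more_effective_more_costly: float
    ceac: dict  # wtp -> probability cost-effective
    draws: pd.DataFrame = field(repr=False, default=None)

    def prob_cost_effective(self, wtp: float) -> float:
        if wtp not in self.ceac:
            raise KeyError(f"WTP {wtp} not on the grid")
        return self.ceac[wtp]


def _beta_draw(rng: np.random.Generator, p: BetaParam) -> float:
    return float(rng.beta(p.alpha, p.beta))


def _beta_count_draw(rng: np.random.Generator, risk: float, n: int) -> float:
    if risk <= 0:
        return 0.0
    return float(rng.beta(risk * n, (1 - risk) * n))


def _gamma_draw(rng: np.random.Generator, g: GammaParam) -> float:
    if g.sd == 0:
        return g.mean
    return float(rng.gamma(g.shape, g.scale))


def sample_parameters(
    rng: np.random.Generator,
    screening: ScreeningParams,
    costs: CostParams,
    cancer: CancerParams,
    decrement_cv: float = 0.20,
    cost_cv: float = 0.20,
) -> dict:
    """Sample one complete parameter set.

    Returns a flat dict of sampled scalars plus rebuilt ``CancerParams``
    under key ``"cancer"``. Fixed parameters pass through unchanged.
    """
    s = {
        "detect_overall_aidm": _beta_draw(rng, screening.detect_biennial_overall_aidm),
        "detect_overall_cdm": _beta_draw(rng, screening.detect_biennial_overall_cdm),
        "conference_prop_aidm": _beta_draw(rng, screening.prop_conference_aidm),
        "conference_prop_cdm": _beta_draw(rng, screening.prop_conference_cdm),
        "recall_prop_40_54": _beta_draw(rng, screening.prop_recall_40_54),
        "recall_prop_55_74": _beta_draw(rng, screening.prop_recall_55_74),
        "screen_reading_unit": _gamma_draw(
            rng, GammaParam(costs.screen_reading_unit, costs.screen_reading_sd)
        ),
        "conference_unit": _gamma_draw(
            rng, GammaParam(costs.conference_unit, costs.conference_sd)
        ),
    }

    # grouped cancer costs: shared first-year cost, shared follow-up cost,
    # flat metastatic cost (the source applies one figure per group)
    first_year = cancer.tunnel("I").cost(1)
    follow_up = cancer.tunnel("I").cost(2)
    metastatic = cancer.tunnel("IV").cost(1)
    s["cost_first_year"] = _gamma_draw(rng, GammaParam(first_year, cost_cv * first_year))
    s["cost_follow_up"] = _gamma_draw(rng, GammaParam(follow_up, cost_cv * follow_up))
    s["cost_metastatic"] = _gamma_draw(rng, GammaParam(metastatic, cost_cv * metastatic))

    # grouped QOL decrements (stages 0/I/II share one value)
    for key, stage in [("dec_early", "I"), ("dec_stage_iii", "III"), ("dec_metastatic", "IV")]:
        mean = cancer.tunnel(stage).qol_decrement(1)
        s[key] = _beta_draw(rng, BetaParam.from_mean_cv(mean, decrement_cv))

    # tunnel risks with count-based Beta shapes
    for stage in ("I", "II", "III"):
        sched = cancer.tunnel(stage)
        s[f"met_risk_{stage}"] = tuple(
            _beta_count_draw(rng, sched.metastasis_risk(t), RISK_SOURCE_N[stage])
            for t in range(1, MAX_TUNNEL + 1)
        )
    sched_iv = cancer.tunnel("IV")
    s["bc_death_risk"] = tuple(
        _beta_count_draw(rng, sched_iv.bc_death_risk(t), RISK_SOURCE_N["IV"])
        for t in range(1, MAX_TUNNEL + 1)
    )

    s["cancer"] = _rebuild_cancer(cancer, s)
    return s


def _rebuild_cancer(cancer: CancerParams, s: dict) -> CancerParams:
    def costs_for(stage):
        if stage == "IV":
            return (s["cost_metastatic"],) * MAX_TUNNEL
        if stage == "0":
            return (s["cost_first_year"],) + (0.0,) * (MAX_TUNNEL - 1)
        return (s["cost_first_year"],) + (s["cost_follow_up"],) * (MAX_TUNNEL - 1)

    def decs_for(stage):
        if stage == "IV":
            return (s["dec_metastatic"],) * MAX_TUNNEL
        if stage == "III":
            return (s["dec_stage_iii"],) * MAX_TUNNEL
        if stage == "0":
            return (s["dec_early"],) + (0.0,) * (MAX_TUNNEL - 1)
        return (s["dec_early"],) * MAX_TUNNEL

    tunnels = {}
    for stage in ("0", "I", "II", "III", "IV"):
        met = s.get(f"met_risk_{stage}", (0.0,) * MAX_TUNNEL)
        tunnels[stage] = TunnelSchedule(
            stage=stage,
            metastasis_risk_by_year=met,
            cost_by_year=costs_for(stage),
            qol_decrement_by_year=decs_for(stage),
            bc_death_risk_by_year=s["bc_death_risk"] if stage == "IV" else (),
            cost_carry_forward=(stage == "IV"),
        )
    return CancerParams(
        stage_distributions=cancer.stage_distributions, tunnels=tunnels
    )


def _strategy_from_sample(
    base: StrategyConfig,
    arm_kind: str,
    s: dict,
    screening: ScreeningParams,
    base_reading_unit: float,
) -> StrategyConfig:
    """Rebuild a strategy with its detection chain re-derived from a draw."""
    overall = s[f"detect_overall_{arm_kind}"]
    overall_mean = (
        screening.detect_biennial_overall_aidm.mean
        if arm_kind == "aidm"
        else screening.detect_biennial_overall_cdm.mean
    )
    printed_high = (
        screening.detect_biennial_55_74_aidm
        if arm_kind == "aidm"
        else screening.detect_biennial_55_74_cdm
    )
    mult = base.detection_multiplier
    detect = {
        "40_54": derive_age_detection(overall, screening.age_factor_low) * mult,
        # the printed 55-74 figure scales with the sampled overall risk
        "55_74": printed_high * (overall / overall_mean) * mult,
    }
    cdm_ref = {
        "40_54": derive_age_detection(
            s["detect_overall_cdm"], screening.age_factor_low
        ),
        "55_74": screening.detect_biennial_55_74_cdm
        * (s["detect_overall_cdm"] / screening.detect_biennial_overall_cdm.mean),
    }
    interval = {
        band: derive_interval_risk(
            cdm_ref[band], detect[band], screening.interval_share, clamp=True
        )
        for band in ("40_54", "55_74")
    }
    # scenario-specific reading costs (e.g. outsourced reading) stay fixed;
    # the in-house unit cost is the Gamma-distributed one
    reading_cost = (
        s["screen_reading_unit"]
        if base.reading_unit_cost == base_reading_unit
        else base.reading_unit_cost
    )
    return replace(
        base,
        detection_biennial=detect,
        interval_annual=interval,
        conference_prop=s[f"conference_prop_{arm_kind}"],
        recall_props={
            "40_54": s["recall_prop_40_54"],
            "55_74": s["recall_prop_55_74"],
        },
        reading_unit_cost=reading_cost,
    )


def run_psa(
    n: int,
    seed: int,
    arm_a: StrategyConfig,
    arm_b: StrategyConfig,
    screening: ScreeningParams,
    costs: CostParams,
    cancer: CancerParams,
    lt: LifeTable,
    utilities: UtilityCurve,
    inc75: IncidenceCurve,
    settings: EconomicSettings,
    wtp_grid: tuple = DEFAULT_WTP_GRID,
    decrement_cv: float = 0.20,
    cost_cv: float = 0.20,
) -> PsaSummary:
    """Run ``n`` paired Monte Carlo evaluations of ``arm_a`` vs ``arm_b``.

    Both arms within a draw share the sampled common parameters. Quadrant
    shares partition the draws; the CEAC reports, for each willingness to
    pay on the grid, the share of draws with positive net monetary benefit
    for ``arm_a``.
    """
    if n < 1:
        raise ParameterError("need at least one draw")
    rng = np.random.default_rng(seed)
    recs = []
    for i in range(n):
        s = sample_parameters(rng, screening, costs, cancer,
                              decrement_cv=decrement_cv, cost_cv=cost_cv)
        sampled_costs = replace(
            costs,
            conference_unit=s["conference_unit"],
        )
        unit = costs.screen_reading_unit
        a = _strategy_from_sample(arm_a, "aidm", s, screening, unit)
        b = _strategy_from_sample(arm_b, "cdm", s, screening, unit)
        res_a = run_arm(a, s["cancer"], lt, utilities, inc75, settings, sampled_costs)
        res_b = run_arm(b, s["cancer"], lt, utilities, inc75, settings, sampled_costs)
        d_cost = res_a.total_cost - res_b.total_cost
        d_qaly = res_a.total_qaly - res_b.total_qaly
        if d_qaly <= 0:
            quadrant = "less_effective"
        elif d_cost < 0:
            quadrant = "dominant"
        else:
            quadrant = "more_effective_more_costly"
        recs.append(
            {
                "draw": i,
                "d_cost": d_cost,
                "d_qaly": d_qaly,
                "quadrant": quadrant,
                "detect_overall_aidm": s["detect_overall_aidm"],
                "detect_overall_cdm": s["detect_overall_cdm"],
                "screen_reading_unit": s["screen_reading_unit"],
                "cost_first_year": s["cost_first_year"],
                "cost_follow_up": s["cost_follow_up"],
                "cost_metastatic": s["cost_metastatic"],
            }
        )
    draws = pd.DataFrame(recs)
    shares = draws["quadrant"].value_counts(normalize=True)
    ceac = {
        float(w): float(((w * draws["d_qaly"] - draws["d_cost"]) > 0).mean())
        for w in wtp_grid
    }
    return PsaSummary(
        n_draws=n,
        share_dominant=float(shares.get("dominant", 0.0)),
        share_less_effective=float(shares.get("less_effective", 0.0)),
        share_more_effective_more_costly=float(
            shares.get("more_effective_more_costly", 0.0)
        ),
        ceac=ceac,
        draws=draws,
    )


def plot_ce_plane(summary: PsaSummary, wtp: float = 50_000.0, ax=None):
    """Incremental cost-effectiveness plane of all PSA draws."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    d = summary.draws
    colors = {"dominant": "tab:green", "less_effective": "tab:red",
              "more_effective_more_costly": "tab:orange"}
    for quadrant, grp in d.groupby("quadrant"):
        ax.scatter(grp["d_qaly"], grp["d_cost"], s=8, alpha=0.5,
                   color=colors.get(quadrant, "gray"), label=quadrant)
    ax.axhline(0, color="k", lw=0.8)
    ax.axvline(0, color="k", lw=0.8)
    q = np.array(ax.get_xlim())
    ax.plot(q, wtp * q, "k--", lw=0.8, label=f"WTP {wtp:,.0f}/QALY")
    ax.set_xlabel("Incremental QALYs (per 1000)")
    ax.set_ylabel("Incremental cost (EUR per 1000)")
    ax.legend(fontsize=8)
    return ax


def plot_ceac(summary: PsaSummary, ax=None):
    """Cost-effectiveness acceptability curve."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    wtps = sorted(summary.ceac)
    ax.plot(wtps, [summary.ceac[w] for w in wtps], marker="o", ms=3)
    ax.set_xlabel("Willingness to pay (EUR/QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(0, 1.02)
    return ax
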