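"""Model/Results interface to the screening cost-effectiveness analysis.

``ScreeningCEModel`` bundles the comparison of two screening strategies
with all model inputs; ``fit()`` runs the deterministic cohort analysis
and returns ``ScreeningCEResults`` carrying per-arm totals, incremental
statistics and a printable summary table; ``fit_psa()`` runs the
probabilistic sensitivity analysis and returns ``PsaResults`` with
quadrant shares, the acceptability curve, and plotting helpers.

    >>> model = ScreeningCEModel.from_defaults()
    >>> res = model.fit()
    >>> print(res.summary())            # doctest: +SKIP
    >>> psa = model.fit_psa(n_draws=1000, seed=1)
    >>> psa.share_dominant              # doctest: +SKIP
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd

from . import report
from .engine import CEAResult, IncrementalResult, compare_arms, run_arm
from .lifetables import (
    IncidenceCurve,
    LifeTable,
    UtilityCurve,
    synth_lifetable,
    synth_post75_incidence,
    synth_utilities,
)
from .params import (
    CancerParams,
    CostParams,
    EconomicSettings,
    ScreeningParams,
    default_cancer_params,
    default_cost_params,
    default_screening_params,
)
from .psa import PsaSummary, plot_ce_plane, plot_ceac, run_psa
from .strategies import StrategyConfig, make_base_aidm, make_base_cdm, make_scenario

__all__ = ["ScreeningCEModel", "ScreeningCEResults", "PsaResults"]


@dataclass
class ScreeningCEModel:
    """Cost-effectiveness comparison of two mammography screening strategies.

    Parameters
    ----------
    arm, comparator
        Strategy configurations; by default the AI-assisted base case
        versus conventional double reading.
    lifetable, utilities, incidence
        Other-cause mortality, population utility weights, and post-75
        breast cancer incidence. Defaults are the synthetic Swedish-like
        stand-ins.
    """

    arm: StrategyConfig
    comparator: StrategyConfig
    screening: ScreeningParams
    costs: CostParams
    cancer: CancerParams
    lifetable: LifeTable
    utilities: UtilityCurve
    incidence: IncidenceCurve
    settings: EconomicSettings = field(default_factory=EconomicSettings)

    @classmethod
    def from_defaults(
        cls,
        scenario: str | None = None,
        lifetable: LifeTable | None = None,
        utilities: UtilityCurve | None = None,
        incidence: IncidenceCurve | None = None,
        settings: EconomicSettings | None = None,
    ) -> "ScreeningCEModel":
        """Model from the packaged parameter tables and synthetic curves.

        ``scenario`` replaces the AI-assisted arm with one of the one-way
        scenario variants ('S1'..'S4'); the comparator is always the
        conventional double-reading arm.
        """
        screening = default_screening_params()
        costs = default_cost_params()
        arm = (
            make_scenario(scenario, screening, costs)
            if scenario
            else make_base_aidm(screening, costs)
        )
        return cls(
            arm=arm,
            comparator=make_base_cdm(screening, costs),
            screening=screening,
            costs=costs,
            cancer=default_cancer_params(),
            lifetable=lifetable if lifetable is not None else synth_lifetable(),
            utilities=utilities if utilities is not None else synth_utilities(),
            incidence=incidence if incidence is not None else synth_post75_incidence(),
            settings=settings or EconomicSettings(),
        )

    def fit(self) -> "ScreeningCEResults":
        """Deterministic base-case evaluation of both arms."""
        res_a = run_arm(self.arm, self.cancer, self.lifetable, self.utilities,
                        self.incidence, self.settings, self.costs)
        res_b = run_arm(self.comparator, self.cancer, self.lifetable,
                        self.utilities, self.incidence, self.settings, self.costs)
        return ScreeningCEResults(self, res_a, res_b, compare_arms(res_a, res_b))

    def fit_psa(
        self,
        n_draws: int = 1000,
        seed: int = 0,
        wtp_grid: tuple | None = None,
        decrement_cv: float = 0.20,
        cost_cv: float = 0.20,
    ) -> "PsaResults":
        """Probabilistic sensitivity analysis with ``n_draws`` Monte Carlo draws."""
        kwargs = {} if wtp_grid is None else {"wtp_grid": wtp_grid}
        summary = run_psa(
            n_draws, seed, self.arm, self.comparator, self.screening,
            self.costs, self.cancer, self.lifetable, self.utilities,
            self.incidence, self.settings,
            decrement_cv=decrement_cv, cost_cv=cost_cv, **kwargs,
        )
        return PsaResults(self, summary, seed)


@dataclass
class ScreeningCEResults:
    """Deterministic results: per-arm totals and incremental statistics."""

    model: ScreeningCEModel
    arm_result: CEAResult
    comparator_result: CEAResult
    incremental: IncrementalResult

    @property
    def incremental_cost(self) -> float:
        return self.incremental.incremental_cost

    @property
    def incremental_qaly(self) -> float:
        return self.incremental.incremental_qaly

    @property
    def icer(self) -> float | None:
        return self.incremental.icer

    @property
    def break_even_age(self) -> int | None:
        return self.incremental.break_even_age

    def summary(self) -> str:
        """Printable base-case table: counts, costs by category, QALYs, ICER."""
        return report.render_table3(self.arm_result, self.comparator_result,
                                    self.incremental)

    def summary_frame(self) -> pd.DataFrame:
        return report.table3_frame(self.arm_result, self.comparator_result,
                                   self.incremental)

    def trace_frame(self) -> pd.DataFrame:
        """Tidy per-cycle trace for both arms."""
        fa = self.arm_result.trace.to_frame().assign(arm=self.arm_result.name)
        fb = self.comparator_result.trace.to_frame().assign(
            arm=self.comparator_result.name
        )
        return pd.concat([fa, fb], ignore_index=True)

    def to_json(self) -> str:
        inc = self.incremental
        payload = {
            "arm": self.arm_result.name,
            "comparator": self.comparator_result.name,
            "total_cost": {
                self.arm_result.name: self.arm_result.total_cost,
                self.comparator_result.name: self.comparator_result.total_cost,
            },
            "total_qaly": {
                self.arm_result.name: self.arm_result.total_qaly,
                self.comparator_result.name: self.comparator_result.total_qaly,
            },
            "incremental_cost": inc.incremental_cost,
            "incremental_qaly": inc.incremental_qaly,
            "icer": inc.icer,
            "label": inc.label,
            "break_even_age": inc.break_even_age,
        }
        return json.dumps(payload, indent=2)


@dataclass
class PsaResults:
    """Probabilistic results: quadrant shares, CEAC, plotting."""

    model: ScreeningCEModel
    psa: PsaSummary
    seed: int

    @property
    def share_dominant(self) -> float:
        return self.psa.share_dominant

    @property
    def draws(self) -> pd.DataFrame:
        return self.psa.draws

    def prob_cost_effective(self, wtp: float | None = None) -> float:
        wtp = self.model.settings.wtp_threshold if wtp is None else wtp
        return self.psa.prob_cost_effective(wtp)

    def summary(self) -> str:
        p = self.psa
        wtp = self.model.settings.wtp_threshold
        lines = [
            f"Probabilistic sensitivity analysis ({p.n_draws} draws, seed {self.seed})",
            f"  dominant (cheaper, more QALYs):     {p.share_dominant:6.1%}",
            f"  less effective (fewer QALYs):       {p.share_less_effective:6.1%}",
            f"  more effective, more costly:        {p.share_more_effective_more_costly:6.1%}",
            f"  cost-effective at WTP {wtp:,.0f}/QALY: {p.prob_cost_effective(wtp):6.1%}",
        ]
        return "\n".join(lines)

    def plot_ce_plane(self, ax=None):
        return plot_ce_plane(self.psa, self.model.settings.wtp_threshold, ax=ax)

    def plot_ceac(self, ax=None):
        return plot_ceac(self.psa, ax=ax)
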