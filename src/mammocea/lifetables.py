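"""Other-cause mortality, population utility weights, and post-screening
breast cancer incidence.

Real inputs, when available, are read from their standard layouts (HMD
1x1 period life tables for mortality). Synthetic stand-ins with the same
statistical structure are generated for fully offline runs:

* mortality follows a Gompertz hazard ``qx(age) = min(1, a * exp(b * age))``,
  the canonical shape of adult human mortality, with defaults calibrated to
  a recent Swedish female period table (life expectancy at age 40 of about
  45-46 years);
* population utility declines linearly with age from a base value at 40,
  floored at 0.5, and is frozen at the age-88 value for older ages;
* post-screening (age 75+) breast cancer incidence varies gently with age
  around a level of 0.35% per year up to age 90 and is constant at the
  75-90 average beyond, with the stage distribution of spontaneously
  detected cancer in the 75+ band.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .params import ParameterError, StageDistribution

__all__ = [
    "LifeTable",
    "UtilityCurve",
    "IncidenceCurve",
    "read_hmd_lifetable",
    "synth_lifetable",
    "synth_utilities",
    "synth_post75_incidence",
]

UTILITY_FREEZE_AGE = 88
INCIDENCE_FLAT_AGE = 90


@dataclass(frozen=True)
class LifeTable:
    """Female period life table: annual death probabilities qx by age."""

    age: np.ndarray
    qx: np.ndarray

    def __post_init__(self) -> None:
        if len(self.age) != len(self.qx):
            raise ParameterError("age and qx must have equal length")
        if np.any((self.qx < 0) | (self.qx > 1)):
            raise ParameterError("qx values must lie in [0,1]")

    def qx_at(self, age: int) -> float:
        """Annual other-cause death probability at ``age`` (clamped to ends)."""
        i = int(np.clip(np.searchsorted(self.age, age), 0, len(self.age) - 1))
        if self.age[i] != age:
            i = max(0, i - 1) if age < self.age[0] else len(self.age) - 1
        return float(self.qx[i])

    def survival_from(self, start_age: int, end_age: int) -> np.ndarray:
        """Survivors per unit mass at the *start* of each age start..end.

        ``out[0] == 1``; subsequent entries multiply through (1 - qx).
        """
        ages = np.arange(start_age, end_age + 1)
        s = np.ones(len(ages))
        for k in range(1, len(ages)):
            s[k] = s[k - 1] * (1.0 - self.qx_at(int(ages[k - 1])))
        return s

    def to_hmd(self, year: int = 2022) -> str:
        """Render in HMD 1x1 period layout (Year, Age, mx, qx, ...)."""
        buf = io.StringIO()
        buf.write("Synthetic life table (period 1x1)\n\n")
        buf.write("  Year          Age         mx       qx    ax      lx      dx      Lx       Tx     ex\n")
        lx = 100000.0
        for a, q in zip(self.age, self.qx):
            tok = "110+" if a >= 110 else str(int(a))
            mx = q / (1 - q / 2) if q < 1 else 1.0
            # qx written at full precision so a write/read round-trip is exact
            buf.write(
                f"  {year}       {tok:>5}   {mx:.5f}  {q:.17g}  0.50  {lx:7.0f}"
                f"  {lx * q:7.0f}  {lx * (1 - q / 2):7.0f}  0  0.00\n"
            )
            lx *= 1 - q
        return buf.getvalue()


@dataclass(frozen=True)
class UtilityCurve:
    """Age-specific population utility weights, frozen from age 88 upward."""

    age: np.ndarray
    weight: np.ndarray

    def __post_init__(self) -> None:
        if np.any((self.weight < 0) | (self.weight > 1)):
            raise ParameterError("utility weights must lie in [0,1]")
        frozen = self.age >= UTILITY_FREEZE_AGE
        if frozen.any():
            w88 = self.weight[frozen][0]
            if not np.allclose(self.weight[frozen], w88):
                raise ParameterError("weights must be frozen from age 88 upward")

    def weight_at(self, age: int) -> float:
        a = min(int(age), int(self.age[-1]))
        a = max(a, int(self.age[0]))
        i = int(np.searchsorted(self.age, a))
        return float(self.weight[i])


@dataclass(frozen=True)
class IncidenceCurve:
    """Annual breast cancer incidence after the screening programme ends."""

    age: np.ndarray  # 75..110
    annual_risk: np.ndarray
    stage_probs: StageDistribution

    def __post_init__(self) -> None:
        if np.any((self.annual_risk < 0) | (self.annual_risk > 1)):
            raise ParameterError("annual risks must lie in [0,1]")
        past90 = self.age > INCIDENCE_FLAT_AGE
        if past90.any() and not np.allclose(
            self.annual_risk[past90], self.annual_risk[past90][0]
        ):
            raise ParameterError("incidence must be constant beyond age 90")

    def risk_at(self, age: int) -> float:
        a = int(np.clip(age, self.age[0], self.age[-1]))
        return float(self.annual_risk[a - int(self.age[0])])


def read_hmd_lifetable(path, year: int, sex: str = "female") -> LifeTable:
    """Read one year from an HMD 1x1 period life table file.

    Accepts the standard whitespace layout with a ``Year Age mx qx ...``
    header; the terminal ``110+`` age token maps to age 110. Only female
    period tables (fltper_1x1) are supported.
    """
    if sex != "female":
        raise ParameterError("only female period tables are supported")
    ages, qxs = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 4 or not parts[0].isdigit():
                continue  # headers, blank lines
            if int(parts[0]) != year:
                continue
            tok = parts[1]
            age = 110 if tok.endswith("+") else int(tok)
            try:
                qx = float(parts[3])
            except ValueError as e:
                raise ParameterError(f"malformed qx {parts[3]!r} at age {tok}") from e
            ages.append(age)
            qxs.append(qx)
    if not ages:
        raise LookupError(f"year {year} not found in {path}")
    order = np.argsort(ages)
    return LifeTable(np.asarray(ages)[order], np.asarray(qxs)[order])


def synth_lifetable(
    a: float = 7e-6,
    b: float = 0.106,
    max_age: int = 110,
    seed: int | None = None,
) -> LifeTable:
    """Synthetic female period life table with Gompertz mortality.

    Defaults give qx(40) = 0.0005 and life expectancy at 40 of ~45.8 years,
    in line with a recent Swedish female period table. Deterministic:
    ``seed`` is accepted for interface uniformity but unused.
    """
    if a <= 0 or b < 0:
        raise ParameterError("Gompertz parameters must be positive")
    ages = np.arange(0, max_age + 1)
    qx = np.minimum(1.0, a * np.exp(b * ages))
    qx[-1] = 1.0  # table closes out at the terminal age
    return LifeTable(ages, qx)


def synth_utilities(
    base_at_40: float = 0.87,
    slope: float = 0.003,
    max_age: int = 110,
) -> UtilityCurve:
    """Linearly declining population utility curve, floored and frozen.

    ``weight(age) = base_at_40 - slope * (age - 40)``, floored at 0.5 and
    held at the age-88 value for ages 88+. Defaults emulate Swedish EQ-5D
    population norms (0.87 at 40, 0.726 at 88).
    """
    if not 0 < base_at_40 <= 1:
        raise ParameterError("base utility must lie in (0,1]")
    if slope < 0:
        raise ParameterError("slope must be non-negative")
    ages = np.arange(0, max_age + 1)
    w = np.maximum(0.5, base_at_40 - slope * (ages - 40))
    w = np.minimum(w, 1.0)
    w[ages >= UTILITY_FREEZE_AGE] = w[ages == UTILITY_FREEZE_AGE]
    return UtilityCurve(ages, w)


def synth_post75_incidence(
    level: float = 0.0035,
    stage_probs: StageDistribution | None = None,
    max_age: int = 110,
    seed: int | None = None,
) -> IncidenceCurve:
    """Synthetic post-screening breast cancer incidence curve.

    Risks ramp gently (+/-10%) around ``level`` across ages 75-90 and are
    constant at the 75-90 average beyond age 90. An optional ``seed`` adds
    small reproducible age-to-age jitter (3% of level) to mimic registry
    noise; by default the curve is smooth.
    """
    if not 0 <= level < 0.02:
        raise ParameterError("incidence level must lie in [0, 0.02)")
    if stage_probs is None:
        from .params import default_cancer_params

        stage_probs = default_cancer_params().stage_dist("post75", "75plus")
    ages = np.arange(75, max_age + 1)
    risks = np.empty(len(ages), dtype=float)
    ramp_ages = np.arange(75, INCIDENCE_FLAT_AGE + 1)
    ramp = level * (1.0 + 0.10 * (ramp_ages - ramp_ages.mean()) / 7.5)
    if seed is not None and level > 0:
        rng = np.random.default_rng(seed)
        ramp = np.clip(ramp + rng.normal(0, 0.03 * level, len(ramp)), 0, 1)
    n_ramp = len(ramp_ages)
    risks[:n_ramp] = ramp
    risks[n_ramp:] = ramp.mean()
    return IncidenceCurve(ages, risks, stage_probs)
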