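# Methods

## Model structure

The model is a discrete-time state-transition (Markov) cohort model with
annual cycles, run from age 40 to a terminal age of 110 for a cohort of
1000 women, from a healthcare perspective. The state space is

* `Healthy`;
* `Cancer(s, t)` for stages s ∈ {0, I, II, III} and tunnel year
  t = 1…9 plus one beyond-horizon slot — *t* counts years since
  diagnosis, so that metastasis risk, cancer cost, and quality-of-life
  (QOL) decrement can depend on time since the event;
* `Metastatic(t)`, the stage IV tunnel (entered either at detection of a
  stage IV cancer or by progression), the only state carrying a breast
  cancer-specific death risk;
* `DeadBC` and `DeadOther`, absorbing.

Breast cancer mortality therefore flows exclusively through the
metastatic state; stages 0–III kill only via the progression →
metastasis → death chain. Stage 0 cannot metastasise by definition, and
carries cost and decrement only in its first year.

### Within-cycle event order

Events within a cycle are applied sequentially, in this order:

1. **Screening** (biennial, ages 40–74, 100% adherence): only `Healthy`
   occupants attend — diagnosed women leave the screening pool. Detected
   mass moves into the stage tunnels at year 1 using the age band's
   screen-detected stage distribution (stage IV goes straight to
   `Metastatic(1)`). All attendees incur invitation, mammography, AI
   licence (AI arms), human-reading, conference and recall resource use.
2. **Other-cause death**: the life-table probability q(age) applied to
   every alive state.
3. **Spontaneous incidence** from `Healthy`: the annual interval-cancer
   risk (ages 40–74, every cycle including screening years) with the
   interval stage distribution, or the registry-style incidence curve
   with its own stage distribution from age 75.
4. **Distant metastasis**: `Cancer(s, t)` → `Metastatic(1)` with the
   stage- and year-specific annual risk.
5. **Breast-cancer death**: `Metastatic(t)` → `DeadBC` with the
   year-specific risk. Because substeps are sequential, mass that
   metastasises in a cycle faces the year-1 death risk in that same
   cycle.
6. **Payoff accrual** on the post-event occupancy: cycle cost
   = Σ occupancy × cost(state, t); cycle QALYs = Σ occupancy ×
   max(0, utility(age) − decrement(state, t)). Both are discounted by
   (1+r)^(−cycle) with cycle 0 at age 40. Event counts are reported
   undiscounted. No half-cycle correction is applied.
7. **Tunnel increment**, capped at the beyond-horizon slot.

Mass conservation is asserted every cycle at 1e-9 relative tolerance;
residual alive mass at the terminal age is absorbed after the last cycle
without further payoffs.

### Beyond the nine scheduled years

The tunnel schedules print nine annual values. Beyond year 9 the model
carries the year-9 values forward for metastasis risk, metastatic death
risk, and QOL decrements (mirroring the schedules' own carry-forward of
their year-5 values), and for the metastatic cost, for which no long-term
data exist. The stage I–III follow-up cost (€3,489/yr), however, ends
with the schedule: long-term survivors of early-stage cancer stop
accruing cancer cost after nine years. This choice reproduces the
reference accounting of stage-specific lifetime costs, which a perpetual
follow-up cost overshoots by roughly a factor of two. It is implemented
as a tenth "beyond-horizon" tunnel slot.

## Parameters

All fixed inputs live in two packaged CSV tables (2023 EUR throughout).

**Reading policy and screening proportions.** The AI arm double-reads 30%
of exams (AI score triage), the conventional arm 100%; conference
proportions 4.0%/3.9% (Beta(1475, 35403)/Beta(1404, 34590)); recall
proportions 3.5% (40–54) and 2.5% (55–74), shared between arms. Each
conference consumes two extra reader-units, so expected human readings
per exam are 1.3 + 2×0.040 = 1.38 (AI arm) and 2 + 2×0.039 = 2.078
(conventional).

**Detection chain.** Overall biennial screen-detection risks are Beta
means: 222/36,391 = 0.61% (AI) and 203/39,779 = 0.51% (conventional).
The 40–54 band applies a 0.53 multiplier (47% lower detection) to the
unrounded mean; the 55–74 band values (0.86%/0.72%) are taken as printed,
since the 1.40 multiplier on the unrounded mean lands one final digit
away from the printed figures and the original rounding path is not
recoverable. Interval-cancer risk follows by subtraction: interval
cancers are 29.5% of all cancers over a two-year period, the total is
anchored on the conventional arm
(total = cdm_detect/(1 − 0.295)), and a strategy's interval risk is
(total − strategy_detect)/2 per year. Division by two, rather than the
compounding conversion 1 − √(1 − p), reproduces all four printed annual
interval risks (0.03/0.06/0.08/0.15%) at printed precision. Scenario
detection multipliers feed this same rule, so reduced screen detection
surfaces as extra interval cancers and total cancers are conserved.

**Unit costs.** Invitation €0.7, mammography €30.5, screen reading
€79.0/h ÷ 29 exams/h = €2.7 (Gamma, SD 0.5), AI licence €1.9/exam,
conference €5.4 (Gamma, SD 1.1), recall €370.8 plus one invitation,
outsourced reading €4.8 (scenario S4). Costs marked fixed are point
masses in the PSA.

**Economic settings.** 3% annual discount rate for costs and effects;
willingness-to-pay threshold €50,000/QALY; cohort 1000; horizon to age
110.

## External inputs and their synthetic stand-ins

Three inputs are national data that ship with the package only as
calibrated synthetic stand-ins (a real HMD 1×1 life table file is read
directly when supplied):

* **Other-cause mortality** — Gompertz hazard q(age) = min(1, a·e^{b·age})
  with a = 7×10⁻⁶, b = 0.106, giving q(40) = 0.00049, q(85) = 0.057 and a
  remaining life expectancy at 40 of 45.8 years, matching a recent Swedish
  female period table to within half a year.
* **Population utilities** — linear decline from 0.87 at age 40 by
  0.003/yr, floored at 0.5, and frozen at the age-88 value (0.726) for
  all older ages, the same freeze rule applied to published Swedish
  population norms.
* **Post-75 incidence** — 0.35%/yr with a gentle ±10% age ramp over
  75–90 and the 75–90 average held constant beyond 90, using the 75+
  stage distribution at detection.

What the stand-ins do *not* emulate: the exact age profile of Swedish
mortality (a one-parameter-pair Gompertz is slightly heavy in mid-life),
the non-linear shape of empirical utility norms, and year-to-year
registry noise in incidence. Consequently absolute totals (life-years,
QALYs, total costs) carry a few percent of input error, and quantities
that are *differences of near-equal totals* inherit more relative
uncertainty the closer they are to zero — the break-even age, the zero
crossing of a cumulative difference worth ~0.02% of total cost at the
relevant ages, is the most sensitive output of all and can shift by a few
years relative to a real-data run. Incremental costs and QALYs
themselves are dominated by the packaged detection and stage-distribution
tables and are far more stable. Passing tests on the synthetic fixture
therefore validate the mechanics and the packaged-parameter arithmetic,
not the Swedish calibration itself.

## Probabilistic sensitivity analysis

Each draw samples, independently:

* detection risks and conference proportions per arm, and recall
  proportions, from their Beta(α, β) count-based shapes; the printed
  55–74 detection scales proportionally with the sampled overall risk,
  and the interval-risk subtraction is re-derived per draw (floored at
  zero in the rare draws where the AI arm's sampled detection exceeds the
  implied total);
* screen-reading and conference unit costs from Gamma (method of
  moments on mean/SD);
* tunnel risks (metastasis by stage-year, metastatic death by year) from
  Beta with count-based shapes α = r·n, β = (1−r)·n using the source
  cohort sizes behind the estimates (11,459 / 5,916 / 433 patients for
  stages I–III; 977 for metastatic deaths);
* grouped cancer costs (first-year €12,652, follow-up €3,489, metastatic
  €22,752) from Gamma and grouped QOL decrements (0.018 / 0.077 / 0.099)
  from Beta, both method-of-moments with an assumed 20% coefficient of
  variation — no dispersion is published for these; the CVs are
  arguments of `fit_psa`.

Common parameters are shared between the two arms within a draw, so
draw-to-draw variation reflects strategy differences rather than sampling
noise. Draws are classified on the CE plane as dominant (ΔC < 0, ΔQ > 0),
less effective (ΔQ ≤ 0), or more effective and more costly; the CEAC
reports the share of draws with positive net monetary benefit λ·ΔQ − ΔC
on a WTP grid (€0–100k in €5k steps).

## Numerical choices and conventions

* Mass-conservation tolerance 1e-9 (relative), enforced every cycle.
* Break-even tie rule: the *first* age at which cumulative discounted
  incremental cost is ≤ 0, inclusive — identical arms break even at the
  start age.
* ICER undefined (None) at ΔQ = 0; dominance labels by CE-plane quadrant.
* Stage distributions are renormalised to sum to one exactly (printed
  columns round to 0.1 pp; a deviation above 0.5 pp raises).
* Negative effective utilities (utility − decrement) clamp at zero.
* Screen-reading unit cost is reported and used at one decimal
  (79.0/29 → 2.7), matching its role as a unit price.
* All randomness flows through `numpy.random.default_rng(seed)`; a fixed
  seed reproduces PSA draws bit-for-bit.

## Problem sizes used in validation

The test suite validates the cohort engine against an independent
individual-level Monte Carlo simulator (200,000 women, fixed seed,
agreement within 3 standard errors on lifetime discounted cost and
QALYs), checks the zero-risk limit against the closed-form discounted
utility-weighted survivorship at 1e-9, and runs the PSA at its full 1000
draws. The deterministic model itself is cheap (~30 ms per arm), so all
base-case and scenario checks run at full size.

## Known limitations

* No overdiagnosis or lead-time bias modelling; extra screen-detected
  cancers are real cancers that would otherwise surface as interval
  cancers (total cancers fixed by the subtraction rule).
* 100% screening adherence; no individual-level risk heterogeneity.
* Breast-cancer death only from the metastatic state — early-stage
  cancers carry no direct excess mortality.
* One-year cycles without half-cycle correction slightly front-load
  payoffs relative to continuous time; both arms are affected alike.
* Independent PSA sampling (no correlation structure between
  parameters).
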