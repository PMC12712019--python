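"""Independent individual-level Monte Carlo simulator.

Used as an oracle against the expected-value cohort engine: it propagates
each simulated woman separately with the same per-cycle probabilities and
payoff rules, using its own state coding and bookkeeping (no code shared
with ``mammocea.engine``). With a large sample its mean discounted cost
and QALYs per 1000 women must agree with the cohort engine within Monte
Carlo error.
"""

from __future__ import annotations

import numpy as np

from mammocea.params import MAX_TUNNEL, STAGES

# state coding (deliberately different from the engine's dense index):
HEALTHY = 0
DEAD_OTHER = 1
DEAD_BC = 2
METASTATIC = 3
CANCER0 = 4  # 4..7 = cancer stages 0, I, II, III
_TUNNEL_CAP = MAX_TUNNEL + 1  # beyond-horizon slot, as in the engine


def simulate_individuals(arm, cancer, lt, utilities, inc75, settings, costs,
                         n: int, seed: int):
    """Simulate ``n`` women; return per-person discounted (cost, qaly) arrays."""
    rng = np.random.default_rng(seed)
    state = np.full(n, HEALTHY, dtype=np.int8)
    tyear = np.zeros(n, dtype=np.int8)
    cost = np.zeros(n)
    qaly = np.zeros(n)

    # per (stage, tunnel-year) lookups, years 1.._TUNNEL_CAP
    def table(fn):
        return np.array([[fn(s, t) for t in range(1, _TUNNEL_CAP + 1)]
                         for s in STAGES])

    cost_tab = table(lambda s, t: cancer.tunnel(s).cost(t))
    dec_tab = table(lambda s, t: cancer.tunnel(s).qol_decrement(t))
    met_tab = table(lambda s, t: cancer.tunnel(s).metastasis_risk(t))
    death_iv = np.array([cancer.tunnel("IV").bc_death_risk(t)
                         for t in range(1, _TUNNEL_CAP + 1)])

    unit = arm.reading_unit_cost
    r = settings.discount_rate
    for cycle, age in enumerate(range(settings.start_age, settings.terminal_age + 1)):
        disc = (1.0 + r) ** (-cycle)
        band = "40_54" if age < 55 else "55_74"

        if age in arm.screening_ages:
            att = state == HEALTHY
            reads = arm.human_read_share + arm.double_read_share
            per_att = (
                costs.invitation + costs.mammography
                + (costs.ai_licence_per_exam if arm.uses_ai else 0.0)
                + unit * reads
                + arm.conference_prop * (costs.conference_unit + 2.0 * unit)
                + arm.recall_props[band] * (costs.invitation + costs.recall_unit)
            )
            cost[att] += per_att * disc
            det = att & (rng.random(n) < arm.detection_biennial[band])
            k = int(det.sum())
            if k:
                dist = cancer.stage_dist("screening", band)
                picks = rng.choice(len(STAGES), size=k, p=dist.probs)
                new_state = np.where(picks == STAGES.index("IV"),
                                     METASTATIC, CANCER0 + picks)
                state[det] = new_state
                tyear[det] = 1

        # other-cause mortality
        alive = state != DEAD_OTHER
        alive &= state != DEAD_BC
        die = alive & (rng.random(n) < lt.qx_at(age))
        state[die] = DEAD_OTHER

        # spontaneous incidence
        healthy = state == HEALTHY
        if age < 75:
            risk = arm.interval_annual[band]
            dist = cancer.stage_dist("interval", band)
        else:
            risk = inc75.risk_at(age)
            dist = inc75.stage_probs
        new = healthy & (rng.random(n) < risk)
        k = int(new.sum())
        if k:
            picks = rng.choice(len(STAGES), size=k, p=dist.probs)
            state[new] = np.where(picks == STAGES.index("IV"),
                                  METASTATIC, CANCER0 + picks)
            tyear[new] = 1

        # distant metastasis from the stage tunnels
        u = rng.random(n)
        for si, stage in enumerate(STAGES[:4]):
            mask = state == CANCER0 + si
            if not mask.any():
                continue
            p = met_tab[si, tyear[mask] - 1]
            prog = np.zeros(n, bool)
            prog[mask] = u[mask] < p
            state[prog] = METASTATIC
            tyear[prog] = 1

        # breast-cancer death from the metastatic tunnel
        met = state == METASTATIC
        if met.any():
            p = death_iv[tyear[met] - 1]
            dead = np.zeros(n, bool)
            dead[met] = rng.random(int(met.sum())) < p
            state[dead] = DEAD_BC

        # accrue payoffs on post-event states
        uw = utilities.weight_at(age)
        qaly[state == HEALTHY] += uw * disc
        for si, stage in enumerate(STAGES[:4]):
            mask = state == CANCER0 + si
            if not mask.any():
                continue
            ty = tyear[mask] - 1
            cost[mask] += cost_tab[si, ty] * disc
            qaly[mask] += np.maximum(0.0, uw - dec_tab[si, ty]) * disc
        met = state == METASTATIC
        if met.any():
            ty = tyear[met] - 1
            iv = STAGES.index("IV")
            cost[met] += cost_tab[iv, ty] * disc
            qaly[met] += np.maximum(0.0, uw - dec_tab[iv, ty]) * disc

        # tunnel increment
        in_tunnel = (state == METASTATIC) | (state >= CANCER0)
        tyear[in_tunnel] = np.minimum(tyear[in_tunnel] + 1, _TUNNEL_CAP)

    return cost, qaly
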