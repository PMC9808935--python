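"""Lifetime nine-state Markov cohort engine.

Transition structure per cycle: every alive state carries the same
probability of death (the model's identical-death assumption); non-stroke
NYHA states move to their post-stroke counterpart with the annualized
major-stroke probability, composed multiplicatively on survivors; NYHA
class is otherwise frozen (no inter-class drift); post-stroke states never
revert; death is absorbing.

Rewards accrue at end-of-cycle on the end-of-cycle occupancy, discounted
at the annual rate with exponent equal to the cycle index (an optional
half-cycle correction averages successive occupancy rows instead). The
stroke disutility is deferred during the first long-term cycle (the
rehabilitation year) and applied as an absolute decrement floored at zero
from cycle 2 on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .acute import StateDistribution, acute_cost, entry_distribution
from .parameters import ModelConfig, annual_event_prob, prob_over_period
from .states import (
    ALIVE_INDICES,
    DEAD_INDEX,
    N_STATES,
    NYHA_INDICES,
    STATES,
    Arm,
)


@dataclass(frozen=True)
class TransitionMatrix:
    cycle: int
    matrix: np.ndarray


@dataclass
class CohortTrace:
    """Occupancy per cycle: rows 0..stop_cycle, columns in canonical state order."""

    occupancy: np.ndarray
    stop_cycle: int
    converged: bool
    warnings: list[str] = field(default_factory=list)

    @property
    def survival(self) -> np.ndarray:
        return 1.0 - self.occupancy[:, DEAD_INDEX]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=[s.value for s in STATES])
        df.insert(0, "cycle", np.arange(self.occupancy.shape[0]))
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class RewardVector:
    cycle: int
    qaly: np.ndarray
    cost: np.ndarray


@dataclass
class ArmResult:
    """Discounted lifetime cost and QALYs per patient for one strategy."""

    arm: Arm
    discounted_cost: float
    discounted_qalys: float
    life_years: float = float("nan")
    trace: Optional[CohortTrace] = None


def discount_factor(cycle: int, rate: float) -> float:
    """Annual discount factor 1/(1+rate)^cycle."""
    if cycle < 0:
        raise ValueError(f"cycle must be non-negative, got {cycle}")
    if rate < 0:
        raise ValueError(f"discount rate must be non-negative, got {rate}")
    return (1.0 + rate) ** (-cycle)


def death_probability(arm: Arm, cycle: int, cfg: ModelConfig) -> float:
    """Per-cycle all-cause death probability shared by every alive state.

    Cycle 1 uses the entry-cohort annual death probability; later cycles
    follow the long-term mortality knob (held constant by default, or taken
    from a user table). An explicit ``annual_death_override`` replaces the
    value for every cycle.
    """
    if cycle < 1:
        raise ValueError(f"cycle must be >= 1, got {cycle}")
    knobs = cfg.knobs
    p_entry = cfg.entry.for_arm(arm).death
    if knobs.annual_death_override is not None:
        p_annual = knobs.annual_death_override
    elif cycle == 1 or knobs.longterm_death_mode == "CONSTANT_YEAR1":
        p_annual = p_entry
    else:  # USER_TABLE, cycle >= 2
        table = (knobs.death_table or {}).get(arm.value, [])
        p_annual = p_entry
        for from_cycle, prob in table:
            if cycle >= from_cycle:
                p_annual = prob
    return prob_over_period(p_annual, cfg.econ.cycle_length_years)


def build_transition_matrix(arm: Arm, cycle: int, cfg: ModelConfig) -> TransitionMatrix:
    p_death = death_probability(arm, cycle, cfg)
    p_stroke_annual = annual_event_prob(cfg, arm, "stroke")
    p_stroke = prob_over_period(p_stroke_annual, cfg.econ.cycle_length_years)

    m = np.zeros((N_STATES, N_STATES))
    stay = (1.0 - p_death) * (1.0 - p_stroke)
    to_stroke = (1.0 - p_death) * p_stroke
    for k in NYHA_INDICES:
        m[k, k] = stay
        m[k, k + 4] = to_stroke
        m[k, DEAD_INDEX] = p_death
    for k in (4, 5, 6, 7):
        m[k, k] = 1.0 - p_death
        m[k, DEAD_INDEX] = p_death
    m[DEAD_INDEX, DEAD_INDEX] = 1.0

    if (m < 0).any() or (m > 1).any():  # guards composed probabilities
        bad = np.argwhere((m < 0) | (m > 1))[0]
        raise ValueError(
            f"transition probability out of [0,1] at cycle {cycle}, "
            f"state {STATES[bad[0]].value}"
        )
    return TransitionMatrix(cycle=cycle, matrix=m)


def per_cycle_event_cost(arm: Arm, cycle: int, cfg: ModelConfig) -> float:
    """Expected recurring event cost per alive patient for one cycle."""
    length = cfg.econ.cycle_length_years
    total = 0.0
    for item in cfg.costs:
        for a in item.assignment:
            if a.arm != arm.value or a.phase != "PER_CYCLE_EVENT":
                continue
            if (
                a.event == "rehospitalization"
                and not cfg.knobs.rehospitalization_recurring
                and cycle > 1
            ):
                continue
            p_annual = annual_event_prob(cfg, arm, a.event)
            total += a.weight * prob_over_period(p_annual, length) * item.mean
    return total


def state_utilities(arm: Arm, cycle: int, cfg: ModelConfig) -> np.ndarray:
    """Per-state utility weights for one cycle (stroke decrement from cycle 2)."""
    u = cfg.utilities.mean_by_nyha.as_tuple()
    d = cfg.utilities.stroke_disutility if cycle >= 2 else 0.0
    values = np.zeros(N_STATES)
    values[0:4] = u
    values[4:8] = [max(0.0, uk - d) for uk in u]
    return values


def cycle_rewards(arm: Arm, cycle: int, cfg: ModelConfig) -> RewardVector:
    if cycle < 1:
        raise ValueError(f"cycle must be >= 1, got {cycle}")
    length = cfg.econ.cycle_length_years
    qaly = state_utilities(arm, cycle, cfg) * length
    cost = np.zeros(N_STATES)
    cost[list(ALIVE_INDICES)] = per_cycle_event_cost(arm, cycle, cfg)
    return RewardVector(cycle=cycle, qaly=qaly, cost=cost)


def run_cohort(entry: StateDistribution, arm: Arm, cfg: ModelConfig) -> CohortTrace:
    """Propagate the cohort until (almost) nobody is left alive.

    Stops at ``max_cycles`` or when survival drops below
    ``survival_stop_epsilon``, whichever comes first.
    """
    eps = cfg.econ.survival_stop_epsilon
    rows = [np.asarray(entry.probs, dtype=float)]
    converged = 1.0 - rows[0][DEAD_INDEX] < eps
    t = 0
    while not converged and t < cfg.econ.max_cycles:
        t += 1
        tm = build_transition_matrix(arm, t, cfg)
        rows.append(rows[-1] @ tm.matrix)
        converged = 1.0 - rows[-1][DEAD_INDEX] < eps
    warnings = []
    if not converged:
        warnings.append(
            f"survival {1.0 - rows[-1][DEAD_INDEX]:.3g} still above "
            f"epsilon {eps} after max_cycles={cfg.econ.max_cycles}"
        )
    return CohortTrace(
        occupancy=np.vstack(rows), stop_cycle=t, converged=converged, warnings=warnings
    )


def accumulate(trace: CohortTrace, arm: Arm, cfg: ModelConfig) -> ArmResult:
    """Discounted lifetime cost and QALYs from a cohort trace.

    QALYs and recurring costs sum end-of-cycle occupancy times rewards,
    discounted per cycle; acute cost enters undiscounted at time zero.
    """
    occ = trace.occupancy
    n_cycles = occ.shape[0] - 1
    length = cfg.econ.cycle_length_years
    # effective per-cycle rate so the exponent stays the cycle index
    rate_eff = (1.0 + cfg.econ.discount_rate) ** length - 1.0

    qalys = 0.0
    recurring = 0.0
    life_years = 0.0
    for t in range(1, n_cycles + 1):
        rewards = cycle_rewards(arm, t, cfg)
        row = occ[t]
        if cfg.econ.half_cycle_correction:
            row = 0.5 * (occ[t - 1] + occ[t])
        df = discount_factor(t, rate_eff)
        qalys += df * float(row @ rewards.qaly)
        recurring += df * float(row @ rewards.cost)
        life_years += float(1.0 - row[DEAD_INDEX]) * length

    cost = acute_cost(arm, cfg).expected_cost + recurring
    return ArmResult(
        arm=arm,
        discounted_cost=cost,
        discounted_qalys=qalys,
        life_years=life_years,
        trace=trace,
    )


def run_arm(arm: Arm, cfg: ModelConfig) -> ArmResult:
    """Entry distribution → cohort trace → discounted accumulation, one arm."""
    entry = entry_distribution(arm, cfg)
    trace = run_cohort(entry, arm, cfg)
    return accumulate(trace, arm, cfg)
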