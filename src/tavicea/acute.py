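"""The 30-day decision-tree stage.

Computes each arm's entry distribution into the Markov model (the printed
twelve-month NYHA/death split; acute strokes are costed as events, the
stroke-state split begins in the Markov stage) and the acute per-patient
cost: procedure-phase items in full plus event-triggered items weighted by
the trial-horizon event probabilities. Patients who die acutely still
accrue the full procedure-phase cost but no QALYs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .parameters import ConfigError, ModelConfig
from .states import DEAD_INDEX, N_STATES, Arm


@dataclass(frozen=True)
class StateDistribution:
    """Probability mass over the nine health states (canonical order)."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (N_STATES,):
            raise ValueError(f"expected {N_STATES} state probabilities, got {p.shape}")
        if (p < -1e-12).any():
            raise ValueError("negative state probability")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"state probabilities sum to {p.sum()!r}, expected 1")
        object.__setattr__(self, "probs", p)


@dataclass
class AcuteCost:
    arm: Arm
    expected_cost: float
    breakdown: dict[str, float] = field(default_factory=dict)


def entry_distribution(arm: Arm, cfg: ModelConfig) -> StateDistribution:
    """Distribution over states at entry to the long-term model (cycle 0 row)."""
    e = cfg.entry.for_arm(arm)
    probs = np.zeros(N_STATES)
    probs[0:4] = (e.NYHA1, e.NYHA2, e.NYHA3, e.NYHA4)
    probs[DEAD_INDEX] = e.death
    return StateDistribution(probs=probs)


def acute_cost(arm: Arm, cfg: ModelConfig) -> AcuteCost:
    """Expected acute (procedure + perioperative event) cost per patient.

    PROCEDURE items accrue in full; ACUTE_EVENT items accrue once, weighted
    by the (cumulative, trial-horizon) probability of their triggering event
    in this arm. PER_CYCLE_EVENT items belong to the Markov stage and are
    ignored here.
    """
    breakdown: dict[str, float] = {}
    for item in cfg.costs:
        for a in item.assignment:
            if a.arm != arm.value:
                continue
            if a.phase == "PROCEDURE":
                contrib = a.weight * item.mean
            elif a.phase == "ACUTE_EVENT":
                if a.event is None:  # defensive; schema already enforces this
                    raise ConfigError(
                        f"cost item {item.name!r}: ACUTE_EVENT without an event"
                    )
                p = cfg.events.for_arm(arm)[a.event]
                contrib = a.weight * p * item.mean
            else:
                continue
            breakdown[item.name] = breakdown.get(item.name, 0.0) + contrib
    return AcuteCost(
        arm=arm,
        expected_cost=math.fsum(breakdown.values()),
        breakdown=breakdown,
    )
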