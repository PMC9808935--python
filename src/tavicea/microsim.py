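"""Patient-level Monte-Carlo simulator over the identical state process.

Serves two purposes: it is the synthetic-data generator (event logs with
exactly the state-transition structure the cohort model assumes) and the
independent validation oracle for the cohort engine — both consume the same
entry distribution, transition matrices, rewards and discounting, so the
cohort expectation must match the microsimulation mean up to Monte-Carlo
error.

Randomness: each patient owns an independently seeded substream derived
from the master seed and the patient index, so enlarging the cohort never
perturbs earlier patients. Every patient pre-draws a fixed block of
uniforms (entry draw, then one transition draw and one draw per recurring
cost item per cycle) and the walk consumes a prefix of it; this makes the
single-patient and the vectorized cohort paths bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .acute import acute_cost, entry_distribution
from .markov import build_transition_matrix, cycle_rewards, discount_factor
from .parameters import ModelConfig, annual_event_prob, prob_over_period
from .states import DEAD_INDEX, N_STATES, STATES, Arm

EVENT_LOG_COLUMNS = (
    "patient_id",
    "arm",
    "cycle",
    "state",
    "event",
    "cost_irr",
    "qaly",
)


@dataclass
class PatientPath:
    patient_id: int
    arm: Arm
    #: state index per cycle, ending at DEAD or the horizon
    states: list[int]
    cost_discounted: float
    qalys_discounted: float
    cost_undiscounted: float
    qalys_undiscounted: float
    #: one record per cycle: (cycle, state index, event names, discounted
    #: cost accrued that cycle, discounted QALYs accrued that cycle)
    cycle_records: list[tuple[int, int, str, float, float]] = field(
        default_factory=list
    )


@dataclass
class CohortEstimate:
    """Monte-Carlo aggregate of patient paths for one arm."""

    arm: Arm
    n: int
    seed: int
    mean_cost: float
    se_cost: float
    mean_qalys: float
    se_qalys: float
    #: empirical state-occupancy fractions, rows = cycles, cols = states
    occupancy: np.ndarray
    paths: Optional[list[PatientPath]] = None


def patient_rng(seed: int, patient_id: int) -> np.random.Generator:
    """The independent substream owned by one patient."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(patient_id,)))


def _recurring_items(arm: Arm, cfg: ModelConfig) -> list[tuple[str, str, float, float]]:
    """(item name, event, accrued cost on hit, per-cycle probability) in
    deterministic config order."""
    length = cfg.econ.cycle_length_years
    out = []
    for item in cfg.costs:
        for a in item.assignment:
            if a.arm != arm.value or a.phase != "PER_CYCLE_EVENT":
                continue
            p_cyc = prob_over_period(annual_event_prob(cfg, arm, a.event), length)
            out.append((item.name, a.event, a.weight * item.mean, p_cyc))
    return out


def _draw_block_width(cfg: ModelConfig, n_items: int) -> int:
    return 1 + cfg.econ.max_cycles * (1 + n_items)


def _walk(
    arm: Arm,
    cfg: ModelConfig,
    uniforms: np.ndarray,
    keep_detail: bool = False,
) -> dict:
    """Vectorized walk of ``uniforms.shape[0]`` patients through the model."""
    n = uniforms.shape[0]
    t_max = cfg.econ.max_cycles
    length = cfg.econ.cycle_length_years
    rate_eff = (1.0 + cfg.econ.discount_rate) ** length - 1.0
    items = _recurring_items(arm, cfg)
    k = len(items)

    cum_entry = np.cumsum(entry_distribution(arm, cfg).probs)
    states = np.full((n, t_max + 1), DEAD_INDEX, dtype=np.int64)
    states[:, 0] = np.searchsorted(cum_entry, uniforms[:, 0], side="left")

    acute = acute_cost(arm, cfg).expected_cost
    cost_d = np.full(n, acute)
    cost_u = np.full(n, acute)
    qaly_d = np.zeros(n)
    qaly_u = np.zeros(n)
    hits = (
        np.zeros((n, t_max + 1, k), dtype=bool) if keep_detail and k else None
    )
    cost_by_cycle = np.zeros((n, t_max + 1)) if keep_detail else None
    qaly_by_cycle = np.zeros((n, t_max + 1)) if keep_detail else None
    if keep_detail:
        cost_by_cycle[:, 0] = acute

    last_cycle = np.zeros(n, dtype=np.int64)
    for t in range(1, t_max + 1):
        cur = states[:, t - 1]
        alive = cur != DEAD_INDEX
        if not alive.any():
            break
        base = 1 + (t - 1) * (1 + k)
        cum_rows = np.cumsum(build_transition_matrix(arm, t, cfg).matrix, axis=1)
        nxt = cur.copy()
        nxt[alive] = np.sum(
            uniforms[alive, base, None] >= cum_rows[cur[alive]], axis=1
        )
        states[:, t] = nxt
        alive_end = nxt != DEAD_INDEX
        last_cycle[alive] = t

        df = discount_factor(t, rate_eff)
        rewards = cycle_rewards(arm, t, cfg)
        utilities = rewards.qaly[nxt]
        qaly_d += df * utilities
        qaly_u += utilities
        if keep_detail:
            qaly_by_cycle[:, t] = df * utilities

        for j, (_name, _event, amount, p_cyc) in enumerate(items):
            if (
                _event == "rehospitalization"
                and not cfg.knobs.rehospitalization_recurring
                and t > 1
            ):
                continue
            u_ev = uniforms[:, base + 1 + j]
            hit = alive_end & (u_ev < p_cyc)
            cost_d += df * amount * hit
            cost_u += amount * hit
            if keep_detail:
                hits[:, t, j] = hit
                cost_by_cycle[:, t] += df * amount * hit

    return {
        "states": states,
        "last_cycle": last_cycle,
        "cost_discounted": cost_d,
        "cost_undiscounted": cost_u,
        "qalys_discounted": qaly_d,
        "qalys_undiscounted": qaly_u,
        "items": items,
        "hits": hits,
        "cost_by_cycle": cost_by_cycle,
        "qaly_by_cycle": qaly_by_cycle,
    }


def _extract_path(
    walk: dict, row: int, patient_id: int, arm: Arm
) -> PatientPath:
    states_row = walk["states"][row]
    last = int(walk["last_cycle"][row])
    # keep states up to the first DEAD (inclusive) or the horizon
    end = last if states_row[last] != DEAD_INDEX else last
    seq = list(states_row[: last + 1])
    if states_row[last] == DEAD_INDEX and last > 0:
        pass  # sequence already ends at DEAD
    records = []
    items = walk["items"]
    for t in range(0, last + 1):
        if walk["hits"] is not None:
            names = [items[j][1] for j in range(len(items)) if walk["hits"][row, t, j]]
        else:
            names = []
        records.append(
            (
                t,
                int(states_row[t]),
                ";".join(names),
                float(walk["cost_by_cycle"][row, t]),
                float(walk["qaly_by_cycle"][row, t]),
            )
        )
    return PatientPath(
        patient_id=patient_id,
        arm=arm,
        states=[int(s) for s in seq],
        cost_discounted=float(walk["cost_discounted"][row]),
        qalys_discounted=float(walk["qalys_discounted"][row]),
        cost_undiscounted=float(walk["cost_undiscounted"][row]),
        qalys_undiscounted=float(walk["qalys_undiscounted"][row]),
        cycle_records=records,
    )


def simulate_patient(
    arm: Arm,
    cfg: ModelConfig,
    draw_source: np.random.Generator,
    patient_id: int = 0,
) -> PatientPath:
    """Simulate a single patient path from a seeded random stream."""
    k = len(_recurring_items(arm, cfg))
    uniforms = draw_source.random(_draw_block_width(cfg, k))[None, :]
    walk = _walk(arm, cfg, uniforms, keep_detail=True)
    return _extract_path(walk, 0, patient_id, arm)


def simulate_cohort(
    arm: Arm,
    cfg: ModelConfig,
    n: int,
    seed: int,
    keep_paths: bool = False,
) -> CohortEstimate:
    """Simulate ``n`` patients and aggregate into mean cost/QALYs with SEs."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    k = len(_recurring_items(arm, cfg))
    width = _draw_block_width(cfg, k)
    uniforms = np.empty((n, width))
    for i in range(n):
        uniforms[i] = patient_rng(seed, i).random(width)
    walk = _walk(arm, cfg, uniforms, keep_detail=keep_paths)

    cost = walk["cost_discounted"]
    qaly = walk["qalys_discounted"]
    se = lambda x: float(np.std(x, ddof=1) / np.sqrt(n)) if n > 1 else 0.0

    t_rows = walk["states"].shape[1]
    occupancy = np.zeros((t_rows, N_STATES))
    for t in range(t_rows):
        occupancy[t] = np.bincount(walk["states"][:, t], minlength=N_STATES) / n

    paths = None
    if keep_paths:
        paths = [_extract_path(walk, i, i, arm) for i in range(n)]
    return CohortEstimate(
        arm=arm,
        n=n,
        seed=seed,
        mean_cost=float(cost.mean()),
        se_cost=se(cost),
        mean_qalys=float(qaly.mean()),
        se_qalys=se(qaly),
        occupancy=occupancy,
        paths=paths,
    )


def write_event_log(paths: list[PatientPath], destination: str | Path) -> Path:
    """Write patient paths as a CSV event log, ordered by (patient, cycle)."""
    destination = Path(destination)
    rows = []
    for p in sorted(paths, key=lambda p: p.patient_id):
        for cycle, state, event, cost, qaly in p.cycle_records:
            rows.append(
                {
                    "patient_id": p.patient_id,
                    "arm": p.arm.value,
                    "cycle": cycle,
                    "state": STATES[state].value,
                    "event": event,
                    "cost_irr": cost,
                    "qaly": qaly,
                }
            )
    df = pd.DataFrame(rows, columns=list(EVENT_LOG_COLUMNS))
    df.to_csv(destination, index=False)
    return destination


def read_event_log(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False)
    missing = set(EVENT_LOG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"event log missing columns: {sorted(missing)}")
    return df
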