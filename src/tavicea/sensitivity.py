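"""Uncertainty analysis: probabilistic sensitivity analysis, acceptability
curves, and one-way (tornado) sensitivity analysis.

The PSA samples every utility carrying a positive SD from its
moment-matched Beta and every Gamma-tagged cost item from its
moment-matched Gamma, re-runs the full two-arm model per draw, and records
the incremental plane. Parameters printed without an SD stay fixed. The
one-way analysis scales a named parameter (both arms jointly for event
rates) over a multiplier grid and tracks the deterministic ICER.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import metrics
from .markov import run_arm
from .parameters import (
    EVENT_NAMES,
    NYHA_CLASSES,
    ModelConfig,
    beta_from_moments,
    config_hash,
    gamma_from_moments,
    validate_config,
)
from .states import ARMS, Arm

#: event rates varied in the default one-way analysis
DEFAULT_OWSA_PARAMETERS = (
    "stroke",
    "new_pacemaker",
    "myocardial_infarction",
    "new_atrial_fibrillation",
    "rehospitalization",
)

#: every name `owsa` accepts
OWSA_ELIGIBLE = EVENT_NAMES + ("stroke_disutility", "discount_rate")

SCATTER_COLUMNS = (
    "iteration",
    "delta_cost_irr",
    "delta_qalys",
    "icer_label",
    "cost_tavi",
    "qalys_tavi",
    "cost_savr",
    "qalys_savr",
)


class PSAIterationError(RuntimeError):
    def __init__(self, iteration: int, violations: list[str]):
        self.iteration = iteration
        super().__init__(
            f"PSA iteration {iteration} produced an invalid configuration: "
            + "; ".join(violations)
        )


@dataclass
class PSAResult:
    n_iterations: int
    seed: int
    config_hash: str
    draws: pd.DataFrame  # one row per iteration, SCATTER_COLUMNS + sampled params

    @property
    def delta_cost(self) -> np.ndarray:
        return self.draws["delta_cost_irr"].to_numpy()

    @property
    def delta_qalys(self) -> np.ndarray:
        return self.draws["delta_qalys"].to_numpy()


@dataclass
class CEACCurve:
    wtp: list[float]
    probability: list[float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp_irr": self.wtp, "probability": self.probability})


@dataclass
class OWSACurve:
    parameter: str
    multipliers: list[float]
    icers: list[float]  # NaN where the quadrant admits no ratio
    labels: list[str]
    clipped: list[bool] = field(default_factory=list)


@dataclass
class TornadoEntry:
    parameter: str
    swing: float
    icer_low: float
    icer_high: float


def sample_parameter_set(
    cfg: ModelConfig, draw_source: np.random.Generator
) -> ModelConfig:
    """One PSA parameter draw: Beta utilities, Gamma costs, all else fixed.

    Sampling order is fixed (utilities I..IV, then cost items in config
    order) so a given stream state always yields the same configuration.
    The returned configuration is a point configuration: drawn values
    replace the means and the distribution tags are cleared, so it can be
    run (and validated) like any deterministic configuration.
    """
    out = cfg.model_copy(deep=True)
    for cls in NYHA_CLASSES:
        sd = cfg.utilities.sd_by_nyha[cls]
        if sd > 0.0:
            spec = beta_from_moments(cfg.utilities.mean_by_nyha[cls], sd)
            setattr(
                out.utilities.mean_by_nyha, cls, float(draw_source.beta(spec.alpha, spec.beta))
            )
            setattr(out.utilities.sd_by_nyha, cls, 0.0)
    for item in out.costs:
        if item.sampling == "GAMMA":
            spec = gamma_from_moments(item.mean, item.sd)
            item.mean = float(draw_source.gamma(spec.shape, spec.scale))
            item.sampling = "FIXED"
            item.sd = None
    return out


def run_psa(cfg: ModelConfig, n: int, seed: int) -> PSAResult:
    """Monte-Carlo PSA: ``n`` full two-arm model runs over sampled parameters."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        sampled = sample_parameter_set(cfg, rng)
        violations = validate_config(sampled)
        if violations:
            raise PSAIterationError(i, violations)
        tavi = run_arm(Arm.TAVI, sampled)
        savr = run_arm(Arm.SAVR, sampled)
        inc = metrics.incremental(tavi, savr)
        rec = {
            "iteration": i,
            "delta_cost_irr": inc.delta_cost,
            "delta_qalys": inc.delta_qalys,
            "icer_label": inc.label,
            "cost_tavi": tavi.discounted_cost,
            "qalys_tavi": tavi.discounted_qalys,
            "cost_savr": savr.discounted_cost,
            "qalys_savr": savr.discounted_qalys,
        }
        for cls in NYHA_CLASSES:
            rec[f"utility_nyha_{cls}"] = sampled.utilities.mean_by_nyha[cls]
        for item in sampled.costs:
            if item.sampling == "GAMMA":
                rec[f"cost_{item.name}"] = item.mean
        records.append(rec)
    return PSAResult(
        n_iterations=n,
        seed=seed,
        config_hash=config_hash(cfg),
        draws=pd.DataFrame.from_records(records),
    )


def ceac(psa: PSAResult, wtp_grid: Sequence[float]) -> CEACCurve:
    """Probability of positive incremental net benefit along a WTP grid.

    Draws with exactly zero net benefit count as not cost-effective.
    """
    if psa.n_iterations < 1 or psa.draws.empty:
        raise ValueError("CEAC needs a non-empty PSA result")
    grid = list(wtp_grid)
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("WTP grid must be strictly increasing")
    dc, de = psa.delta_cost, psa.delta_qalys
    probs = [float(np.mean(w * de - dc > 0.0)) for w in grid]
    return CEACCurve(wtp=grid, probability=probs)


def psa_summary(psa: PSAResult) -> dict:
    """Headline PSA summaries: both ICER aggregations, quadrants, ellipse bounds."""
    dc, de = psa.delta_cost, psa.delta_qalys
    n = psa.n_iterations

    mean_dc, mean_de = float(dc.mean()), float(de.mean())
    ratio_of_means = mean_dc / mean_de if mean_de != 0.0 else None

    ratio_mask = (de > 0) & (dc > 0)  # north-east quadrant: plain ratios
    mean_of_ratios = (
        float((dc[ratio_mask] / de[ratio_mask]).mean()) if ratio_mask.any() else None
    )

    quadrants = {
        "more_costly_more_effective": int(((dc > 0) & (de > 0)).sum()),
        "more_costly_less_effective": int(((dc > 0) & (de <= 0)).sum()),
        "less_costly_more_effective": int(((dc <= 0) & (de > 0)).sum()),
        "less_costly_less_effective": int(((dc <= 0) & (de <= 0)).sum()),
    }

    pct = lambda x, q: float(np.percentile(x, q))
    return {
        "n_iterations": n,
        "mean_delta_cost_irr": mean_dc,
        "mean_delta_qalys": mean_de,
        "icer_ratio_of_means": ratio_of_means,
        "ratio_of_means_undefined": mean_de == 0.0,
        "icer_mean_of_ratios": mean_of_ratios,
        "mean_of_ratios_excluded_draws": int(n - ratio_mask.sum()),
        "quadrant_counts": quadrants,
        "delta_cost_irr_p2_5": pct(dc, 2.5),
        "delta_cost_irr_p97_5": pct(dc, 97.5),
        "delta_qalys_p2_5": pct(de, 2.5),
        "delta_qalys_p97_5": pct(de, 97.5),
    }


def _apply_multiplier(cfg: ModelConfig, parameter: str, m: float) -> tuple[ModelConfig, bool]:
    out = cfg.model_copy(deep=True)
    clipped = False
    if parameter in EVENT_NAMES:
        for arm in ARMS:
            rates = out.events.for_arm(arm)
            value = getattr(rates, parameter) * m
            if value > 1.0:
                value, clipped = 1.0, True
            setattr(rates, parameter, value)
    elif parameter == "stroke_disutility":
        value = cfg.utilities.stroke_disutility * m
        if value > 1.0:
            value, clipped = 1.0, True
        out.utilities.stroke_disutility = value
    elif parameter == "discount_rate":
        value = cfg.econ.discount_rate * m
        if value >= 1.0:
            value, clipped = 1.0 - 1e-12, True
        out.econ.discount_rate = value
    else:
        raise ValueError(
            f"unknown one-way parameter {parameter!r}; eligible: "
            + ", ".join(OWSA_ELIGIBLE)
        )
    return out, clipped


def owsa(
    cfg: ModelConfig,
    parameter: str,
    grid: Optional[Sequence[float]] = None,
) -> OWSACurve:
    """ICER along a multiplier grid for one parameter (both arms scaled jointly)."""
    multipliers = list(grid) if grid is not None else list(cfg.knobs.owsa_grid)
    if not multipliers or any(m <= 0 for m in multipliers):
        raise ValueError("multiplier grid must be non-empty and strictly positive")
    icers: list[float] = []
    labels: list[str] = []
    clipped_flags: list[bool] = []
    for m in multipliers:
        varied, clipped = _apply_multiplier(cfg, parameter, m)
        if clipped:
            warnings.warn(
                f"one-way analysis: {parameter} at multiplier {m} clipped to [0,1]",
                stacklevel=2,
            )
        inc = metrics.incremental(run_arm(Arm.TAVI, varied), run_arm(Arm.SAVR, varied))
        icers.append(inc.icer if inc.icer is not None else float("nan"))
        labels.append(inc.label)
        clipped_flags.append(clipped)
    return OWSACurve(
        parameter=parameter,
        multipliers=multipliers,
        icers=icers,
        labels=labels,
        clipped=clipped_flags,
    )


def tornado(curves: Sequence[OWSACurve]) -> list[TornadoEntry]:
    """Rank one-way curves by ICER swing (max - min over the grid), descending."""
    if not curves:
        raise ValueError("tornado needs at least one curve")
    entries = []
    for c in curves:
        finite = [x for x in c.icers if np.isfinite(x)]
        lo = min(finite) if finite else float("nan")
        hi = max(finite) if finite else float("nan")
        swing = hi - lo if finite else 0.0
        entries.append(
            TornadoEntry(parameter=c.parameter, swing=swing, icer_low=lo, icer_high=hi)
        )
    return sorted(entries, key=lambda e: (-e.swing, e.parameter))
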