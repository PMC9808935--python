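"""Model configuration: loading, validation, and parameter transforms.

The whole analysis is driven by a single structured-text (YAML/JSON)
configuration carrying NYHA utility weights, adverse-event probabilities,
the twelve-month entry distribution per arm, the unit-cost inventory with
its cost-assignment table, economic settings, and the assumption knobs
that pin down every modelling choice left open by the source data.

Also here: method-of-moments Beta/Gamma parameterization for the
probabilistic sensitivity analysis, and constant-hazard conversion between
cumulative and annual probabilities.
"""

from __future__ import annotations

import hashlib
import json
import math
from importlib import resources
from pathlib import Path
from typing import Literal, NamedTuple, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .states import Arm

NYHA_CLASSES = ("I", "II", "III", "IV")

EVENT_NAMES = (
    "tia",
    "stroke",
    "rehospitalization",
    "myocardial_infarction",
    "new_atrial_fibrillation",
    "new_pacemaker",
    "aortic_valve_reintervention",
)

EventName = Literal[
    "tia",
    "stroke",
    "rehospitalization",
    "myocardial_infarction",
    "new_atrial_fibrillation",
    "new_pacemaker",
    "aortic_valve_reintervention",
]


class ConfigError(ValueError):
    """Raised when a configuration file cannot be parsed or fails the schema."""


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=False)


class NyhaMap(_StrictModel):
    """One value per NYHA functional class I-IV."""

    I: float
    II: float
    III: float
    IV: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.I, self.II, self.III, self.IV)

    def __getitem__(self, cls: str) -> float:
        return getattr(self, cls)


class UtilityParams(_StrictModel):
    """EQ-5D utility weights by NYHA class with PSA standard deviations.

    ``stroke_disutility`` is the absolute utility decrement applied to the
    post-major-stroke states (no sampling distribution is attached to it).
    """

    mean_by_nyha: NyhaMap
    sd_by_nyha: NyhaMap
    stroke_disutility: float = Field(ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _ranges(self) -> "UtilityParams":
        for cls in NYHA_CLASSES:
            m = self.mean_by_nyha[cls]
            s = self.sd_by_nyha[cls]
            if not 0.0 <= m <= 1.0:
                raise ValueError(f"utility mean for NYHA {cls} out of [0,1]: {m}")
            if s < 0.0:
                raise ValueError(f"utility SD for NYHA {cls} negative: {s}")
        return self


class ArmEventRates(_StrictModel):
    """Adverse-event probabilities for one arm, cumulative over the follow-up."""

    tia: float = Field(ge=0.0, le=1.0)
    stroke: float = Field(ge=0.0, le=1.0)
    rehospitalization: float = Field(ge=0.0, le=1.0)
    myocardial_infarction: float = Field(ge=0.0, le=1.0)
    new_atrial_fibrillation: float = Field(ge=0.0, le=1.0)
    new_pacemaker: float = Field(ge=0.0, le=1.0)
    aortic_valve_reintervention: float = Field(ge=0.0, le=1.0)

    def __getitem__(self, event: str) -> float:
        if event not in EVENT_NAMES:
            raise KeyError(event)
        return getattr(self, event)


class EventRates(_StrictModel):
    followup_years: float = Field(default=5.0, gt=0.0)
    TAVI: ArmEventRates
    SAVR: ArmEventRates

    def for_arm(self, arm: Arm) -> ArmEventRates:
        return getattr(self, arm.value)


class ArmEntry(_StrictModel):
    """Twelve-month outcome split for one arm: NYHA class or death."""

    NYHA1: float = Field(ge=0.0, le=1.0)
    NYHA2: float = Field(ge=0.0, le=1.0)
    NYHA3: float = Field(ge=0.0, le=1.0)
    NYHA4: float = Field(ge=0.0, le=1.0)
    death: float = Field(ge=0.0, le=1.0)

    def as_tuple(self) -> tuple[float, ...]:
        return (self.NYHA1, self.NYHA2, self.NYHA3, self.NYHA4, self.death)


class EntryProbs(_StrictModel):
    TAVI: ArmEntry
    SAVR: ArmEntry

    def for_arm(self, arm: Arm) -> ArmEntry:
        return getattr(self, arm.value)


Phase = Literal["PROCEDURE", "ACUTE_EVENT", "PER_CYCLE_EVENT"]


class CostAssignment(_StrictModel):
    """Where a cost item accrues: an arm, a phase, and for event phases the
    triggering adverse event whose probability weights the cost. ``weight``
    is an optional extra multiplier (default 1) so splits of an item across
    arms can be expressed as data."""

    arm: Literal["TAVI", "SAVR"]
    phase: Phase
    event: Optional[EventName] = None
    weight: float = Field(default=1.0, gt=0.0)

    @model_validator(mode="after")
    def _event_required(self) -> "CostAssignment":
        if self.phase in ("ACUTE_EVENT", "PER_CYCLE_EVENT") and self.event is None:
            raise ValueError(
                f"{self.phase} assignment needs an 'event' naming the trigger"
            )
        return self


class CostItem(_StrictModel):
    name: str
    mean: float = Field(ge=0.0)
    sd: Optional[float] = Field(default=None, gt=0.0)
    sampling: Literal["FIXED", "GAMMA"] = "FIXED"
    assignment: list[CostAssignment] = Field(default_factory=list)

    @model_validator(mode="after")
    def _sd_iff_gamma(self) -> "CostItem":
        if self.sampling == "GAMMA" and self.sd is None:
            raise ValueError(f"cost item {self.name!r}: Gamma sampling needs an sd")
        if self.sampling == "FIXED" and self.sd is not None:
            raise ValueError(f"cost item {self.name!r}: sd given but sampling FIXED")
        return self


class EconSettings(_StrictModel):
    discount_rate: float = Field(default=0.065, ge=0.0, lt=1.0)
    exchange_rate: float = Field(default=250_000.0, gt=0.0)
    wtp_grid: list[float] = Field(default_factory=list)
    cycle_length_years: float = Field(default=1.0, gt=0.0)
    max_cycles: int = Field(default=50, ge=1)
    survival_stop_epsilon: float = Field(default=1e-4, ge=0.0)
    half_cycle_correction: bool = False


class AssumptionKnobs(_StrictModel):
    """Every under-determined modelling choice, pinned as explicit data."""

    longterm_death_mode: Literal["CONSTANT_YEAR1", "USER_TABLE"] = "CONSTANT_YEAR1"
    annual_death_override: Optional[float] = Field(default=None, ge=0.0, le=1.0)
    #: per arm: list of [from_cycle, annual probability] rows, ascending cycles;
    #: used for cycles >= 2 when longterm_death_mode == USER_TABLE.
    death_table: Optional[dict[Literal["TAVI", "SAVR"], list[list[float]]]] = None
    event_annualization: Literal[
        "CUMULATIVE_OVER_FOLLOWUP", "ALREADY_ANNUAL"
    ] = "CUMULATIVE_OVER_FOLLOWUP"
    rehospitalization_recurring: bool = True
    owsa_mode: Literal["MULTIPLIER"] = "MULTIPLIER"
    owsa_grid: list[float] = Field(
        default_factory=lambda: [0.05, 0.25, 0.50, 0.75, 1.00, 1.50, 2.00, 2.50]
    )
    psa_icer_summary: Literal["RATIO_OF_MEANS", "MEAN_OF_RATIOS"] = "RATIO_OF_MEANS"


class ModelConfig(_StrictModel):
    utilities: UtilityParams
    events: EventRates
    entry: EntryProbs
    costs: list[CostItem]
    econ: EconSettings = Field(default_factory=EconSettings)
    knobs: AssumptionKnobs = Field(default_factory=AssumptionKnobs)

    def cost_item(self, name: str) -> CostItem:
        for item in self.costs:
            if item.name == name:
                return item
        raise KeyError(name)


# ---------------------------------------------------------------------------
# loading & validation


def default_config_path(name: str = "model_default") -> Path:
    """Path of a bundled configuration (``model_default`` or ``model_calibrated``)."""
    ref = resources.files("tavicea.data").joinpath(f"{name}.yaml")
    return Path(str(ref))


def load_model_config(path: str | Path) -> ModelConfig:
    """Load and schema-check a model configuration file (YAML or JSON).

    Unknown keys are rejected, missing optional blocks are filled with the
    documented defaults, and nothing is silently coerced.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:  # pragma: no cover - parser detail
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path} does not contain a mapping at top level")
    try:
        return ModelConfig.model_validate(raw)
    except ValidationError as exc:
        keys = ", ".join(
            ".".join(str(p) for p in err["loc"]) or "<root>" for err in exc.errors()
        )
        raise ConfigError(f"invalid configuration {path} (at: {keys}):\n{exc}") from exc


def load_default_config(name: str = "model_default") -> ModelConfig:
    return load_model_config(default_config_path(name))


def validate_config(cfg: ModelConfig) -> list[str]:
    """Cross-field semantic checks; returns violation descriptions (empty = valid).

    Structural/range violations are already rejected at load time; this layer
    covers the constraints spanning several fields: per-arm entry probabilities
    summing to one, Beta feasibility of every utility with a positive SD,
    monotone grids, and knob consistency.
    """
    violations: list[str] = []

    for arm in ("TAVI", "SAVR"):
        probs = getattr(cfg.entry, arm).as_tuple()
        total = math.fsum(probs)
        if abs(total - 1.0) > 1e-9:
            violations.append(
                f"entry probabilities for {arm} sum to {total!r}, expected 1"
            )

    for cls in NYHA_CLASSES:
        m = cfg.utilities.mean_by_nyha[cls]
        s = cfg.utilities.sd_by_nyha[cls]
        if s > 0.0:
            if not 0.0 < m < 1.0:
                violations.append(
                    f"utility NYHA {cls}: mean {m} must lie strictly in (0,1) "
                    "to carry a Beta distribution"
                )
            elif s * s >= m * (1.0 - m):
                violations.append(
                    f"utility NYHA {cls}: variance {s * s:.6g} not below "
                    f"mean*(1-mean) = {m * (1.0 - m):.6g} (Beta infeasible)"
                )

    grid = cfg.econ.wtp_grid
    if not grid:
        violations.append("econ.wtp_grid is empty")
    elif any(b <= a for a, b in zip(grid, grid[1:])):
        violations.append("econ.wtp_grid is not strictly increasing")

    og = cfg.knobs.owsa_grid
    if any(m <= 0 for m in og):
        violations.append("knobs.owsa_grid contains non-positive multipliers")
    if any(b < a for a, b in zip(og, og[1:])):
        violations.append("knobs.owsa_grid is not sorted")

    if cfg.knobs.longterm_death_mode == "USER_TABLE":
        table = cfg.knobs.death_table
        if not table:
            violations.append("longterm_death_mode USER_TABLE but no death_table given")
        else:
            for arm, rows in table.items():
                for row in rows:
                    if len(row) != 2 or not 0.0 <= row[1] <= 1.0:
                        violations.append(
                            f"death_table[{arm}] row {row} is not [cycle, prob in [0,1]]"
                        )

    for item in cfg.costs:
        for a in item.assignment:
            if a.phase in ("ACUTE_EVENT", "PER_CYCLE_EVENT") and a.event is None:
                violations.append(
                    f"cost item {item.name!r}: {a.phase} assignment without an event"
                )

    return violations


def config_hash(cfg: ModelConfig) -> str:
    """Stable SHA-256 over the canonical JSON form of a configuration."""
    payload = json.dumps(cfg.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


# ---------------------------------------------------------------------------
# distribution moment matching


class BetaSpec(NamedTuple):
    alpha: float
    beta: float

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def sd(self) -> float:
        a, b = self.alpha, self.beta
        return math.sqrt(a * b / ((a + b) ** 2 * (a + b + 1.0)))


class GammaSpec(NamedTuple):
    shape: float
    scale: float

    @property
    def mean(self) -> float:
        return self.shape * self.scale

    @property
    def sd(self) -> float:
        return math.sqrt(self.shape) * self.scale


def beta_from_moments(mean: float, sd: float) -> BetaSpec:
    """Method-of-moments Beta(alpha, beta) for a utility with given mean/SD.

    alpha = m*c, beta = (1-m)*c with c = m(1-m)/sd^2 - 1. The variance must be
    strictly below m(1-m); an infeasible pair raises instead of being clipped.
    """
    if not 0.0 < mean < 1.0:
        raise ValueError(f"Beta mean must be in (0,1), got {mean}")
    var = sd * sd
    if not 0.0 < var < mean * (1.0 - mean):
        raise ValueError(
            f"Beta variance {var} infeasible for mean {mean} "
            f"(needs 0 < var < {mean * (1.0 - mean)})"
        )
    c = mean * (1.0 - mean) / var - 1.0
    return BetaSpec(alpha=mean * c, beta=(1.0 - mean) * c)


def gamma_from_moments(mean: float, sd: float) -> GammaSpec:
    """Method-of-moments Gamma(shape, scale) for a cost with given mean/SD."""
    if mean <= 0.0 or sd <= 0.0:
        raise ValueError(f"Gamma moments must be positive, got mean={mean}, sd={sd}")
    return GammaSpec(shape=(mean / sd) ** 2, scale=sd * sd / mean)


def annual_prob_from_cumulative(p_cum: float, years: float) -> float:
    """Constant-hazard annual probability equivalent to a cumulative one.

    Solves 1-(1-p)^years = p_cum for p. The trial-horizon event probabilities
    are cumulative over ``followup_years``; the cycle model needs annual ones.
    """
    if years <= 0.0:
        raise ValueError(f"years must be positive, got {years}")
    if not 0.0 <= p_cum < 1.0:
        raise ValueError(f"cumulative probability must be in [0,1), got {p_cum}")
    return -math.expm1(math.log1p(-p_cum) / years)


def prob_over_period(p_annual: float, years: float) -> float:
    """Constant-hazard probability over ``years`` from an annual probability."""
    if not 0.0 <= p_annual <= 1.0:
        raise ValueError(f"annual probability out of range: {p_annual}")
    if p_annual == 1.0:
        return 1.0
    if years == 1.0:  # exact for the default annual cycle
        return p_annual
    return -math.expm1(years * math.log1p(-p_annual))


def annual_event_prob(cfg: ModelConfig, arm: Arm, event: str) -> float:
    """Annual probability of an adverse event, honouring the annualization knob."""
    p = cfg.events.for_arm(arm)[event]
    if cfg.knobs.event_annualization == "ALREADY_ANNUAL":
        return p
    if p >= 1.0:
        raise ValueError(f"cumulative probability of {event} ({arm.value}) is 1")
    return annual_prob_from_cumulative(p, cfg.events.followup_years)
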