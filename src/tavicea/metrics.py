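"""Incremental cost-effectiveness arithmetic.

Delta cost / delta QALYs between intervention and comparator, the ICER with
quadrant-aware dominance handling, net monetary benefit, Rial-to-dollar
conversion and WTP threshold ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

from .markov import ArmResult

#: ICER labels: RATIO carries a meaningful ratio; DOMINANT/DOMINATED do not;
#: NO_RATIO flags a zero effect difference.
RATIO = "RATIO"
DOMINANT = "DOMINANT"
DOMINATED = "DOMINATED"
NO_RATIO = "NO_RATIO"


@dataclass
class IncrementalResult:
    delta_cost: float
    delta_qalys: float
    label: str
    icer: Optional[float] = None
    #: the south-west quadrant (cheaper and worse) inverts the decision
    #: meaning of the ratio, so it is flagged rather than reported bare
    southwest: bool = False
    exchange_rate: Optional[float] = None

    @property
    def delta_cost_usd(self) -> Optional[float]:
        if self.exchange_rate is None:
            return None
        return self.delta_cost / self.exchange_rate

    @property
    def icer_usd(self) -> Optional[float]:
        if self.exchange_rate is None or self.icer is None:
            return None
        return self.icer / self.exchange_rate


def incremental(
    intervention: ArmResult,
    comparator: ArmResult,
    exchange_rate: Optional[float] = None,
) -> IncrementalResult:
    """ΔC, ΔE and the ICER (or a dominance label) for intervention vs comparator."""
    dc = intervention.discounted_cost - comparator.discounted_cost
    de = intervention.discounted_qalys - comparator.discounted_qalys

    if de == 0.0:
        label, icer, sw = NO_RATIO, None, False
    elif de > 0.0:
        if dc <= 0.0:
            label, icer, sw = DOMINANT, None, False
        else:
            label, icer, sw = RATIO, dc / de, False
    else:  # de < 0
        if dc >= 0.0:
            label, icer, sw = DOMINATED, None, False
        else:
            label, icer, sw = RATIO, dc / de, True

    return IncrementalResult(
        delta_cost=dc,
        delta_qalys=de,
        label=label,
        icer=icer,
        southwest=sw,
        exchange_rate=exchange_rate,
    )


def nmb(inc: IncrementalResult, wtp: float) -> float:
    """Incremental net monetary benefit wtp*ΔE - ΔC; positive iff cost-effective."""
    if wtp < 0:
        raise ValueError(f"willingness-to-pay must be non-negative, got {wtp}")
    return wtp * inc.delta_qalys - inc.delta_cost


def to_usd(amount_irr: float, exchange_rate: float) -> float:
    """Unrounded US$ view of an IRR amount."""
    if exchange_rate <= 0:
        raise ValueError(f"exchange rate must be positive, got {exchange_rate}")
    return amount_irr / exchange_rate


def usd_display(amount_irr: float, exchange_rate: float) -> int:
    """Whole-dollar display value, rounded half-up (matches table presentation)."""
    usd = Decimal(str(to_usd(amount_irr, exchange_rate)))
    return int(usd.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def threshold_ratio(icer: float, wtp: float) -> float:
    """ICER as a multiple of a willingness-to-pay threshold."""
    if wtp <= 0:
        raise ValueError(f"threshold must be positive, got {wtp}")
    return icer / wtp
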