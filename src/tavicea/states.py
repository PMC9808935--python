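"""Health states and treatment arms of the aortic-stenosis model.

The long-term model tracks a cohort over nine mutually exclusive states:
the four NYHA functional classes, the same four classes after a major
stroke, and death. Death is the unique absorbing state.
"""

from __future__ import annotations

from enum import Enum


class HealthState(str, Enum):
    NYHA1 = "NYHA1"
    NYHA2 = "NYHA2"
    NYHA3 = "NYHA3"
    NYHA4 = "NYHA4"
    NYHA1_STROKE = "NYHA1_STROKE"
    NYHA2_STROKE = "NYHA2_STROKE"
    NYHA3_STROKE = "NYHA3_STROKE"
    NYHA4_STROKE = "NYHA4_STROKE"
    DEAD = "DEAD"


#: Canonical state ordering used by every matrix, trace and CSV export.
STATES: tuple[HealthState, ...] = tuple(HealthState)
STATE_INDEX: dict[HealthState, int] = {s: i for i, s in enumerate(STATES)}

N_STATES = len(STATES)
DEAD_INDEX = STATE_INDEX[HealthState.DEAD]
#: Indices of the plain NYHA states and their post-stroke counterparts.
NYHA_INDICES = (0, 1, 2, 3)
STROKE_INDICES = (4, 5, 6, 7)
ALIVE_INDICES = NYHA_INDICES + STROKE_INDICES


class Arm(str, Enum):
    """The two strategies compared: transcatheter implantation vs surgery."""

    TAVI = "TAVI"
    SAVR = "SAVR"


ARMS: tuple[Arm, Arm] = (Arm.TAVI, Arm.SAVR)
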