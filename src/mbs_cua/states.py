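"""Health states of the BMI-class Markov model.

The model partitions the alive cohort into four BMI classes —
overweight (25–29.9 kg/m²), obesity class I (30–34.9), class II
(35–39.9) and class III (40+) — plus an absorbing death state.
The integer values double as row/column indices of transition
matrices and occupancy vectors, and their order carries the
"move up / move down one class" semantics used by the annual
drift matrices.
"""

from __future__ import annotations

from enum import IntEnum


class HealthState(IntEnum):
    OW = 0
    OB1 = 1
    OB2 = 2
    OB3 = 3
    DEAD = 4


#: Alive states in ascending BMI order.
ALIVE_STATES = (
    HealthState.OW,
    HealthState.OB1,
    HealthState.OB2,
    HealthState.OB3,
)

N_STATES = len(HealthState)
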