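"""Health-state space of the long-term Markov model.

The cohort model tracks eight mutually exclusive states. Nonfatal events are
split into a one-cycle tunnel state (``NEW_*``, carrying first-year risks)
and a chronic post-event state (``POST_*``, carrying the lower risks that
apply from the second year after the event onward). Death is absorbing.
"""

from __future__ import annotations

from enum import IntEnum


class HealthState(IntEnum):
    EVENT_FREE = 0
    NEW_MI = 1
    POST_MI = 2
    NEW_STROKE = 3
    POST_STROKE = 4
    NEW_UA = 5
    POST_UA = 6
    DEAD = 7


N_STATES = len(HealthState)

#: tunnel states: occupied for exactly one cycle after an incident event
NEW_STATES = (HealthState.NEW_MI, HealthState.NEW_STROKE, HealthState.NEW_UA)

#: chronic states entered one cycle after the corresponding event
POST_STATES = (HealthState.POST_MI, HealthState.POST_STROKE, HealthState.POST_UA)

#: event label associated with each event-affected state (for disutilities)
STATE_EVENT = {
    HealthState.NEW_MI: "mi",
    HealthState.POST_MI: "mi",
    HealthState.NEW_STROKE: "stroke",
    HealthState.POST_STROKE: "stroke",
    HealthState.NEW_UA: "ua",
    HealthState.POST_UA: "ua",
}
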