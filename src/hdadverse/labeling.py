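"""Outcome labels, adverse-event group definitions, negative-control relabeling.

A session is labeled 1 when it carries at least one adverse event whose type
is in scope under the chosen scheme, else 0.  Three event groups raise the
positive fraction of the otherwise heavily imbalanced outcome: group 1 is
every event type except blood-pressure elevation and the two vascular-access
complications; group 2 is muscle cramps; group 3 is blood-pressure
elevation.  The negative control permutes the label multiset at preserved
0:1 counts, severing any feature-label association while keeping class
balance identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .session_model import EVENT_VOCABULARY, HDSession

__all__ = [
    "LabelScheme",
    "SCHEMES",
    "get_scheme",
    "label_sessions",
    "negative_control_relabel",
]

GROUP1_EXCLUDED = frozenset(
    {"blood_pressure_elevation", "vascular_access_occlusion", "vascular_access_thrombosis"}
)


@dataclass(frozen=True, slots=True)
class LabelScheme:
    name: str
    included_types: frozenset[str]

    def in_scope(self, event_type: str) -> bool:
        return event_type in self.included_types


SCHEMES: dict[str, LabelScheme] = {
    "any_event": LabelScheme("any_event", EVENT_VOCABULARY),
    "group1": LabelScheme("group1", EVENT_VOCABULARY - GROUP1_EXCLUDED),
    "group2_cramps": LabelScheme("group2_cramps", frozenset({"muscle_cramps"})),
    "group3_bp_elevation": LabelScheme(
        "group3_bp_elevation", frozenset({"blood_pressure_elevation"})
    ),
}
# convenient aliases
SCHEMES["any"] = SCHEMES["any_event"]
SCHEMES["group2"] = SCHEMES["group2_cramps"]
SCHEMES["group3"] = SCHEMES["group3_bp_elevation"]


def get_scheme(scheme: str | LabelScheme) -> LabelScheme:
    if isinstance(scheme, LabelScheme):
        return scheme
    try:
        return SCHEMES[scheme]
    except KeyError:
        raise ValueError(f"unknown label scheme {scheme!r}") from None


def label_sessions(
    sessions: Iterable[HDSession], scheme: str | LabelScheme = "any_event"
) -> np.ndarray:
    """Binary labels: 1 iff a session has >= 1 in-scope adverse event."""
    sch = get_scheme(scheme)
    return np.array(
        [int(any(sch.in_scope(e.event_type) for e in s.events)) for s in sessions],
        dtype=int,
    )


def negative_control_relabel(
    labels: Sequence[int] | np.ndarray, seed: int
) -> np.ndarray:
    """Random permutation of the label multiset (exact 0:1 counts preserved)."""
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    return labels[rng.permutation(labels.size)]
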