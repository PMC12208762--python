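"""Kleene strong three-valued logic.

Partial questionnaires leave group findings undetermined, so rule
conditions are evaluated over {true, false, unknown}. Kleene's strong
connectives are used because they are sound with respect to every
completion of the missing answers: a condition that evaluates to true
(or false) on partial data keeps that value however the remaining
questions are answered.
"""

from __future__ import annotations

import enum
from typing import Iterable


class Tri(enum.Enum):
    """A three-valued truth value."""

    TRUE = "true"
    FALSE = "false"
    UNKNOWN = "unknown"

    def __bool__(self) -> bool:  # pragma: no cover - guard against misuse
        raise TypeError("Tri is not coercible to bool; compare explicitly")


def from_bool(value: bool) -> Tri:
    return Tri.TRUE if value else Tri.FALSE


def tri_not(value: Tri) -> Tri:
    if value is Tri.TRUE:
        return Tri.FALSE
    if value is Tri.FALSE:
        return Tri.TRUE
    return Tri.UNKNOWN


def tri_and(values: Iterable[Tri]) -> Tri:
    """Kleene conjunction: false dominates, else unknown dominates."""
    result = Tri.TRUE
    for v in values:
        if v is Tri.FALSE:
            return Tri.FALSE
        if v is Tri.UNKNOWN:
            result = Tri.UNKNOWN
    return result


def tri_or(values: Iterable[Tri]) -> Tri:
    """Kleene disjunction: true dominates, else unknown dominates."""
    result = Tri.FALSE
    for v in values:
        if v is Tri.TRUE:
            return Tri.TRUE
        if v is Tri.UNKNOWN:
            result = Tri.UNKNOWN
    return result
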