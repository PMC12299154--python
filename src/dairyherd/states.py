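"""State space of the monthly dairy-cow replacement chain.

A cow is described by four coordinates:

* ``ab``   — abortion level: 0 never aborted, 1 after a rebreeding abortion
  (RA), 2 after a new-lactation abortion (NLA).  The *base* model keeps
  every cow at ``ab = 0``; the *extended* model tracks all three levels.
* ``par``  — parity (number of calvings started), 1..15.
* ``preg`` — month of gestation, 0 for an open (non-pregnant) cow, 9 means
  calving occurs this month.
* ``mil``  — month in lactation, 1..24.

Not every combination is biologically reachable: insemination is only
possible from the second month of lactation, so a cow in gestation month
``p`` must have been lactating for at least ``p + 2`` months.  Filtering the
24 x 10 grid by that rule removes 54 combinations per parity, leaving 186
feasible (PREG, MIL) pairs per parity, i.e. 2790 states for the base model
and 3 x 2790 = 8370 for the extended one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal, NamedTuple

import pandas as pd

__all__ = [
    "CowState",
    "StateSpace",
    "ModelKind",
    "INITIAL_STATE",
    "MAX_PARITY",
    "MAX_MIL",
    "MAX_PREG",
    "ab_levels",
    "is_feasible",
    "enumerate_states",
]

ModelKind = Literal["base", "extended"]

MAX_PARITY = 15
MAX_MIL = 24
MAX_PREG = 9

#: Abortion levels.
AB_NONE, AB_RA, AB_NLA = 0, 1, 2


class CowState(NamedTuple):
    """One cow's coordinates ``(ab, par, preg, mil)``."""

    ab: int
    par: int
    preg: int
    mil: int


#: Every culled, dead or retired cow is replaced by a heifer in this state.
INITIAL_STATE = CowState(ab=AB_NONE, par=1, preg=0, mil=1)


def ab_levels(model_kind: ModelKind) -> tuple[int, ...]:
    """Abortion levels tracked by a model kind."""
    if model_kind == "base":
        return (AB_NONE,)
    if model_kind == "extended":
        return (AB_NONE, AB_RA, AB_NLA)
    raise ValueError(f"unknown model_kind {model_kind!r}")


def _validate_ranges(state: CowState) -> None:
    ab, par, preg, mil = state
    if not 0 <= ab <= AB_NLA:
        raise ValueError(f"ab={ab} outside [0, {AB_NLA}]")
    if not 1 <= par <= MAX_PARITY:
        raise ValueError(f"par={par} outside [1, {MAX_PARITY}]")
    if not 0 <= preg <= MAX_PREG:
        raise ValueError(f"preg={preg} outside [0, {MAX_PREG}]")
    if not 1 <= mil <= MAX_MIL:
        raise ValueError(f"mil={mil} outside [1, {MAX_MIL}]")


def is_feasible(state: CowState) -> bool:
    """Whether a state is biologically reachable in principle.

    Conception can only happen from MIL >= 2, so gestation month ``p`` is
    first reachable at MIL = ``p + 2``; e.g. (PREG=1, MIL=1) and
    (PREG=2, MIL=3) are impossible.  Raises :class:`ValueError` naming the
    offending field when a coordinate is out of range.
    """
    state = CowState(*state)
    _validate_ranges(state)
    return state.preg == 0 or state.mil >= state.preg + 2


@dataclass(frozen=True)
class StateSpace:
    """Deterministic enumeration of the feasible states of a model.

    States are ordered lexicographically by ``(ab, par, preg, mil)`` and
    ``index_of`` maps each state to its dense row index, a bijection onto
    ``0..len(states)-1``.  ``nominal_order`` is the size of the full
    rectangular grid (including infeasible combinations), which is how the
    transition-matrix order is usually quoted: 3600 for the base model,
    10,800 for the extended one.
    """

    model_kind: ModelKind
    states: tuple[CowState, ...]
    index_of: dict[CowState, int] = field(repr=False)
    nominal_order: int

    def __len__(self) -> int:
        return len(self.states)

    def __iter__(self) -> Iterator[CowState]:
        return iter(self.states)

    def __contains__(self, state: CowState) -> bool:
        return CowState(*state) in self.index_of

    @property
    def initial_index(self) -> int:
        return self.index_of[INITIAL_STATE]

    def to_frame(self) -> pd.DataFrame:
        """States as a DataFrame with columns ab, par, preg, mil, index."""
        frame = pd.DataFrame(self.states, columns=["ab", "par", "preg", "mil"])
        frame["index"] = range(len(self.states))
        return frame


def enumerate_states(model_kind: ModelKind = "base") -> StateSpace:
    """Enumerate all feasible states of the base or extended model."""
    levels = ab_levels(model_kind)
    states = tuple(
        CowState(ab, par, preg, mil)
        for ab in levels
        for par in range(1, MAX_PARITY + 1)
        for preg in range(0, MAX_PREG + 1)
        for mil in range(1, MAX_MIL + 1)
        if preg == 0 or mil >= preg + 2
    )
    index_of = {s: i for i, s in enumerate(states)}
    nominal = len(levels) * MAX_PARITY * (MAX_PREG + 1) * MAX_MIL
    return StateSpace(
        model_kind=model_kind,
        states=states,
        index_of=index_of,
        nominal_order=nominal,
    )
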