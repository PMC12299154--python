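"""Monthly transition kernel of the replacement chain.

Events compete in a fixed order within one month: death and involuntary
culling resolve first; the survivors then either hit the voluntary-culling
threshold (open cows only), conceive, abort, calve or simply progress one
month.  Every removed cow — dead, culled, retired at the parity cap or
pushed off the lactation grid — is immediately replaced by a heifer in the
initial state (ab=0, par=1, preg=0, mil=1), which keeps each row of the
kernel a probability distribution and the chain irreducible on its
reachable states.

Abortion semantics follow the two recognised abortion types: a loss before
gestation month 3 is not recorded (the cow simply returns to open), while a
detectable abortion is a rebreeding abortion (RA) with probability
``ra_share`` — the cow keeps lactating in the same parity — or a
new-lactation abortion (NLA) otherwise — the cow starts a fresh lactation
and parity.  The base model collapses both to "return to open" and never
leaves abortion level 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .params import (
    AbortionEffects,
    Policy,
    RateTables,
    class_index,
)
from .states import (
    AB_NLA,
    AB_RA,
    INITIAL_STATE,
    MAX_MIL,
    MAX_PREG,
    CowState,
    ModelKind,
    StateSpace,
    enumerate_states,
    is_feasible,
)

__all__ = [
    "EventProbabilities",
    "TransitionMatrix",
    "ProbabilityCapWarning",
    "EVENT_NAMES",
    "transition_distribution",
    "build_transition_matrix",
]


class ProbabilityCapWarning(UserWarning):
    """A risk multiplier pushed a probability above 1 and was capped."""


EVENT_NAMES = (
    "death",
    "involuntary_cull",
    "voluntary_cull",
    "conception",
    "early_abortion",
    "ra_abortion",
    "nla_abortion",
    "calving",
    "remain",
)


@dataclass(frozen=True)
class EventProbabilities:
    """Decomposition of one cow-month into mutually exclusive events.

    ``voluntary_cull`` includes the forced replacements at the lactation
    safety bound; ``calving`` includes the parity-cap calving after which
    the cow is replaced.  The nine components sum to one.
    """

    death: float = 0.0
    involuntary_cull: float = 0.0
    voluntary_cull: float = 0.0
    conception: float = 0.0
    early_abortion: float = 0.0
    ra_abortion: float = 0.0
    nla_abortion: float = 0.0
    calving: float = 0.0
    remain: float = 0.0

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def total(self) -> float:
        return sum(self.as_dict().values())


def _kernel(
    state: CowState,
    rates: RateTables,
    effects: AbortionEffects | None,
    policy: Policy,
    model_kind: ModelKind,
    nonpreg_factor: float = 1.0,
) -> tuple[dict[CowState, float], EventProbabilities, bool]:
    """One row of the kernel: destination mass, event split, capped flag."""
    state = CowState(*state)
    if not is_feasible(state):
        raise ValueError(f"infeasible origin state {state}")
    ab, par, preg, mil = state
    cls = class_index(par)
    extended = model_kind == "extended"

    mortality = float(rates.mortality[cls, mil])
    inv_cull = float(rates.inv_cull[cls, mil])
    capped = False
    if extended and ab >= 1 and effects is not None:
        inv_cull *= effects.cull_risk_multiplier
        if mortality + inv_cull > 1.0:
            inv_cull = 1.0 - mortality
            capped = True
    exit_mass = mortality + inv_cull
    survive = 1.0 - exit_mass

    dist: dict[CowState, float] = {}
    ev: dict[str, float] = {"death": mortality, "involuntary_cull": inv_cull}

    def put(dest: CowState, mass: float) -> None:
        if mass > 0.0:
            dist[dest] = dist.get(dest, 0.0) + mass

    put(INITIAL_STATE, exit_mass)

    if preg == 0:
        # an open cow is replaced exactly when it reaches the threshold
        # month without having conceived; cows that re-enter the open pool
        # beyond it (abortion returns) keep being inseminated while the
        # window allows, and the MIL-24 bound catches any cow left over
        if mil == policy.threshold_for(par) or mil >= policy.forced_open_cull_mil:
            put(INITIAL_STATE, survive)
            ev["voluntary_cull"] = survive
        else:
            rate = float(rates.preg_rate[cls, mil])
            # aborted cows may breed back more slowly (sensitivity analysis)
            if extended and ab >= 1:
                rate *= nonpreg_factor
            conception = survive * rate
            put(CowState(ab, par, 1, mil + 1), conception)
            put(CowState(ab, par, 0, mil + 1), survive - conception)
            ev["conception"] = conception
            ev["remain"] = survive - conception
    elif preg == MAX_PREG:
        # calving this month; cows completing the parity cap are replaced
        dest = INITIAL_STATE if par >= policy.max_parity_cull else CowState(ab, par + 1, 0, 1)
        put(dest, survive)
        ev["calving"] = survive
    elif mil >= MAX_MIL:
        # pregnant cow would outlive the lactation grid before calving:
        # forced replacement (unreachable with the packaged conception window)
        put(INITIAL_STATE, survive)
        ev["voluntary_cull"] = survive
    else:
        hazard = float(rates.abort_hazard[preg])
        abort_mass = survive * hazard
        ongoing = survive - abort_mass
        if preg <= 2:
            # undetected loss: back to open, abortion level unchanged
            put(CowState(ab, par, 0, mil + 1), abort_mass)
            ev["early_abortion"] = abort_mass
        elif not extended:
            put(CowState(ab, par, 0, mil + 1), abort_mass)
            ev["ra_abortion"] = abort_mass
        else:
            ra_mass = abort_mass * rates.ra_share
            nla_mass = abort_mass * rates.nla_share
            put(CowState(max(ab, AB_RA), par, 0, mil + 1), ra_mass)
            if par >= policy.max_parity_cull:
                put(INITIAL_STATE, nla_mass)
            else:
                put(CowState(AB_NLA, par + 1, 0, 1), nla_mass)
            ev["ra_abortion"] = ra_mass
            ev["nla_abortion"] = nla_mass
        put(CowState(ab, par, preg + 1, mil + 1), ongoing)
        ev["remain"] = ev.get("remain", 0.0) + ongoing

    return dist, EventProbabilities(**ev), capped


def transition_distribution(
    state: CowState,
    rates: RateTables,
    effects: AbortionEffects | None = None,
    policy: Policy | None = None,
    model_kind: ModelKind = "base",
    nonpreg_factor: float = 1.0,
) -> list[tuple[CowState, float]]:
    """Destination distribution of one cow-month, sorted by destination."""
    policy = policy if policy is not None else Policy()
    dist, _, capped = _kernel(state, rates, effects, policy, model_kind, nonpreg_factor)
    if capped:
        warnings.warn(
            f"involuntary-culling probability capped at state {tuple(state)}",
            ProbabilityCapWarning,
            stacklevel=2,
        )
    return sorted(dist.items())


def event_probabilities(
    state: CowState,
    rates: RateTables,
    effects: AbortionEffects | None = None,
    policy: Policy | None = None,
    model_kind: ModelKind = "base",
    nonpreg_factor: float = 1.0,
) -> EventProbabilities:
    """Event decomposition of one cow-month (components sum to one)."""
    policy = policy if policy is not None else Policy()
    _, ev, _ = _kernel(state, rates, effects, policy, model_kind, nonpreg_factor)
    return ev


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic monthly kernel over the feasible states.

    ``matrix`` is a CSR matrix in the :class:`StateSpace` order; ``events``
    holds the per-row event decomposition (one column per event, rows
    aligned with the state index).  ``nominal_order`` restates the size of
    the rectangular grid the matrix is conventionally quoted at.
    """

    space: StateSpace
    matrix: sp.csr_matrix = field(repr=False)
    events: pd.DataFrame = field(repr=False)
    policy: Policy
    n_capped: int = 0

    @property
    def nominal_order(self) -> int:
        return self.space.nominal_order

    def row(self, state: CowState) -> list[tuple[CowState, float]]:
        i = self.space.index_of[CowState(*state)]
        start, stop = self.matrix.indptr[i], self.matrix.indptr[i + 1]
        return [
            (self.space.states[j], float(v))
            for j, v in zip(self.matrix.indices[start:stop], self.matrix.data[start:stop])
        ]

    def to_triplets(self) -> pd.DataFrame:
        coo = self.matrix.tocoo()
        return pd.DataFrame({"row": coo.row, "col": coo.col, "prob": coo.data})


def build_transition_matrix(
    space: StateSpace,
    rates: RateTables,
    effects: AbortionEffects | None = None,
    policy: Policy | None = None,
    nonpreg_factor: float = 1.0,
) -> TransitionMatrix:
    """Assemble the kernel row by row for every feasible state."""
    policy = policy if policy is not None else Policy()
    n = len(space)
    index_of = space.index_of
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    event_rows = np.zeros((n, len(EVENT_NAMES)), dtype=float)
    n_capped = 0
    for i, state in enumerate(space.states):
        dist, ev, capped = _kernel(
            state, rates, effects, policy, space.model_kind, nonpreg_factor
        )
        n_capped += capped
        for dest, mass in dist.items():
            rows.append(i)
            cols.append(index_of[dest])
            vals.append(mass)
        event_rows[i] = [getattr(ev, name) for name in EVENT_NAMES]
    if n_capped:
        warnings.warn(
            f"{n_capped} rows had their involuntary-culling probability capped",
            ProbabilityCapWarning,
            stacklevel=2,
        )
    matrix = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    events = pd.DataFrame(event_rows, columns=list(EVENT_NAMES))
    return TransitionMatrix(
        space=space, matrix=matrix, events=events, policy=policy, n_capped=n_capped
    )
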