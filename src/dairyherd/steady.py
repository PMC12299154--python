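"""Stationary distribution of the herd chain and derived summaries.

Replacement makes the chain irreducible on the states reachable from the
initial heifer state, and the self-loop of the initial state makes it
aperiodic, so the stationary distribution is unique there; structurally
feasible but unreachable states (e.g. a first-parity cow with a
new-lactation abortion on record) carry probability zero.

Two solvers are provided and cross-check each other: a direct sparse solve
of the balance equations with the normalisation replacing one redundant
equation, and power iteration.  A forward Monte-Carlo cohort simulation
(:func:`simulate_cohort`) serves as an independent validation oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph
import scipy.sparse.linalg as spla

from .params import AbortionEffects, Policy, RateTables
from .states import CowState, MAX_MIL, MAX_PARITY, MAX_PREG, ModelKind, StateSpace, enumerate_states
from .transitions import TransitionMatrix, build_transition_matrix

__all__ = [
    "SteadyState",
    "HerdStructure",
    "AbortionPrevalence",
    "CohortResult",
    "solve_steady_state",
    "herd_structure",
    "abortion_prevalence",
    "simulate_cohort",
]


@dataclass(frozen=True)
class SteadyState:
    """Stationary probability over the feasible states of one model."""

    space: StateSpace
    pi: np.ndarray = field(repr=False)
    method: str
    residual: float
    n_iterations: int | None = None

    def prob(self, state: CowState) -> float:
        return float(self.pi[self.space.index_of[CowState(*state)]])

    def to_series(self) -> pd.Series:
        idx = pd.MultiIndex.from_tuples(self.space.states, names=["ab", "par", "preg", "mil"])
        return pd.Series(self.pi, index=idx, name="probability")


def _reachable_indices(matrix: sp.csr_matrix, start: int) -> np.ndarray:
    order = csgraph.breadth_first_order(matrix, start, directed=True, return_predecessors=False)
    return np.sort(order)


def _solve_direct(sub: sp.csr_matrix) -> np.ndarray:
    n = sub.shape[0]
    # balance equations (P^T - I) pi = 0 with the last one replaced by sum=1
    m = (sub.T - sp.identity(n, format="csr")).tolil()
    m[n - 1, :] = 1.0
    b = np.zeros(n)
    b[n - 1] = 1.0
    pi = spla.spsolve(m.tocsr(), b)
    return pi


def _solve_power(sub: sp.csr_matrix, tol: float, max_iter: int) -> tuple[np.ndarray, int]:
    n = sub.shape[0]
    pt = sub.T.tocsr()
    pi = np.full(n, 1.0 / n)
    for it in range(1, max_iter + 1):
        new = pt @ pi
        new /= new.sum()
        delta = np.max(np.abs(new - pi))
        pi = new
        if delta < tol:
            return pi, it
    raise RuntimeError(
        f"power iteration did not converge in {max_iter} iterations "
        f"(last residual {np.max(np.abs(new - pi)):.3e})"
    )


def solve_steady_state(
    tm: TransitionMatrix,
    method: str = "direct",
    tol: float = 1e-12,
    max_iter: int = 1_000_000,
) -> SteadyState:
    """Solve pi P = pi on the communicating class reachable from the
    initial state; unreachable feasible states get probability zero."""
    matrix = tm.matrix
    n = matrix.shape[0]
    row_sums = np.asarray(matrix.sum(axis=1)).ravel()
    if np.max(np.abs(row_sums - 1.0)) > 1e-9:
        raise ValueError("transition matrix is not row-stochastic")
    reach = _reachable_indices(matrix, tm.space.initial_index)
    sub = matrix[reach][:, reach].tocsr()
    n_iterations = None
    if method == "direct":
        pi_sub = _solve_direct(sub)
    elif method == "power":
        pi_sub, n_iterations = _solve_power(sub, tol, max_iter)
    else:
        raise ValueError(f"unknown method {method!r}; expected 'direct' or 'power'")
    pi_sub = np.clip(pi_sub, 0.0, None)
    pi_sub /= pi_sub.sum()
    pi = np.zeros(n)
    pi[reach] = pi_sub
    residual = float(np.max(np.abs(matrix.T @ pi - pi)))
    return SteadyState(
        space=tm.space, pi=pi, method=method, residual=residual, n_iterations=n_iterations
    )


# ---------------------------------------------------------------------------
# herd structure summaries


@dataclass(frozen=True)
class HerdStructure:
    """Marginal herd composition at the steady state."""

    par_marginal: pd.Series
    mil_marginal: pd.Series
    preg_mil: dict[int, pd.DataFrame] = field(repr=False)

    def parity_table(self, par: int) -> pd.DataFrame:
        """PREG x MIL joint table (herd-level probabilities) for one parity."""
        return self.preg_mil[par]


def herd_structure(steady: SteadyState) -> HerdStructure:
    """Marginals over parity and month in lactation, and the per-parity
    joint PREG x MIL tables (rows MIL 1..24, columns PREG 0..9; infeasible
    cells are NaN)."""
    series = steady.to_series()
    par_marginal = series.groupby("par").sum().reindex(range(1, MAX_PARITY + 1), fill_value=0.0)
    mil_marginal = series.groupby("mil").sum().reindex(range(1, MAX_MIL + 1), fill_value=0.0)
    joint = series.groupby(["par", "preg", "mil"]).sum()
    tables: dict[int, pd.DataFrame] = {}
    for par in range(1, MAX_PARITY + 1):
        table = pd.DataFrame(
            np.nan, index=range(1, MAX_MIL + 1), columns=range(0, MAX_PREG + 1)
        )
        table.index.name = "mil"
        table.columns.name = "preg"
        for preg in range(0, MAX_PREG + 1):
            for mil in range(1, MAX_MIL + 1):
                if preg == 0 or mil >= preg + 2:
                    table.at[mil, preg] = joint.get((par, preg, mil), 0.0)
        tables[par] = table
    return HerdStructure(par_marginal=par_marginal, mil_marginal=mil_marginal, preg_mil=tables)


class AbortionPrevalence(NamedTuple):
    total: float
    ra: float
    nla: float


def abortion_prevalence(steady: SteadyState) -> AbortionPrevalence:
    """Fraction of the herd that has experienced an abortion (extended model)."""
    if steady.space.model_kind != "extended":
        raise ValueError("abortion prevalence requires the extended model")
    ab = np.fromiter((s.ab for s in steady.space.states), dtype=int, count=len(steady.space))
    ra = float(steady.pi[ab == 1].sum())
    nla = float(steady.pi[ab == 2].sum())
    return AbortionPrevalence(total=ra + nla, ra=ra, nla=nla)


# ---------------------------------------------------------------------------
# Monte-Carlo cohort oracle


@dataclass(frozen=True)
class CohortResult:
    """Empirical occupancy of a simulated cohort.

    ``frequencies`` averages the post-burn-in monthly occupancies;
    ``tail_counts`` keeps the per-month state counts of the averaging
    window so that Monte-Carlo errors can be estimated by batch means.
    """

    space: StateSpace
    frequencies: np.ndarray = field(repr=False)
    tail_counts: np.ndarray = field(repr=False)
    n_cows: int
    n_months: int
    burn_in: int

    def total_variation(self, pi: np.ndarray) -> float:
        return 0.5 * float(np.abs(self.frequencies - pi).sum())


def simulate_cohort(
    rates: RateTables,
    effects: AbortionEffects | None,
    policy: Policy,
    n_cows: int,
    n_months: int,
    seed: int,
    model_kind: ModelKind = "base",
    burn_in: int | None = None,
    start: np.ndarray | None = None,
) -> CohortResult:
    """Forward-simulate a cohort of cows with the same monthly kernel.

    Each cow's next state is sampled from its kernel row; occupancy is
    averaged over the months after ``burn_in`` (default: half the horizon,
    at most 300 months — several cow lifetimes).  Deterministic per seed.
    """
    if n_cows <= 0 or n_months <= 0:
        raise ValueError("n_cows and n_months must be positive")
    space = enumerate_states(model_kind)
    tm = build_transition_matrix(space, rates, effects, policy)
    if burn_in is None:
        burn_in = min(300, n_months // 2)
    if not 0 <= burn_in < n_months:
        raise ValueError("burn_in must lie in [0, n_months)")

    matrix = tm.matrix
    n = matrix.shape[0]
    width = int(np.diff(matrix.indptr).max())
    cum = np.ones((n, width))
    dest = np.zeros((n, width), dtype=np.int32)
    for i in range(n):
        lo, hi = matrix.indptr[i], matrix.indptr[i + 1]
        k = hi - lo
        c = np.cumsum(matrix.data[lo:hi])
        c[-1] = 1.0
        cum[i, :k] = c
        dest[i, :k] = matrix.indices[lo:hi]
        dest[i, k:] = matrix.indices[hi - 1]

    rng = np.random.default_rng(seed)
    if start is None:
        current = np.full(n_cows, space.initial_index, dtype=np.int32)
    else:
        start = np.asarray(start, dtype=float)
        if start.shape != (n,):
            raise ValueError("start distribution has the wrong length")
        current = rng.choice(n, size=n_cows, p=start / start.sum()).astype(np.int32)

    tail = np.zeros((n_months - burn_in, n), dtype=np.int32)
    for month in range(n_months):
        u = rng.random(n_cows)
        slot = (u[:, None] > cum[current]).sum(axis=1)
        current = dest[current, slot]
        if month >= burn_in:
            tail[month - burn_in] = np.bincount(current, minlength=n)
    freq = tail.sum(axis=0) / (tail.sum())
    return CohortResult(
        space=space,
        frequencies=freq,
        tail_counts=tail,
        n_cows=n_cows,
        n_months=n_months,
        burn_in=burn_in,
    )
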