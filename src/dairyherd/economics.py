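"""Per-cow monthly cash flow and its steady-state herd aggregate.

The value of one cow-month combines income over feed cost (IOFC = milk
revenue minus dry-matter intake times the feed price), the value of calves
born, and the salvage value of culled cows, against the replacement-heifer
cost of every exit, insemination and veterinary services, and any twin
loss:

    net = (IOFC + calf + salvage) - (replacement + AI + vet + twin)

Event-driven terms are weighted by the event probabilities of the same
kernel row that drives the chain, and the herd value is the expectation of
the per-state value under the stationary distribution — an average monthly
profit per cow slot, with no discounting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import AbortionEffects, EconomicScenario, Policy, RateTables, class_index
from .states import AB_NLA, AB_RA, CowState
from .steady import SteadyState
from .transitions import EventProbabilities, TransitionMatrix

__all__ = [
    "CashflowBreakdown",
    "monthly_milk",
    "state_cashflow",
    "cashflow_table",
    "herd_net_benefit",
]

_COMPONENTS = (
    "iofc",
    "calf_income",
    "salvage_income",
    "replacement_cost",
    "ai_cost",
    "vet_cost",
    "twin_loss",
)


@dataclass(frozen=True)
class CashflowBreakdown:
    """Income and cost components, USD per cow per month."""

    iofc: float = 0.0
    calf_income: float = 0.0
    salvage_income: float = 0.0
    replacement_cost: float = 0.0
    ai_cost: float = 0.0
    vet_cost: float = 0.0
    twin_loss: float = 0.0

    @property
    def net(self) -> float:
        return (self.iofc + self.calf_income + self.salvage_income) - (
            self.replacement_cost + self.ai_cost + self.vet_cost + self.twin_loss
        )

    @property
    def annual_net(self) -> float:
        return 12.0 * self.net

    def as_dict(self) -> dict[str, float]:
        out = {name: getattr(self, name) for name in _COMPONENTS}
        out["net"] = self.net
        out["annual_net"] = self.annual_net
        return out


def monthly_milk(
    state: CowState,
    scenario: EconomicScenario,
    effects: AbortionEffects | None = None,
) -> float:
    """Milk yield (kg) of one cow-month.

    The lactation curve is tabulated for months 1..10 (parity classes <= 2
    and >= 3); months 11 up to ``max_milking_mil`` carry the month-10 yield
    forward, later months are dry.  A pregnant cow dries off from gestation
    month ``dry_off_preg``.  Cows that aborted produce a reduced yield.
    """
    ab, par, preg, mil = CowState(*state)
    if mil > scenario.max_milking_mil:
        return 0.0
    if preg >= scenario.dry_off_preg:
        return 0.0
    curve_class = 0 if par <= 2 else 1
    month = min(mil, 10)
    milk = float(scenario.milk_curve[curve_class, month])
    if effects is not None:
        if ab == AB_RA:
            milk *= 1.0 - effects.milk_reduction_ra
        elif ab == AB_NLA:
            milk *= 1.0 - effects.milk_reduction_nla
    return milk


def _ai_charged(
    state: CowState, rates: RateTables, policy: Policy | None
) -> bool:
    """AI is billed when the cow is open, in the insemination window, and
    retained for breeding (not at or past the voluntary-culling threshold)."""
    ab, par, preg, mil = state
    if preg != 0 or mil < 2:
        return False
    if rates.preg_rate[class_index(par), mil] <= 0.0:
        return False
    if policy is not None and (
        mil == policy.threshold_for(par) or mil >= policy.forced_open_cull_mil
    ):
        return False
    return True


def state_cashflow(
    state: CowState,
    events: EventProbabilities,
    scenario: EconomicScenario,
    rates: RateTables,
    effects: AbortionEffects | None = None,
    policy: Policy | None = None,
) -> CashflowBreakdown:
    """Expected cash flow of one cow-month in a given state.

    Salvage is earned on culls only (a dead cow's carcass is written off),
    the replacement heifer is charged on every exit, and calf value, vet
    cost and twin loss ride on the calving probability.
    """
    state = CowState(*state)
    milk = monthly_milk(state, scenario, effects)
    feed_price = scenario.feed_cost_lact if milk > 0 else scenario.feed_cost_dry
    iofc = milk * scenario.milk_price - scenario.dmi * scenario.days_per_month * feed_price

    exit_prob = events.death + events.involuntary_cull + events.voluntary_cull
    cull_prob = events.involuntary_cull + events.voluntary_cull
    if state.par >= (policy.max_parity_cull if policy is not None else 15):
        # retirement at the parity cap: the calving (or NLA) cow is sold too
        cull_prob += events.calving + events.nla_abortion
        exit_prob += events.calving + events.nla_abortion

    vet = (
        scenario.vet_cost
        if scenario.vet_basis == "per_month"
        else scenario.vet_cost * events.calving
    )
    return CashflowBreakdown(
        iofc=iofc,
        calf_income=scenario.calf_value * events.calving,
        salvage_income=scenario.salvage_value * cull_prob,
        replacement_cost=scenario.replacement_cost * exit_prob,
        ai_cost=scenario.ai_cost if _ai_charged(state, rates, policy) else 0.0,
        vet_cost=vet,
        twin_loss=scenario.twin_loss * events.calving,
    )


def cashflow_table(
    tm: TransitionMatrix,
    scenario: EconomicScenario,
    rates: RateTables,
    effects: AbortionEffects | None = None,
) -> pd.DataFrame:
    """Per-state cash-flow components aligned with the state-space order."""
    event_rows = tm.events.to_numpy()
    names = list(tm.events.columns)
    records = []
    for i, state in enumerate(tm.space.states):
        ev = EventProbabilities(**dict(zip(names, event_rows[i])))
        records.append(
            state_cashflow(state, ev, scenario, rates, effects, tm.policy).as_dict()
        )
    return pd.DataFrame.from_records(records)


def herd_net_benefit(steady: SteadyState, cashflows: pd.DataFrame) -> CashflowBreakdown:
    """Probability-weighted herd cash flow, USD per cow per month."""
    if len(cashflows) != len(steady.pi):
        raise ValueError(
            f"cashflow table has {len(cashflows)} rows but the steady state "
            f"has {len(steady.pi)} states"
        )
    weighted = {
        name: float(np.dot(steady.pi, cashflows[name].to_numpy())) for name in _COMPONENTS
    }
    return CashflowBreakdown(**weighted)
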