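"""Model parameters: biological rates, abortion effects, prices, policy.

The packaged defaults reproduce the published monthly input tables for a
confined Holstein herd: pregnancy, mortality and involuntary-culling
probabilities by month in lactation and parity class; gestation-month
abortion hazards; the productive penalties of the two abortion types; and
the price set used for the per-cow cash flow.  All of them can be
overridden from a YAML file (:func:`load_params`).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .states import MAX_MIL, MAX_PARITY, MAX_PREG

__all__ = [
    "RateTables",
    "AbortionEffects",
    "EconomicScenario",
    "Policy",
    "ParameterError",
    "PRIMIPAROUS",
    "MULTIPAROUS",
    "class_index",
    "default_params",
    "default_policy",
    "load_params",
    "validate_params",
    "random_rate_tables",
    "reference_parity2_table",
]

#: Row indices of the parity-class axis of the rate tables.
PRIMIPAROUS, MULTIPAROUS = 0, 1

_CLASS_NAMES = {"primiparous": PRIMIPAROUS, "multiparous": MULTIPAROUS}


class ParameterError(ValueError):
    """A parameter file or table violates the model's constraints."""


def class_index(par: int) -> int:
    """Parity class used by the rate tables: first parity vs. later ones."""
    return PRIMIPAROUS if par == 1 else MULTIPAROUS


def _frozen_array(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    arr.setflags(write=False)
    return arr


@dataclass(frozen=True)
class RateTables:
    """Monthly biological transition inputs.

    ``preg_rate``, ``mortality`` and ``inv_cull`` have shape
    ``(2, MAX_MIL + 1)``: first axis is the parity class
    (:data:`PRIMIPAROUS`, :data:`MULTIPAROUS`), second axis is indexed by
    month in lactation (index 0 unused).  ``abort_hazard`` is indexed by
    gestation month (nonzero only for months 2..8; month-1 losses are
    undetectable and month 9 is calving).  ``nla_share`` is the probability
    that a detectable abortion after gestation month 2 starts a new
    lactation rather than a rebreeding attempt.
    """

    preg_rate: np.ndarray
    mortality: np.ndarray
    inv_cull: np.ndarray
    abort_hazard: np.ndarray
    nla_share: float

    @property
    def ra_share(self) -> float:
        return 1.0 - self.nla_share

    def get_preg_rate(self, mil: int, par: int) -> float:
        return float(self.preg_rate[class_index(par), mil])

    def get_mortality(self, mil: int, par: int) -> float:
        return float(self.mortality[class_index(par), mil])

    def get_inv_cull(self, mil: int, par: int) -> float:
        return float(self.inv_cull[class_index(par), mil])


@dataclass(frozen=True)
class AbortionEffects:
    """Productive and reproductive penalties for cows that aborted.

    ``milk_reduction_*`` are fractional losses of the lactation curve for
    cows at abortion level RA or NLA; ``cull_risk_multiplier`` scales the
    involuntary-culling probability of any cow that has aborted (extended
    model only).
    """

    milk_reduction_ra: float = 0.073
    milk_reduction_nla: float = 0.194
    cull_risk_multiplier: float = 1.9

    @classmethod
    def neutral(cls) -> "AbortionEffects":
        """Effects that make the extended model collapse onto the base one."""
        return cls(milk_reduction_ra=0.0, milk_reduction_nla=0.0, cull_risk_multiplier=1.0)


@dataclass(frozen=True)
class EconomicScenario:
    """Prices and husbandry constants for the monthly cash flow.

    ``milk_curve`` has shape ``(2, 11)``: rows are parity classes
    (parities <= 2 and >= 3), columns are lactation months 1..10 (index 0
    unused); months beyond 10 carry the month-10 yield forward up to
    ``max_milking_mil``, after which the cow is dry.  A pregnant cow also
    dries off from gestation month ``dry_off_preg`` onward.
    """

    milk_price: float = 0.36
    calf_value: float = 100.0
    carcass_price: float = 1.16
    replacement_cost: float = 1300.0
    vet_cost: float = 50.0
    vet_basis: str = "per_calving"
    feed_cost_lact: float = 0.17
    feed_cost_dry: float = 0.13
    dmi: float = 25.0
    days_per_month: float = 30.0
    ai_cost: float = 0.0
    carcass_weight: float = 563.0
    twin_loss: float = 0.0
    dry_off_preg: int = 8
    max_milking_mil: int = 12
    milk_curve: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        curve = self.milk_curve
        if curve is None:
            curve = _packaged_milk_curve()
        object.__setattr__(self, "milk_curve", _frozen_array(curve))

    @property
    def salvage_value(self) -> float:
        """Market value of one culled cow, USD."""
        return self.carcass_price * self.carcass_weight


@dataclass(frozen=True)
class Policy:
    """Threshold replacement policy for open cows.

    An open cow that reaches ``cull_mil_*`` months in lactation without
    conceiving is voluntarily culled and replaced.  Cows completing parity
    ``max_parity_cull`` are always replaced, and ``forced_open_cull_mil``
    is a safety bound guaranteeing no cow outlives the state grid.
    """

    cull_mil_primiparous: int = 11
    cull_mil_multiparous: int = 10
    max_parity_cull: int = MAX_PARITY
    forced_open_cull_mil: int = MAX_MIL

    def __post_init__(self):
        for name in ("cull_mil_primiparous", "cull_mil_multiparous"):
            value = getattr(self, name)
            if not 2 <= value <= MAX_MIL:
                raise ParameterError(f"{name}={value} outside [2, {MAX_MIL}]")

    def threshold_for(self, par: int) -> int:
        if par == 1:
            return self.cull_mil_primiparous
        return self.cull_mil_multiparous


def default_policy() -> Policy:
    """The published validation policy: cull open cows at MIL 11 (parity 1)
    or MIL 10 (later parities)."""
    return Policy(cull_mil_primiparous=11, cull_mil_multiparous=10)


# ---------------------------------------------------------------------------
# packaged defaults


def _data_path(name: str):
    return importlib.resources.files("dairyherd") / "data" / name


def _packaged_rate_frame() -> pd.DataFrame:
    with importlib.resources.as_file(_data_path("transition_rates.csv")) as p:
        return pd.read_csv(p)


def _packaged_milk_curve() -> np.ndarray:
    with importlib.resources.as_file(_data_path("milk_curve.csv")) as p:
        table = pd.read_csv(p)
    curve = np.zeros((2, 11))
    curve[0, table["month"].to_numpy()] = table["parity_le2"].to_numpy()
    curve[1, table["month"].to_numpy()] = table["parity_ge3"].to_numpy()
    return curve


def _packaged_defaults_yaml() -> dict:
    with importlib.resources.as_file(_data_path("defaults.yaml")) as p:
        return yaml.safe_load(p.read_text())


def reference_parity2_table() -> pd.DataFrame:
    """Published steady-state parity-2 PREG x MIL table (validation policy).

    Rows are months in lactation, columns gestation months 0..8; cells not
    reachable under the validation policy are NaN.
    """
    with importlib.resources.as_file(_data_path("reference_parity2_structure.csv")) as p:
        table = pd.read_csv(p, index_col="mil")
    table.columns = [int(c.removeprefix("preg")) for c in table.columns]
    table.columns.name = "preg"
    return table


def _rates_from_config(cfg: dict) -> RateTables:
    frame = _packaged_rate_frame().set_index("mil")
    shape = (2, MAX_MIL + 1)
    preg = np.zeros(shape)
    mort = np.zeros(shape)
    cull = np.zeros(shape)
    for cname, idx in _CLASS_NAMES.items():
        preg[idx, frame.index] = frame[f"preg_rate_{cname}"]
        mort[idx, frame.index] = frame[f"mortality_{cname}"]
        cull[idx, frame.index] = frame[f"inv_cull_{cname}"]
    hazard = np.zeros(MAX_PREG + 1)
    for month, value in cfg["rates"]["abort_hazard"].items():
        hazard[int(month)] = float(value)
    return RateTables(
        preg_rate=_frozen_array(preg),
        mortality=_frozen_array(mort),
        inv_cull=_frozen_array(cull),
        abort_hazard=_frozen_array(hazard),
        nla_share=float(cfg["rates"]["nla_share"]),
    )


def default_params() -> tuple[RateTables, AbortionEffects, EconomicScenario]:
    """The packaged published parameter set."""
    cfg = _packaged_defaults_yaml()
    rates = _rates_from_config(cfg)
    effects = AbortionEffects(**cfg["effects"])
    scenario = EconomicScenario(**cfg["economics"])
    validate_params(rates, effects, scenario)
    return rates, effects, scenario


# ---------------------------------------------------------------------------
# validation


def validate_params(
    rates: RateTables,
    effects: AbortionEffects | None = None,
    scenario: EconomicScenario | None = None,
) -> None:
    """Raise :class:`ParameterError` on any violated constraint."""
    for name in ("preg_rate", "mortality", "inv_cull"):
        arr = getattr(rates, name)
        if arr.shape != (2, MAX_MIL + 1):
            raise ParameterError(f"{name} must have shape (2, {MAX_MIL + 1})")
        if np.any(arr[:, 1:] < 0) or np.any(arr[:, 1:] > 1):
            raise ParameterError(f"{name} has entries outside [0, 1]")
    total = rates.preg_rate + rates.mortality + rates.inv_cull
    if np.any(total[:, 1:] > 1 + 1e-12):
        raise ParameterError("preg_rate + mortality + inv_cull exceeds 1 for some month")
    if rates.preg_rate[:, 1].any():
        raise ParameterError("conception is impossible in the first month of lactation")
    hz = rates.abort_hazard
    if hz.shape != (MAX_PREG + 1,):
        raise ParameterError(f"abort_hazard must have shape ({MAX_PREG + 1},)")
    if np.any(hz < 0) or np.any(hz > 1):
        raise ParameterError("abort_hazard has entries outside [0, 1]")
    if hz[0] != 0 or hz[1] != 0 or hz[MAX_PREG] != 0:
        raise ParameterError("abort_hazard must vanish for gestation months 0, 1 and 9")
    if not 0 <= rates.nla_share <= 1:
        raise ParameterError("nla_share outside [0, 1]")
    if effects is not None:
        for name in ("milk_reduction_ra", "milk_reduction_nla"):
            v = getattr(effects, name)
            if not 0 <= v < 1:
                raise ParameterError(f"{name}={v} outside [0, 1)")
        if effects.cull_risk_multiplier < 1:
            raise ParameterError("cull_risk_multiplier must be >= 1")
    if scenario is not None:
        for f in fields(scenario):
            if f.name in ("milk_curve", "vet_basis", "dry_off_preg", "max_milking_mil"):
                continue
            if getattr(scenario, f.name) < 0:
                raise ParameterError(f"{f.name} must be non-negative")
        if scenario.vet_basis not in ("per_calving", "per_month"):
            raise ParameterError("vet_basis must be 'per_calving' or 'per_month'")
        if scenario.milk_curve.shape != (2, 11):
            raise ParameterError("milk_curve must have shape (2, 11)")
        if np.any(scenario.milk_curve < 0):
            raise ParameterError("milk_curve must be non-negative")
        if not 1 <= scenario.dry_off_preg <= MAX_PREG:
            raise ParameterError("dry_off_preg outside [1, 9]")
        if not 1 <= scenario.max_milking_mil <= MAX_MIL:
            raise ParameterError("max_milking_mil outside [1, 24]")


# ---------------------------------------------------------------------------
# user parameter files


def _apply_table_overrides(arr: np.ndarray, spec: dict, what: str) -> np.ndarray:
    out = arr.copy()
    for cname, per_month in spec.items():
        if cname not in _CLASS_NAMES:
            raise ParameterError(f"{what}: unknown parity class {cname!r}")
        if not isinstance(per_month, dict):
            raise ParameterError(f"{what}.{cname}: expected a mapping month -> value")
        for month, value in per_month.items():
            month = int(month)
            if not 1 <= month <= MAX_MIL:
                raise ParameterError(f"{what}.{cname}: month {month} outside [1, {MAX_MIL}]")
            out[_CLASS_NAMES[cname], month] = float(value)
    return out


def load_params(path: str | Path) -> tuple[RateTables, AbortionEffects, EconomicScenario]:
    """Load a YAML parameter file; unspecified fields keep their defaults.

    The file mirrors the packaged ``defaults.yaml`` layout: top-level
    ``rates`` (with optional ``preg_rate`` / ``mortality`` / ``inv_cull``
    per-class per-month overrides, ``abort_hazard``, ``nla_share``),
    ``effects`` and ``economics`` sections.  An empty file yields the
    packaged defaults.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"parameter file not found: {path}")
    user = yaml.safe_load(path.read_text()) or {}
    if not isinstance(user, dict):
        raise ParameterError(f"{path}: expected a YAML mapping at the top level")
    unknown = set(user) - {"rates", "effects", "economics"}
    if unknown:
        raise ParameterError(f"{path}: unknown sections {sorted(unknown)}")

    rates, effects, scenario = default_params()

    rates_cfg = user.get("rates") or {}
    table_kwargs: dict = {}
    for name in ("preg_rate", "mortality", "inv_cull"):
        if name in rates_cfg:
            table_kwargs[name] = _frozen_array(
                _apply_table_overrides(getattr(rates, name), rates_cfg[name], name)
            )
    if "abort_hazard" in rates_cfg:
        hazard = rates.abort_hazard.copy()
        for month, value in rates_cfg["abort_hazard"].items():
            month = int(month)
            if not 0 <= month <= MAX_PREG:
                raise ParameterError(f"abort_hazard: month {month} outside [0, {MAX_PREG}]")
            hazard[month] = float(value)
        table_kwargs["abort_hazard"] = _frozen_array(hazard)
    if "nla_share" in rates_cfg:
        table_kwargs["nla_share"] = float(rates_cfg["nla_share"])
    if table_kwargs:
        rates = replace(rates, **table_kwargs)

    effects_cfg = user.get("effects") or {}
    if effects_cfg:
        unknown = set(effects_cfg) - {f.name for f in fields(AbortionEffects)}
        if unknown:
            raise ParameterError(f"effects: unknown fields {sorted(unknown)}")
        effects = replace(effects, **effects_cfg)

    econ_cfg = user.get("economics") or {}
    if econ_cfg:
        known = {f.name for f in fields(EconomicScenario)}
        unknown = set(econ_cfg) - known
        if unknown:
            raise ParameterError(f"economics: unknown fields {sorted(unknown)}")
        scenario = replace(scenario, **econ_cfg)

    validate_params(rates, effects, scenario)
    return rates, effects, scenario


# ---------------------------------------------------------------------------
# randomized fixtures


def random_rate_tables(seed: int) -> RateTables:
    """Draw a random but valid rate table, deterministically per seed.

    Used by property tests: monthly exits stay small, conception is only
    possible in the insemination window (MIL 2..15) and row totals never
    exceed one by construction (each month's probabilities come from a
    Dirichlet draw whose last component is the 'nothing happens' slack).
    """
    rng = np.random.default_rng(seed)
    shape = (2, MAX_MIL + 1)
    preg = np.zeros(shape)
    mort = np.zeros(shape)
    cull = np.zeros(shape)
    for cls in (PRIMIPAROUS, MULTIPAROUS):
        for mil in range(1, MAX_MIL + 1):
            p, m, c, _slack = rng.dirichlet([4.0, 0.5, 0.8, 14.0])
            if not 2 <= mil <= 15:
                p = 0.0
            preg[cls, mil] = p
            mort[cls, mil] = m
            cull[cls, mil] = c
    hazard = np.zeros(MAX_PREG + 1)
    hazard[2:MAX_PREG] = rng.uniform(0.0, 0.04, MAX_PREG - 2)
    tables = RateTables(
        preg_rate=_frozen_array(preg),
        mortality=_frozen_array(mort),
        inv_cull=_frozen_array(cull),
        abort_hazard=_frozen_array(hazard),
        nla_share=float(rng.uniform(0.05, 0.5)),
    )
    validate_params(tables)
    return tables
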