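"""Synthetic inputs and an individual-level microsimulation oracle.

Three generators support testing and validation: a Gompertz mortality law
producing plausible old-age life tables, a uniform sampler of valid
parameter records, and a per-patient Monte Carlo simulation of the exact
event sequence the cohort engine integrates analytically. The
microsimulation shares no code with the cohort transition algebra — it
samples each patient's events — so agreement between the two is evidence of
correctness rather than tautology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .markov import ARMS, discount_weight
from .parameters import LifeTable, ModelParams, mortality_at_age

__all__ = [
    "GompertzLaw",
    "MicrosimResult",
    "DEFAULT_BOUNDS",
    "generate_lifetable",
    "generate_random_params",
    "microsimulate",
]


@dataclass(frozen=True)
class GompertzLaw:
    """Exponentially increasing mortality hazard: q(age) = min(1, a·e^{b·age})."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError(f"baseline scale a must be positive, got {self.a}")
        if self.b < 0:
            raise ValueError(f"age slope b must be nonnegative, got {self.b}")

    def q(self, age: float) -> float:
        return min(1.0, self.a * math.exp(self.b * age))


def generate_lifetable(law: GompertzLaw, ages) -> LifeTable:
    """Tabulate the law's annual death probability over an age range."""
    ages = list(ages)
    if not ages:
        raise ValueError("age range must be nonempty")
    return LifeTable.from_mapping({int(a): law.q(a) for a in ages})


# Uniform sampling bounds keeping every record valid and clinically plausible.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "periop_mort_if": (0.005, 0.15),
    "periop_mort_ha": (0.005, 0.15),
    "periop_mort_tha": (0.005, 0.15),
    "fail_if": (0.005, 0.10),
    "fail_ha": (0.002, 0.08),
    "conv_split_if_to_ha": (0.2, 0.8),
    "u_if": (0.40, 0.90),
    "u_ha": (0.40, 0.90),
    "u_tha": (0.40, 0.95),
    "disutil_salvage": (-0.30, -0.02),
    "c_if": (3_000.0, 15_000.0),
    "c_ha": (5_000.0, 20_000.0),
    "c_if_to_ha": (10_000.0, 40_000.0),
    "c_if_to_tha": (10_000.0, 40_000.0),
    "c_ha_to_tha": (10_000.0, 40_000.0),
    "wtp": (5_000.0, 30_000.0),
    "discount_rate": (0.0, 0.05),
}


def generate_random_params(seed=None, bounds: dict | None = None,
                           rng: np.random.Generator | None = None) -> ModelParams:
    """Draw a validated parameter record uniformly within the bounds profile."""
    if rng is None:
        rng = np.random.default_rng(seed)
    profile = dict(DEFAULT_BOUNDS)
    if bounds:
        profile.update(bounds)
    values = {}
    for name, (lo, hi) in profile.items():
        if lo > hi:
            raise ValueError(f"infeasible bounds for {name}: ({lo}, {hi})")
        values[name] = float(rng.uniform(lo, hi))
    return ModelParams(**values)  # raises ValidationError if a bound is inadmissible


@dataclass(frozen=True)
class MicrosimResult:
    n: int
    seed: int
    mean_cost: float
    se_cost: float
    mean_qaly: float
    se_qaly: float
    costs: np.ndarray = field(repr=False)
    qalys: np.ndarray = field(repr=False)


# per-patient state codes (death is tracked separately by the alive mask)
_PRIMARY, _SALVAGE_HA, _SALVAGE_THA = 0, 1, 2


def microsimulate(arm: str, params: ModelParams, table: LifeTable, n: int,
                  seed: int, *, accrual: str = "end",
                  half_cycle_correction: bool = False) -> MicrosimResult:
    """Simulate ``n`` independent patients through the event sequence.

    Events per patient and year: other-cause death (no utility that year),
    implant failure, conversion surgery with its perioperative mortality and
    cost, then utility accrual for survivors (converts get the destination
    utility plus the salvage disutility). Cycle 0 charges the initial
    procedure and applies its perioperative mortality, mirroring the cohort
    engine's reward conventions.
    """
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}; expected one of {ARMS}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    p = params

    periop0 = p.periop_mort_if if arm == "IF" else p.periop_mort_ha
    cost0 = p.c_if if arm == "IF" else p.c_ha
    u_primary = p.u_if if arm == "IF" else p.u_ha

    costs = np.full(n, cost0)
    qalys = np.zeros(n)
    alive = rng.random(n) >= periop0
    state = np.full(n, _PRIMARY, dtype=np.int8)

    for t in range(1, p.horizon_cycles + 1):
        w = discount_weight(t, p.discount_rate, accrual, half_cycle_correction)
        q = mortality_at_age(table, p.start_age + t - 1)

        alive &= rng.random(n) >= q  # other-cause deaths accrue nothing this year

        fail_draw = rng.random(n)
        type_draw = rng.random(n)
        periop_draw = rng.random(n)

        if arm == "IF":
            failing_primary = alive & (state == _PRIMARY) & (fail_draw < p.fail_if)
            to_ha = failing_primary & (type_draw < p.conv_split_if_to_ha)
            to_tha = failing_primary & ~to_ha
            costs[to_ha] += w * p.c_if_to_ha
            costs[to_tha] += w * p.c_if_to_tha
            die_ha = to_ha & (periop_draw < p.periop_mort_ha)
            die_tha = to_tha & (periop_draw < p.periop_mort_tha)
            alive &= ~(die_ha | die_tha)
            surv_ha = to_ha & alive
            surv_tha = to_tha & alive
            state[surv_ha] = _SALVAGE_HA
            state[surv_tha] = _SALVAGE_THA
            qalys[surv_ha] += w * (p.u_ha + p.disutil_salvage)
            qalys[surv_tha] += w * (p.u_tha + p.disutil_salvage)
            converted = to_ha | to_tha
        else:
            converted = np.zeros(n, dtype=bool)

        # a primary HA (HA arm) or a salvage HA (either arm) can fail to THA
        ha_states = (state == _SALVAGE_HA)
        if arm == "HA":
            ha_states |= (state == _PRIMARY)
        failing_ha = alive & ~converted & ha_states & (fail_draw < p.fail_ha)
        costs[failing_ha] += w * p.c_ha_to_tha
        die = failing_ha & (periop_draw < p.periop_mort_tha)
        alive &= ~die
        surv = failing_ha & alive
        state[surv] = _SALVAGE_THA
        qalys[surv] += w * (p.u_tha + p.disutil_salvage)
        converted |= failing_ha

        quiet = alive & ~converted
        util = np.where(
            state == _PRIMARY, u_primary,
            np.where(state == _SALVAGE_HA, p.u_ha, p.u_tha),
        )
        qalys[quiet] += w * util[quiet]

    se_cost = float(costs.std(ddof=1) / math.sqrt(n)) if n > 1 else math.nan
    se_qaly = float(qalys.std(ddof=1) / math.sqrt(n)) if n > 1 else math.nan
    return MicrosimResult(
        n=n, seed=seed,
        mean_cost=float(costs.mean()), se_cost=se_cost,
        mean_qaly=float(qalys.mean()), se_qaly=se_qaly,
        costs=costs, qalys=qalys,
    )
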