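"""Markov cohort engine: state space, cohort trace, discounted totals, ICER.

Two strategy arms are modelled, named ``"IF"`` (internal fixation) and
``"HA"`` (hemiarthroplasty). Five states track the cohort:

``PRIMARY_IF``
    alive with the initial fixation in place (IF arm only);
``PRIMARY_HA``
    alive with the initial hemiarthroplasty (HA arm only);
``CONVERTED_HA``
    alive with a hemiarthroplasty received as salvage of a failed fixation —
    kept separate from ``PRIMARY_HA`` so a salvage HA can itself fail at the
    HA failure rate;
``CONVERTED_THA``
    alive with a salvage total hip arthroplasty, which never fails within
    the horizon;
``DEAD``
    absorbing.

Each one-year cycle applies, in order: background (other-cause) death at the
age-specific life-table probability, then implant failure among survivors,
then perioperative death of that cycle's conversion procedures. Survivors
accrue their end-of-cycle state utility, new converts additionally the
one-off salvage disutility; conversion costs are charged to everyone who
undergoes the procedure. Cycle 0 charges the initial procedure cost to the
whole cohort (undiscounted) and applies its perioperative mortality; no
utility accrues at cycle 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import LifeTable, ModelParams, mortality_at_age

__all__ = [
    "STATES",
    "ARMS",
    "CycleEvents",
    "CohortTrace",
    "ArmResult",
    "IcerResult",
    "StateError",
    "discount_weight",
    "cycle_transition",
    "run_cohort",
    "compute_icer",
]

STATES = ("PRIMARY_IF", "PRIMARY_HA", "CONVERTED_HA", "CONVERTED_THA", "DEAD")
PRIMARY_IF, PRIMARY_HA, CONVERTED_HA, CONVERTED_THA, DEAD = range(5)
ARMS = ("IF", "HA")

_SUM_TOL = 1e-9


class StateError(ValueError):
    """A state-occupancy vector is invalid (negative mass or not summing to 1)."""


@dataclass(frozen=True)
class CycleEvents:
    """Conversion flows of one cycle (fractions of the initial cohort)."""

    conv_if_to_ha: float = 0.0   # underwent IF -> HA salvage
    conv_if_to_tha: float = 0.0  # underwent IF -> THA salvage
    conv_ha_to_tha: float = 0.0  # underwent HA -> THA salvage (primary or salvage HA)
    periop_conv_deaths: float = 0.0


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle state occupancy; row 0 is the post-surgery starting split."""

    occupancy: np.ndarray  # shape (horizon+1, 5)
    start_age: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=STATES)
        df.insert(0, "cycle", range(len(df)))
        return df


@dataclass(frozen=True)
class ArmResult:
    strategy: str
    discounted_cost: float
    discounted_qaly: float
    trace: CohortTrace
    well_state_share: float
    alive_at_end: float
    cycle_costs: np.ndarray = field(repr=False)   # discounted, index = cycle
    cycle_qalys: np.ndarray = field(repr=False)

    def to_record(self) -> dict:
        return {
            "strategy": self.strategy,
            "discounted_cost": self.discounted_cost,
            "discounted_qaly": self.discounted_qaly,
            "well_state_share": self.well_state_share,
            "alive_at_end": self.alive_at_end,
        }


@dataclass(frozen=True)
class IcerResult:
    """Incremental result of comparator vs. reference (delta = comparator - reference)."""

    delta_cost: float
    delta_qaly: float
    icer: float | None
    classification: str  # dominant | cost_effective | not_cost_effective | dominated | indeterminate

    def to_record(self) -> dict:
        return {
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "icer": self.icer,
            "classification": self.classification,
        }


def discount_weight(cycle: int, rate: float, accrual: str = "end",
                    half_cycle_correction: bool = False) -> float:
    """Discount factor applied to rewards of cycle ``cycle`` (1-based).

    ``accrual="end"`` discounts with exponent t (rewards credited at cycle
    end), ``"begin"`` with t-1; the half-cycle correction overrides both with
    exponent t-1/2.
    """
    if accrual not in ("end", "begin"):
        raise ValueError(f"accrual must be 'end' or 'begin', got {accrual!r}")
    if half_cycle_correction:
        exponent = cycle - 0.5
    elif accrual == "end":
        exponent = cycle
    else:
        exponent = cycle - 1
    return (1.0 + rate) ** (-exponent)


def _check_occupancy(occ: np.ndarray) -> np.ndarray:
    occ = np.asarray(occ, dtype=float)
    if occ.shape != (5,):
        raise StateError(f"occupancy must have 5 entries, got shape {occ.shape}")
    if (occ < -_SUM_TOL).any():
        raise StateError("occupancy has negative mass")
    if abs(occ.sum() - 1.0) > _SUM_TOL:
        raise StateError(f"occupancy sums to {occ.sum()!r}, not 1")
    return occ


def cycle_transition(occ, arm: str, cycle_index: int, params: ModelParams,
                     table: LifeTable) -> tuple[np.ndarray, CycleEvents]:
    """Advance the cohort one cycle; returns the new occupancy and event flows."""
    occ = _check_occupancy(occ)
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}; expected one of {ARMS}")
    if not 1 <= cycle_index <= params.horizon_cycles:
        raise ValueError(f"cycle_index {cycle_index} outside [1, {params.horizon_cycles}]")

    q = mortality_at_age(table, params.start_age + cycle_index - 1)
    alive = occ[:DEAD] * (1.0 - q)

    fail_if = alive[PRIMARY_IF] * params.fail_if
    to_ha = fail_if * params.conv_split_if_to_ha
    to_tha_from_if = fail_if - to_ha
    to_tha_from_ha = (alive[PRIMARY_HA] + alive[CONVERTED_HA]) * params.fail_ha

    in_cha = to_ha * (1.0 - params.periop_mort_ha)
    in_ctha = (to_tha_from_if + to_tha_from_ha) * (1.0 - params.periop_mort_tha)
    conv_deaths = (to_ha + to_tha_from_if + to_tha_from_ha) - (in_cha + in_ctha)

    nxt = np.empty(5)
    nxt[PRIMARY_IF] = alive[PRIMARY_IF] - fail_if
    nxt[PRIMARY_HA] = alive[PRIMARY_HA] * (1.0 - params.fail_ha)
    nxt[CONVERTED_HA] = alive[CONVERTED_HA] * (1.0 - params.fail_ha) + in_cha
    nxt[CONVERTED_THA] = alive[CONVERTED_THA] + in_ctha
    nxt[DEAD] = 1.0 - nxt[:DEAD].sum()

    events = CycleEvents(
        conv_if_to_ha=to_ha,
        conv_if_to_tha=to_tha_from_if,
        conv_ha_to_tha=to_tha_from_ha,
        periop_conv_deaths=conv_deaths,
    )
    return nxt, events


def run_cohort(arm: str, params: ModelParams, table: LifeTable, *,
               accrual: str = "end", half_cycle_correction: bool = False,
               well_state_denominator: str = "survivors") -> ArmResult:
    """Run one strategy arm over the horizon and accumulate discounted totals."""
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}; expected one of {ARMS}")
    ages = range(params.start_age, params.start_age + params.horizon_cycles)
    if not table.covers(ages):
        raise LookupError(
            f"life table must cover ages {ages.start}..{ages.stop - 1} "
            f"for this horizon; it covers {table.ages}"
        )

    horizon = params.horizon_cycles
    occ = np.zeros(5)
    if arm == "IF":
        periop, init_cost, primary = params.periop_mort_if, params.c_if, PRIMARY_IF
    else:
        periop, init_cost, primary = params.periop_mort_ha, params.c_ha, PRIMARY_HA
    occ[primary] = 1.0 - periop
    occ[DEAD] = periop

    trace = np.zeros((horizon + 1, 5))
    trace[0] = occ
    cycle_costs = np.zeros(horizon + 1)
    cycle_qalys = np.zeros(horizon + 1)
    cycle_costs[0] = init_cost  # whole cohort is operated on, undiscounted

    for t in range(1, horizon + 1):
        prev = occ
        occ, ev = cycle_transition(prev, arm, t, params, table)
        trace[t] = occ

        # survivors accrue end-of-cycle state utility; the cycle's converts
        # get their destination utility plus the one-off salvage disutility;
        # perioperative conversion deaths accrue nothing this cycle
        in_cha = ev.conv_if_to_ha * (1.0 - params.periop_mort_ha)
        in_ctha = (ev.conv_if_to_tha + ev.conv_ha_to_tha) * (1.0 - params.periop_mort_tha)
        utility = (
            params.u_if * occ[PRIMARY_IF]
            + params.u_ha * occ[PRIMARY_HA]
            + params.u_ha * (occ[CONVERTED_HA] - in_cha)
            + params.u_tha * (occ[CONVERTED_THA] - in_ctha)
            + (params.u_ha + params.disutil_salvage) * in_cha
            + (params.u_tha + params.disutil_salvage) * in_ctha
        )
        cost = (
            params.c_if_to_ha * ev.conv_if_to_ha
            + params.c_if_to_tha * ev.conv_if_to_tha
            + params.c_ha_to_tha * ev.conv_ha_to_tha
        )
        w = discount_weight(t, params.discount_rate, accrual, half_cycle_correction)
        cycle_qalys[t] = w * utility
        cycle_costs[t] = w * cost

    alive_at_end = float(occ[:DEAD].sum())
    if well_state_denominator == "survivors":
        well = float(occ[primary] / alive_at_end) if alive_at_end > 0 else math.nan
    elif well_state_denominator == "initial":
        well = float(occ[primary])
    else:
        raise ValueError("well_state_denominator must be 'survivors' or 'initial'")

    return ArmResult(
        strategy=arm,
        discounted_cost=float(cycle_costs.sum()),
        discounted_qaly=float(cycle_qalys.sum()),
        trace=CohortTrace(occupancy=trace, start_age=params.start_age),
        well_state_share=well,
        alive_at_end=alive_at_end,
        cycle_costs=cycle_costs,
        cycle_qalys=cycle_qalys,
    )


def compute_icer(reference: ArmResult, comparator: ArmResult, wtp: float) -> IcerResult:
    """Incremental cost-effectiveness of ``comparator`` against ``reference``.

    The ratio is ΔCost/ΔQALY. Classification: *dominant* when the comparator
    is cheaper and more effective, *dominated* when costlier and less
    effective, otherwise *cost_effective* when the net monetary benefit
    wtp·ΔQALY − ΔCost is positive (for the usual costlier-and-better quadrant
    this is exactly ICER < WTP); *indeterminate* when ΔQALY = 0.
    """
    dc = comparator.discounted_cost - reference.discounted_cost
    dq = comparator.discounted_qaly - reference.discounted_qaly
    icer = dc / dq if dq != 0.0 else None

    if dq > 0 and dc < 0:
        cls = "dominant"
    elif dq < 0 and dc > 0:
        cls = "dominated"
    elif dq == 0:
        cls = "indeterminate"
    else:
        cls = "cost_effective" if wtp * dq - dc > 0 else "not_cost_effective"
    return IcerResult(delta_cost=dc, delta_qaly=dq, icer=icer, classification=cls)
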