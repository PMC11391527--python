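"""Deterministic sensitivity analysis: tornado, two-way grids, thresholds.

All analyses compare hemiarthroplasty (comparator) against internal fixation
(reference). The one-way/tornado analysis perturbs one input at a time by a
symmetric relative range (default ±20%) and records the ICER at each end;
the threshold search solves for the parameter value at which HA becomes
exactly cost-effective (ICER = WTP, via the net-monetary-benefit root) or
exactly dominant (ΔCost = 0 with ΔQALY > 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .markov import ArmResult, IcerResult, compute_icer, run_cohort
from .parameters import LifeTable, ModelParams

__all__ = [
    "ELIGIBLE_PARAMS",
    "TornadoEntry",
    "ThresholdResult",
    "evaluate",
    "one_way",
    "tornado",
    "two_way_region",
    "threshold_search",
]

# Inputs varied in the tornado: every base-case probability, utility,
# disutility and cost. The WTP, discount rate, horizon, conversion split and
# the life table are held fixed (pass an explicit list to vary them anyway).
ELIGIBLE_PARAMS = (
    "periop_mort_if",
    "periop_mort_ha",
    "periop_mort_tha",
    "fail_if",
    "fail_ha",
    "u_if",
    "u_ha",
    "u_tha",
    "disutil_salvage",
    "c_if",
    "c_ha",
    "c_if_to_ha",
    "c_if_to_tha",
    "c_ha_to_tha",
)

_UNIT_INTERVAL = {
    "periop_mort_if", "periop_mort_ha", "periop_mort_tha",
    "fail_if", "fail_ha", "conv_split_if_to_ha",
    "u_if", "u_ha", "u_tha",
}


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low: float
    high: float
    icer_at_low: float
    icer_at_high: float

    @property
    def bar_width(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


@dataclass(frozen=True)
class ThresholdResult:
    parameter: str
    criterion: str          # "cost_effective" | "dominant"
    threshold: float | None
    direction: str | None   # criterion holds when the parameter is "below"/"above"
    reason: str | None = None  # set when threshold is None


def evaluate(params: ModelParams, table: LifeTable, wtp: float | None = None,
             **run_kw) -> tuple[ArmResult, ArmResult, IcerResult]:
    """Run both arms and compare HA against IF; returns (IF, HA, incremental)."""
    ref = run_cohort("IF", params, table, **run_kw)
    comp = run_cohort("HA", params, table, **run_kw)
    return ref, comp, compute_icer(ref, comp, params.wtp if wtp is None else wtp)


def _clamped(params: ModelParams, name: str, value: float) -> ModelParams:
    if name in _UNIT_INTERVAL and not 0.0 <= value <= 1.0:
        clamped = min(1.0, max(0.0, value))
        warnings.warn(
            f"{name}={value:.4g} outside [0, 1]; clamped to {clamped}", stacklevel=3
        )
        value = clamped
    if name == "disutil_salvage" and not -1.0 <= value <= 0.0:
        clamped = min(0.0, max(-1.0, value))
        warnings.warn(
            f"disutil_salvage={value:.4g} outside [-1, 0]; clamped to {clamped}",
            stacklevel=3,
        )
        value = clamped
    return params.replace(**{name: value})


def _icer_value(res: IcerResult) -> float:
    return np.nan if res.icer is None else res.icer


def one_way(param_name: str, params: ModelParams, table: LifeTable,
            rel_range: float = 0.2, wtp: float | None = None, **run_kw) -> TornadoEntry:
    """ICER at ``base*(1-rel_range)`` and ``base*(1+rel_range)`` for one input."""
    if param_name not in ModelParams().to_dict():
        raise KeyError(
            f"unknown parameter {param_name!r}; eligible: {', '.join(ELIGIBLE_PARAMS)}"
        )
    base = getattr(params, param_name)
    lo, hi = base * (1.0 - rel_range), base * (1.0 + rel_range)
    if base < 0:  # the salvage disutility: keep 'low' the smaller value
        lo, hi = hi, lo
    icers = []
    for v in (lo, hi):
        *_, inc = evaluate(_clamped(params, param_name, v), table, wtp, **run_kw)
        icers.append(_icer_value(inc))
    return TornadoEntry(param_name, low=lo, high=hi,
                        icer_at_low=icers[0], icer_at_high=icers[1])


def tornado(params: ModelParams, table: LifeTable, rel_range: float = 0.2,
            wtp: float | None = None, eligible=None, **run_kw) -> list[TornadoEntry]:
    """One-way entries for every eligible input, widest bar first."""
    names = ELIGIBLE_PARAMS if eligible is None else tuple(eligible)
    entries = [one_way(n, params, table, rel_range, wtp, **run_kw) for n in names]
    return sorted(entries, key=lambda e: e.bar_width, reverse=True)


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": e.parameter,
                "low": e.low,
                "high": e.high,
                "icer_low": e.icer_at_low,
                "icer_high": e.icer_at_high,
                "bar_width": e.bar_width,
            }
            for e in entries
        ]
    )


def two_way_region(param_x: str, x_grid, param_y: str, y_grid,
                   params: ModelParams, table: LifeTable,
                   wtp: float | None = None, **run_kw) -> pd.DataFrame:
    """Cost-effectiveness classification of HA vs. IF over a 2-D input grid.

    Returns a boolean DataFrame (True = HA cost-effective or dominant at that
    cell) with ``y_grid`` as the index and ``x_grid`` as the columns.
    """
    x_grid = np.asarray(x_grid, dtype=float)
    y_grid = np.asarray(y_grid, dtype=float)
    for name, g in ((param_x, x_grid), (param_y, y_grid)):
        if g.ndim != 1 or g.size == 0:
            raise ValueError(f"{name} grid must be a nonempty 1-D sequence")
        if g.size > 1 and not (np.diff(g) > 0).all():
            raise ValueError(f"{name} grid must be strictly increasing")
    cells = np.empty((y_grid.size, x_grid.size), dtype=bool)
    for i, y in enumerate(y_grid):
        for j, x in enumerate(x_grid):
            p = _clamped(_clamped(params, param_x, x), param_y, y)
            *_, inc = evaluate(p, table, wtp, **run_kw)
            cells[i, j] = inc.classification in ("cost_effective", "dominant")
    return pd.DataFrame(cells, index=pd.Index(y_grid, name=param_y),
                        columns=pd.Index(x_grid, name=param_x))


_DEFAULT_COST_DOMAIN_FACTOR = 4.0
_SCAN_POINTS = 129


def threshold_search(param_name: str, criterion: str, params: ModelParams,
                     table: LifeTable, wtp: float | None = None,
                     domain: tuple[float, float] | None = None,
                     **run_kw) -> ThresholdResult:
    """Parameter value at which HA crosses into the requested criterion.

    ``criterion="cost_effective"`` solves net monetary benefit
    wtp·ΔQALY − ΔCost = 0; ``"dominant"`` solves ΔCost = 0 (requiring
    ΔQALY > 0 at the root). Returns a result with ``threshold=None`` and a
    reason when the criterion is unattainable anywhere in the domain — e.g.
    utilities, which cannot change costs, never yield a dominance threshold.
    """
    if criterion not in ("cost_effective", "dominant"):
        raise ValueError("criterion must be 'cost_effective' or 'dominant'")
    if param_name not in ModelParams().to_dict():
        raise KeyError(
            f"unknown parameter {param_name!r}; eligible: {', '.join(ELIGIBLE_PARAMS)}"
        )
    wtp_val = params.wtp if wtp is None else wtp
    if domain is None:
        if param_name in _UNIT_INTERVAL:
            domain = (0.0, 1.0)
        elif param_name == "disutil_salvage":
            domain = (-1.0, 0.0)
        else:
            base = getattr(params, param_name)
            domain = (0.0, _DEFAULT_COST_DOMAIN_FACTOR * max(base, 1.0))

    def objective(v: float) -> float:
        *_, inc = evaluate(params.replace(**{param_name: v}), table, wtp_val, **run_kw)
        if criterion == "cost_effective":
            return wtp_val * inc.delta_qaly - inc.delta_cost
        return -inc.delta_cost

    grid = np.linspace(domain[0], domain[1], _SCAN_POINTS)
    vals = np.array([objective(v) for v in grid])
    sign_change = np.nonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)[0]
    if sign_change.size == 0:
        hit = np.nonzero(vals == 0.0)[0]
        if hit.size:
            root = float(grid[hit[0]])
        else:
            return ThresholdResult(
                param_name, criterion, threshold=None, direction=None,
                reason=f"criterion never attained over domain {domain}",
            )
    else:
        i = sign_change[0]
        root = float(brentq(objective, grid[i], grid[i + 1], xtol=1e-10, rtol=1e-12))

    if criterion == "dominant":
        *_, inc = evaluate(params.replace(**{param_name: root}), table, wtp_val, **run_kw)
        if inc.delta_qaly <= 0:
            return ThresholdResult(
                param_name, criterion, threshold=None, direction=None,
                reason="ΔCost crosses zero only where ΔQALY <= 0",
            )
    # the criterion holds on the side of the root where the objective is positive
    eps = 1e-6 * max(abs(root), 1.0)
    direction = "above" if objective(min(root + eps, domain[1])) > 0 else "below"
    return ThresholdResult(param_name, criterion, threshold=root, direction=direction)


def thresholds_frame(results: list[ThresholdResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": r.parameter,
                "criterion": r.criterion,
                "threshold": np.nan if r.threshold is None else r.threshold,
                "direction": r.direction or "NA",
                "reason": r.reason or "",
            }
            for r in results
        ]
    )
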