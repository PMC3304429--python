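"""One-way threshold search, multiway preference planes, and tornado summary.

A threshold is the parameter value at which the incremental outcome
(discounted 20-year QALY or cost difference, SLNB minus ALND) crosses zero,
i.e. the point where the preferred strategy switches.  Thresholds are found
by bracketing root search (Brent), with a dense-grid scan available in the
test-suite as an independent oracle.

The axillary-recurrence risk after a false-negative SLNB is searched on the
scale clinicians quote — the 5-year cumulative risk — and mapped to the
model's annual probability via ``annual = 1 - (1 - cum5)**(1/5)``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .markov import run_comparison
from .parameters import (
    COST_RANGE_MULTIPLIER,
    PARAMETER_RANGES,
    CostSet,
    ModelSettings,
    ParameterSet,
)

__all__ = [
    "ThresholdResult",
    "PreferencePlane",
    "incremental_outcome",
    "one_way_threshold",
    "grid_scan_threshold",
    "multiway_plane",
    "tornado",
    "thresholds_report",
    "cum5_to_annual",
    "annual_to_cum5",
    "DEFAULT_THRESHOLD_SPECS",
    "TIE_TOLERANCE",
]

OUTCOME_QALY = "incremental_QALY"
OUTCOME_COST = "incremental_cost"
_OUTCOMES = (OUTCOME_QALY, OUTCOME_COST)

#: |incremental QALY| below which a plane cell is rendered as a tie.
TIE_TOLERANCE = 1e-10


def cum5_to_annual(cum5: float) -> float:
    """5-year cumulative risk -> constant annual probability."""
    return 1.0 - (1.0 - cum5) ** (1.0 / 5.0)


def annual_to_cum5(annual: float) -> float:
    """Constant annual probability -> 5-year cumulative risk."""
    return 1.0 - (1.0 - annual) ** 5


def _apply_parameter(
    name: str, value: float, params: ParameterSet, costs: CostSet
) -> tuple[ParameterSet, CostSet]:
    """Return (params, costs) with ``name`` set to ``value``.

    Recognised names: any ParameterSet field, any CostSet field, the derived
    quantity ``ax_recur_cum5_given_fn`` (5-year scale), and
    ``<cost field>_multiplier`` for proportional cost variation.
    """
    if name == "ax_recur_cum5_given_fn":
        return (
            params.replace(p_axillary_recur_given_fn=cum5_to_annual(value)),
            costs,
        )
    if name.endswith("_multiplier"):
        base_name = name[: -len("_multiplier")]
        base = float(getattr(CostSet(), base_name))
        return params, costs.replace(**{base_name: base * value})
    if hasattr(params, name):
        return params.replace(**{name: value}), costs
    if hasattr(costs, name):
        return params, costs.replace(**{name: value})
    raise KeyError(f"unknown parameter identifier {name!r}")


def incremental_outcome(
    outcome: str,
    params: ParameterSet,
    costs: CostSet,
    settings: ModelSettings,
    year: int | None = None,
    discounted: bool = True,
) -> float:
    """SLNB-minus-ALND difference in the requested outcome, per 1000."""
    if outcome not in _OUTCOMES:
        raise ValueError(f"outcome must be one of {_OUTCOMES}, got {outcome!r}")
    cmp = run_comparison(params, costs, settings)
    diff = cmp.difference(settings.horizon if year is None else year)
    key = "qalys" if outcome == OUTCOME_QALY else "cost"
    return diff[f"{key}_{'discounted' if discounted else 'undiscounted'}"]


@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of a one-way threshold search."""

    parameter: str
    outcome: str
    threshold_value: float | None
    direction: str  # SLNB_preferred_below | SLNB_preferred_above
    search_bounds: tuple[float, float]
    converged: bool
    outcome_at_low: float
    outcome_at_high: float
    outcome_at_threshold: float | None = None


def _slnb_preferred(outcome: str, value: float) -> bool:
    return value > 0 if outcome == OUTCOME_QALY else value < 0


def one_way_threshold(
    parameter: str,
    outcome: str,
    bounds: tuple[float, float],
    tol: float = 1e-3,
    params: ParameterSet | None = None,
    costs: CostSet | None = None,
    settings: ModelSettings | None = None,
) -> ThresholdResult:
    """Root of the incremental outcome in ``parameter``, all else base case.

    If the outcome does not change sign across ``bounds`` a non-converged
    result carrying the two endpoint values is returned (never raised).
    ``tol`` is the acceptable |incremental outcome| at the root, in per-1000
    outcome units.
    """
    params = params or ParameterSet()
    costs = costs or CostSet()
    settings = settings or ModelSettings()

    def f(x: float) -> float:
        p, c = _apply_parameter(parameter, x, params, costs)
        return incremental_outcome(outcome, p, c, settings)

    lo, hi = bounds
    f_lo, f_hi = f(lo), f(hi)
    direction = (
        "SLNB_preferred_below"
        if _slnb_preferred(outcome, f_lo)
        else "SLNB_preferred_above"
    )
    if np.sign(f_lo) == np.sign(f_hi):
        return ThresholdResult(
            parameter, outcome, None, direction, bounds, False, f_lo, f_hi
        )
    root = brentq(f, lo, hi, xtol=1e-8)
    f_root = f(root)
    return ThresholdResult(
        parameter,
        outcome,
        float(root),
        direction,
        bounds,
        abs(f_root) < tol,
        f_lo,
        f_hi,
        f_root,
    )


def grid_scan_threshold(
    parameter: str,
    outcome: str,
    bounds: tuple[float, float],
    n_points: int = 201,
    params: ParameterSet | None = None,
    costs: CostSet | None = None,
    settings: ModelSettings | None = None,
) -> float | None:
    """Brute-force threshold: first sign change on a dense grid.

    Returns the midpoint of the bracketing grid interval, or None if the
    sign never changes.  Used as an independent check on the root search.
    """
    params = params or ParameterSet()
    costs = costs or CostSet()
    settings = settings or ModelSettings()
    xs = np.linspace(bounds[0], bounds[1], n_points)
    values = []
    for x in xs:
        p, c = _apply_parameter(parameter, float(x), params, costs)
        values.append(incremental_outcome(outcome, p, c, settings))
    values = np.asarray(values)
    signs = np.sign(values)
    for i in range(len(xs) - 1):
        if signs[i] != signs[i + 1]:
            return float(0.5 * (xs[i] + xs[i + 1]))
    return None


# --------------------------------------------------------------------------
# Table-4-style default threshold searches
# --------------------------------------------------------------------------

#: (parameter, outcome, search bounds).  Bounds extend beyond the plausible
#: parameter ranges where the switch point lies outside them.
DEFAULT_THRESHOLD_SPECS: list[tuple[str, str, tuple[float, float]]] = [
    ("p_node_positive", OUTCOME_QALY, (0.05, 0.80)),
    ("ax_recur_cum5_given_fn", OUTCOME_QALY, (0.005, 0.50)),
    ("p_slnb_fn", OUTCOME_QALY, (0.0, 0.30)),
    ("p_lymph_alnd", OUTCOME_QALY, (0.119, 0.25)),
    ("lymphoedema_disutility", OUTCOME_QALY, (0.0, 0.05)),
    ("c_slnb_pos_then_alnd", OUTCOME_COST, (7771.28, 80000.0)),
    ("c_slnb_neg", OUTCOME_COST, (4206.38, 60000.0)),
    ("c_alnd", OUTCOME_COST, (0.0, 5576.45)),
    ("p_node_positive", OUTCOME_COST, (0.05, 0.80)),
]


def thresholds_report(
    params: ParameterSet | None = None,
    costs: CostSet | None = None,
    settings: ModelSettings | None = None,
    specs: Sequence[tuple[str, str, tuple[float, float]]] | None = None,
) -> pd.DataFrame:
    """Run every default threshold search and tabulate the results."""
    rows = []
    for parameter, outcome, bounds in specs or DEFAULT_THRESHOLD_SPECS:
        res = one_way_threshold(
            parameter, outcome, bounds, params=params, costs=costs, settings=settings
        )
        row = {
            "parameter": parameter,
            "outcome": outcome,
            "threshold": res.threshold_value,
            "direction": res.direction,
            "bound_low": bounds[0],
            "bound_high": bounds[1],
            "converged": res.converged,
        }
        if parameter == "ax_recur_cum5_given_fn" and res.threshold_value is not None:
            row["annual_probability"] = cum5_to_annual(res.threshold_value)
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Multiway preference planes
# --------------------------------------------------------------------------


@dataclass
class PreferencePlane:
    """One panel: preferred strategy over a 2-D parameter grid.

    ``preference`` holds +1 where SLNB generates more QALYs, -1 where ALND
    does, and 0 at ties (|incremental QALY| < TIE_TOLERANCE per 1000).
    """

    p_node_positive: float
    fn_level: float
    recur5_level: float  # 5-year axillary-recurrence risk given FN
    lymph_alnd_axis: np.ndarray
    disutility_axis: np.ndarray
    preference: np.ndarray = field(repr=False)  # (len(y), len(x))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for iy, d in enumerate(self.disutility_axis):
            for ix, pl in enumerate(self.lymph_alnd_axis):
                rows.append(
                    {
                        "p_node_positive": self.p_node_positive,
                        "p_slnb_fn": self.fn_level,
                        "ax_recur_cum5_given_fn": self.recur5_level,
                        "p_lymph_alnd": pl,
                        "lymphoedema_disutility": d,
                        "preferred": {1: "SLNB", -1: "ALND", 0: "tie"}[
                            int(self.preference[iy, ix])
                        ],
                    }
                )
        return pd.DataFrame(rows)


def multiway_plane(
    p_node_positive: float = 0.269,
    fn_levels: Sequence[float] | None = None,
    recur5_levels: Sequence[float] | None = None,
    lymph_alnd_axis: Sequence[float] | None = None,
    disutility_axis: Sequence[float] | None = None,
    grid: int = 41,
    params: ParameterSet | None = None,
    costs: CostSet | None = None,
    settings: ModelSettings | None = None,
    progress: Callable[[int, int], None] | None = None,
) -> list[PreferencePlane]:
    """3x3 panels of preferred-strategy planes for one nodal-risk scenario.

    Panel coordinates are (FN rate level, 5-year axillary-recurrence-given-FN
    level); within a panel the preferred strategy (by discounted QALYs over
    the full horizon) is mapped over the ALND lymphoedema probability and the
    lymphoedema disutility.  Infeasible parameter combinations are flagged
    with NaN rather than raising.
    """
    params = (params or ParameterSet()).replace(p_node_positive=p_node_positive)
    costs = costs or CostSet()
    settings = settings or ModelSettings()
    spec_fn = PARAMETER_RANGES["p_slnb_fn"]
    if fn_levels is None:
        fn_levels = [spec_fn.low, spec_fn.base, spec_fn.high]
    if recur5_levels is None:
        spec_ax = PARAMETER_RANGES["p_axillary_recur_given_fn"]
        # low and base mapped from the annual scale; the upper level is the
        # conservative assumption that 30% of FN patients recur within 5 years
        recur5_levels = [
            annual_to_cum5(spec_ax.low),
            annual_to_cum5(spec_ax.base),
            0.30,
        ]
    if lymph_alnd_axis is None:
        spec_l = PARAMETER_RANGES["p_lymph_alnd"]
        lymph_alnd_axis = np.linspace(spec_l.low, spec_l.high, grid)
    if disutility_axis is None:
        spec_d = PARAMETER_RANGES["lymphoedema_disutility"]
        disutility_axis = np.linspace(spec_d.low, spec_d.high, grid)
    lymph_alnd_axis = np.asarray(lymph_alnd_axis, dtype=float)
    disutility_axis = np.asarray(disutility_axis, dtype=float)

    planes = []
    n_total = len(fn_levels) * len(recur5_levels) * lymph_alnd_axis.size
    done = 0
    for recur5 in recur5_levels:
        for fn in fn_levels:
            pref = np.zeros((disutility_axis.size, lymph_alnd_axis.size))
            base = params.replace(
                p_slnb_fn=fn,
                p_axillary_recur_given_fn=cum5_to_annual(recur5),
            )
            for ix, pl in enumerate(lymph_alnd_axis):
                for iy, d in enumerate(disutility_axis):
                    try:
                        p = base.replace(
                            p_lymph_alnd=pl, lymphoedema_disutility=d
                        )
                        dq = incremental_outcome(
                            OUTCOME_QALY, p, costs, settings
                        )
                    except (ValueError, KeyError):
                        pref[iy, ix] = np.nan
                        continue
                    if abs(dq) < TIE_TOLERANCE:
                        pref[iy, ix] = 0.0
                    else:
                        pref[iy, ix] = 1.0 if dq > 0 else -1.0
                done += 1
                if progress is not None:
                    progress(done, n_total)
            planes.append(
                PreferencePlane(
                    p_node_positive=p_node_positive,
                    fn_level=float(fn),
                    recur5_level=float(recur5),
                    lymph_alnd_axis=lymph_alnd_axis,
                    disutility_axis=disutility_axis,
                    preference=pref,
                )
            )
    return planes


def planes_to_frame(planes: Sequence[PreferencePlane]) -> pd.DataFrame:
    """Long-format table over all panels."""
    return pd.concat([p.to_frame() for p in planes], ignore_index=True)


def plot_planes(
    planes: Sequence[PreferencePlane], path: str | Path
) -> None:
    """Render the 3x3 preference planes to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(planes)
    ncols = 3
    nrows = int(np.ceil(n / ncols))
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(3.2 * ncols, 3.0 * nrows), squeeze=False
    )
    for ax, plane in zip(axes.flat, planes):
        ax.pcolormesh(
            plane.lymph_alnd_axis,
            plane.disutility_axis,
            plane.preference,
            cmap="RdYlBu",
            vmin=-1,
            vmax=1,
            shading="nearest",
        )
        ax.set_title(
            f"FN={plane.fn_level:.3f}, 5y recur|FN={plane.recur5_level:.2f}",
            fontsize=8,
        )
        ax.set_xlabel("P(lymphoedema | ALND)", fontsize=7)
        ax.set_ylabel("lymphoedema disutility", fontsize=7)
        ax.tick_params(labelsize=6)
    for ax in axes.flat[n:]:
        ax.axis("off")
    fig.suptitle(
        f"Preferred strategy by QALYs, P(node positive) = "
        f"{planes[0].p_node_positive:.2f} (blue=SLNB, red=ALND)",
        fontsize=9,
    )
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# --------------------------------------------------------------------------
# Tornado summary
# --------------------------------------------------------------------------


def tornado(
    parameters: Sequence[str] | None = None,
    outcome: str = OUTCOME_QALY,
    params: ParameterSet | None = None,
    costs: CostSet | None = None,
    settings: ModelSettings | None = None,
) -> pd.DataFrame:
    """One-way swing of the incremental outcome over each parameter's range.

    Probabilities and utilities swing over their plausible low/high range;
    cost items swing over the +/-20% multiplier band.  Rows are sorted by
    output swing, largest first.
    """
    params = params or ParameterSet()
    costs = costs or CostSet()
    settings = settings or ModelSettings()
    if parameters is None:
        parameters = list(PARAMETER_RANGES) + [
            f"{name}_multiplier"
            for name in (
                "c_alnd",
                "c_slnb_neg",
                "c_slnb_pos_then_alnd",
                "c_slnb_fail_then_alnd",
                "c_radiotherapy",
                "c_chemo_first_line",
                "c_endocrine_5yr",
                "c_herceptin_1yr",
                "c_followup_annual",
                "c_lymph_annual",
                "c_local_recur_event",
                "c_axillary_recur_event",
                "c_dm_annual",
                "c_death_cancer",
                "c_death_other",
            )
        ]
    at_base = incremental_outcome(outcome, params, costs, settings)
    rows = []
    for name in parameters:
        if name.endswith("_multiplier"):
            low, high = COST_RANGE_MULTIPLIER
        else:
            spec = PARAMETER_RANGES[name]
            low, high = spec.low, spec.high
        values = {}
        for label, x in (("low", low), ("high", high)):
            p, c = _apply_parameter(name, x, params, costs)
            values[label] = incremental_outcome(outcome, p, c, settings)
        rows.append(
            {
                "parameter": name,
                "low": low,
                "high": high,
                "outcome_at_low": values["low"],
                "outcome_at_base": at_base,
                "outcome_at_high": values["high"],
                "swing": abs(values["high"] - values["low"]),
            }
        )
    df = pd.DataFrame(rows).sort_values("swing", ascending=False, ignore_index=True)
    return df


def frame_to_csv(df: pd.DataFrame, path: str | Path | None = None) -> str:
    buf = io.StringIO()
    df.to_csv(buf, index=False)
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text
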