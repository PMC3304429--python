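"""Time-inhomogeneous Markov cohort engine for the axillary staging model.

Six conceptual health states (disease free, local recurrence, axillary
recurrence, distant metastases, cancer death, other-cause death) are tracked
over annual cycles.  Cancer death is reachable only from distant metastases.
Recurrences are one-year acute states: survivors recover and return to
disease free, but permanently retain the elevated post-recurrence annual
distant-metastasis probability (the local-recurrence rate after a local
recurrence, the higher axillary rate once an axillary recurrence has
occurred).  First-event recurrence risks halve after year 5 and halve again
after year 10; background other-cause mortality rises with age as the
cohort ages from the starting age.

Internally the disease-free and local-recurrence states are expanded into
recurrence-history layers (never / post-local / post-axillary; 10 states in
total) so that post-recurrence distant-metastasis elevation is carried
forward and the elevated axillary-recurrence hazard of the false-negative
stratum applies only until the first axillary recurrence, after which
patients follow the treated node-positive profile.  The expansion is
invisible in the aggregated six-state trace.

Accounting: utilities and annual state costs accrue on half-cycle-corrected
occupancy (the mean of the occupancies bounding the cycle); one-off
transition costs apply to the flow of new entrants without correction;
cycle-t accruals are discounted by (1+r)^-t; upfront surgery and adjuvant
costs accrue undiscounted before the first cycle.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .parameters import CostSet, ModelSettings, ParameterSet
from .staging import NodalStatus, StrategyId, StratumSpec, build_strata

__all__ = [
    "run_strategy",
    "run_comparison",
    "HealthState",
    "InfeasibleParametersError",
    "TransitionSchedule",
    "CohortTrace",
    "ArmResult",
    "Comparison",
    "halving_factor",
    "build_schedule",
    "run_cohort",
    "compare",
]


class HealthState(str, enum.Enum):
    DISEASE_FREE = "DISEASE_FREE"
    LOCAL_RECURRENCE = "LOCAL_RECURRENCE"
    AXILLARY_RECURRENCE = "AXILLARY_RECURRENCE"
    DISTANT_METASTASES = "DISTANT_METASTASES"
    DEAD_CANCER = "DEAD_CANCER"
    DEAD_OTHER = "DEAD_OTHER"


# Internal 10-state indices: recurrence-history layers N (never),
# L (post local recurrence), A (post axillary recurrence).
_DF_N, _LR_N, _DF_L, _LR_L, _AX, _DF_A, _LR_A, _DM, _DC, _DO = range(10)
_N = 10
_ALIVE = slice(0, 8)
_DF_STATES = (_DF_N, _DF_L, _DF_A)
_LR_STATES = (_LR_N, _LR_L, _LR_A)
_STATE_OF = {
    _DF_N: HealthState.DISEASE_FREE,
    _LR_N: HealthState.LOCAL_RECURRENCE,
    _DF_L: HealthState.DISEASE_FREE,
    _LR_L: HealthState.LOCAL_RECURRENCE,
    _AX: HealthState.AXILLARY_RECURRENCE,
    _DF_A: HealthState.DISEASE_FREE,
    _LR_A: HealthState.LOCAL_RECURRENCE,
    _DM: HealthState.DISTANT_METASTASES,
    _DC: HealthState.DEAD_CANCER,
    _DO: HealthState.DEAD_OTHER,
}

_ROW_TOL = 1e-12


class InfeasibleParametersError(ValueError):
    """Competing annual probabilities in one state exceed 1."""

    def __init__(self, cycle: int, state: HealthState, total: float):
        self.cycle = cycle
        self.state = state
        super().__init__(
            f"cycle {cycle}, state {state.value}: competing probabilities "
            f"sum to {total:.6f} > 1"
        )


def halving_factor(cycle: int) -> float:
    """Recurrence-risk multiplier: 1 in years 1-5, 1/2 in 6-10, 1/4 after."""
    if cycle <= 5:
        return 1.0
    if cycle <= 10:
        return 0.5
    return 0.25


@dataclass(frozen=True)
class TransitionSchedule:
    """Per-cycle transition matrices for one stratum (cycles 1..horizon)."""

    stratum: StratumSpec
    matrices: np.ndarray  # shape (horizon, 8, 8)

    def __post_init__(self) -> None:
        sums = self.matrices.sum(axis=2)
        if np.any(np.abs(sums - 1.0) > _ROW_TOL) or np.any(self.matrices < 0.0):
            raise ValueError("transition matrix rows must be stochastic")

    @property
    def horizon(self) -> int:
        return self.matrices.shape[0]


def build_schedule(
    stratum: StratumSpec, params: ParameterSet, settings: ModelSettings
) -> TransitionSchedule:
    """Construct the per-cycle transition matrices for one stratum."""
    positive = stratum.nodal_status is NodalStatus.POSITIVE
    p_dm_first = (
        params.p_dm_first_node_pos if positive else params.p_dm_first_node_neg
    )
    p_dm_local = (
        params.p_dm_after_local_pos if positive else params.p_dm_after_local_neg
    )
    p_dm_ax = (
        params.p_dm_after_axillary_pos if positive else params.p_dm_after_axillary_neg
    )
    p_ax_naive = (
        params.p_axillary_recur_given_fn
        if stratum.fn_elevated
        else params.p_axillary_recur_first
    )

    T = settings.horizon
    mats = np.zeros((T, _N, _N))
    for t in range(1, T + 1):
        h = halving_factor(t)
        age = settings.start_age + (t - 1) * settings.cycle_length
        q = params.q_other(age)
        m = mats[t - 1]
        p_local = h * params.p_local_recur_first

        def df_row(row: int, lr: int, p_dm: float, p_ax: float) -> None:
            total = p_dm + p_local + p_ax + q
            if total > 1.0:
                raise InfeasibleParametersError(t, HealthState.DISEASE_FREE, total)
            m[row, _DM] = p_dm
            m[row, lr] = p_local
            m[row, _AX] = p_ax
            m[row, _DO] = q
            m[row, row] = 1.0 - total

        def acute_row(row: int, back_to: int, p_dm: float) -> None:
            state = (
                HealthState.AXILLARY_RECURRENCE
                if row == _AX
                else HealthState.LOCAL_RECURRENCE
            )
            total = p_dm + q
            if total > 1.0:
                raise InfeasibleParametersError(t, state, total)
            m[row, _DM] = p_dm
            m[row, _DO] = q
            m[row, back_to] = 1.0 - total  # survivors recover to disease free

        # The FN-elevated axillary hazard applies until the first axillary
        # recurrence, i.e. in the never and post-local layers.
        df_row(_DF_N, _LR_N, p_dm_first, h * p_ax_naive)
        df_row(_DF_L, _LR_L, p_dm_local, h * p_ax_naive)
        df_row(_DF_A, _LR_A, p_dm_ax, h * params.p_axillary_recur_first)

        acute_row(_LR_N, _DF_L, p_dm_local)
        acute_row(_LR_L, _DF_L, p_dm_local)
        acute_row(_AX, _DF_A, p_dm_ax)
        acute_row(_LR_A, _DF_A, p_dm_ax)  # axillary history dominates

        total = params.p_death_after_dm + q
        if total > 1.0:
            raise InfeasibleParametersError(t, HealthState.DISTANT_METASTASES, total)
        m[_DM, _DC] = params.p_death_after_dm
        m[_DM, _DO] = q
        m[_DM, _DM] = 1.0 - total

        m[_DC, _DC] = 1.0
        m[_DO, _DO] = 1.0

    return TransitionSchedule(stratum, mats)


@dataclass
class CohortTrace:
    """Per-cycle occupancy and accruals for the strata of one arm."""

    strategy: str
    occupancy: dict[str, np.ndarray] = field(default_factory=dict)  # (T+1, 8)
    weights: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Tidy (cycle, stratum, state, occupancy) table, six-state aggregated."""
        rows = []
        for label, occ in self.occupancy.items():
            for t in range(occ.shape[0]):
                agg: dict[HealthState, float] = {}
                for idx, state in _STATE_OF.items():
                    agg[state] = agg.get(state, 0.0) + occ[t, idx]
                for state, value in agg.items():
                    rows.append(
                        {
                            "strategy": self.strategy,
                            "stratum": label,
                            "cycle": t,
                            "state": state.value,
                            "occupancy": value,
                        }
                    )
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path | None = None) -> str:
        buf = io.StringIO()
        self.to_frame().to_csv(buf, index=False)
        text = buf.getvalue()
        if path is not None:
            Path(path).write_text(text)
        return text


_RESULT_FIELDS = [
    "axillary_recurrences",
    "distant_metastases",
    "cancer_deaths",
    "other_deaths",
    "years_disease_free",
    "life_years",
    "qalys_discounted",
    "qalys_undiscounted",
    "cost_discounted",
    "cost_undiscounted",
]


@dataclass
class ArmResult:
    """Cumulative per-cycle series for one arm, scaled per 1000 patients.

    Every series has length horizon+1 with index t = completed cycles;
    costs include the upfront accrual at t = 0.
    """

    strategy: str
    settings: ModelSettings
    series: dict[str, np.ndarray]
    trace: CohortTrace | None = None

    @property
    def horizon(self) -> int:
        return self.settings.horizon

    def at(self, year: int) -> dict[str, float]:
        """Snapshot of all cumulative quantities after ``year`` cycles."""
        if not (0 <= year <= self.horizon):
            raise ValueError(f"year {year} outside 0..{self.horizon}")
        return {name: float(s[year]) for name, s in self.series.items()}

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.series)
        df.insert(0, "cycle", np.arange(self.horizon + 1))
        return df


def run_cohort(
    strata: list[StratumSpec],
    params: ParameterSet,
    costs: CostSet,
    settings: ModelSettings,
    collect_trace: bool = False,
) -> ArmResult:
    """Run the cohort process for one arm and aggregate across strata."""
    total_weight = sum(s.weight for s in strata)
    if abs(total_weight - 1.0) > 1e-9:
        raise ValueError(f"stratum weights sum to {total_weight!r}, expected 1")

    T = settings.horizon
    u_df, u_rec, u_dm = params.u_disease_free, params.u_recurrence, params.u_dm
    utility = np.array(
        [u_df, u_rec, u_df, u_rec, u_rec, u_df, u_rec, u_dm, 0.0, 0.0]
    )
    state_cost = np.array(
        [costs.c_followup_annual] * 7 + [costs.c_dm_annual, 0.0, 0.0]
    )
    disc = np.array([settings.discount_factor(t) for t in range(1, T + 1)])

    agg = {name: np.zeros(T + 1) for name in _RESULT_FIELDS}
    trace = CohortTrace(strategy=strata[0].strategy.value) if collect_trace else None

    for stratum in strata:
        sched = build_schedule(stratum, params, settings)
        w = stratum.weight
        p_lymph = stratum.p_lymphoedema
        d_lymph = params.lymphoedema_disutility

        occ = np.zeros((T + 1, _N))
        occ[0, _DF_N] = 1.0
        qaly_u = np.zeros(T + 1)
        cost_u = np.zeros(T + 1)
        qaly_d = np.zeros(T + 1)
        cost_d = np.zeros(T + 1)
        cost_u[0] = cost_d[0] = stratum.upfront_cost
        counters = {
            "axillary_recurrences": np.zeros(T + 1),
            "distant_metastases": np.zeros(T + 1),
            "cancer_deaths": np.zeros(T + 1),
            "other_deaths": np.zeros(T + 1),
        }
        ly = np.zeros(T + 1)
        ydf = np.zeros(T + 1)

        for t in range(1, T + 1):
            P = sched.matrices[t - 1]
            prev = occ[t - 1]
            cur = prev @ P
            occ[t] = cur

            hcc = 0.5 * (prev + cur) if settings.half_cycle_correction else cur
            alive = hcc[_ALIVE].sum()

            # first-event counters (flows of new entrants)
            first_ax = prev[_DF_N] * P[_DF_N, _AX] + prev[_DF_L] * P[_DF_L, _AX]
            inflow_ax = cur[_AX]  # acute state: all occupants are entrants
            inflow_lr = sum(cur[i] for i in _LR_STATES)
            inflow_dm = cur[_DM] - prev[_DM] * P[_DM, _DM]
            inflow_dc = cur[_DC] - prev[_DC]
            inflow_do = cur[_DO] - prev[_DO]
            counters["axillary_recurrences"][t] = first_ax
            counters["distant_metastases"][t] = inflow_dm
            counters["cancer_deaths"][t] = inflow_dc
            counters["other_deaths"][t] = inflow_do

            q_t = hcc @ utility - p_lymph * d_lymph * alive
            c_t = (
                hcc @ state_cost
                + p_lymph * alive * costs.c_lymph_annual
                + inflow_lr * costs.c_local_recur_event
                + inflow_ax * costs.c_axillary_recur_event
                + inflow_dc * costs.c_death_cancer
                + inflow_do * costs.c_death_other
            )
            qaly_u[t] = q_t
            cost_u[t] = c_t
            qaly_d[t] = q_t * disc[t - 1]
            cost_d[t] = c_t * disc[t - 1]
            ly[t] = alive
            ydf[t] = sum(hcc[i] for i in _DF_STATES)

        scale = 1000.0 * w
        for name, flow in counters.items():
            agg[name] += scale * np.cumsum(flow)
        agg["years_disease_free"] += scale * np.cumsum(ydf)
        agg["life_years"] += scale * np.cumsum(ly)
        agg["qalys_discounted"] += scale * np.cumsum(qaly_d)
        agg["qalys_undiscounted"] += scale * np.cumsum(qaly_u)
        agg["cost_discounted"] += scale * np.cumsum(cost_d)
        agg["cost_undiscounted"] += scale * np.cumsum(cost_u)

        if trace is not None:
            label = f"{stratum.pathway.value}/{stratum.nodal_status.value}"
            trace.occupancy[label] = occ
            trace.weights[label] = w

    return ArmResult(
        strategy=strata[0].strategy.value,
        settings=settings,
        series=agg,
        trace=trace,
    )


@dataclass
class Comparison:
    """SLNB-minus-ALND differences and dominance classification."""

    slnb: ArmResult
    alnd: ArmResult

    def difference(self, year: int) -> dict[str, float]:
        s, a = self.slnb.at(year), self.alnd.at(year)
        return {name: s[name] - a[name] for name in s}

    def classification(self, year: int | None = None, discounted: bool = True) -> str:
        year = self.slnb.horizon if year is None else year
        diff = self.difference(year)
        suffix = "discounted" if discounted else "undiscounted"
        dq = diff[f"qalys_{suffix}"]
        dc = diff[f"cost_{suffix}"]
        if dq > 0 and dc <= 0:
            return "SLNB dominant"
        if dq < 0 and dc >= 0:
            return "ALND dominant"
        if dq == 0:
            return "tie" if dc == 0 else ("SLNB dominant" if dc < 0 else "ALND dominant")
        return f"ICER = {dc / dq:.2f} per QALY"

    def to_table(self, years: tuple[int, ...] | None = None) -> pd.DataFrame:
        """Report table: one row per outcome, columns per horizon and arm."""
        horizon = self.slnb.horizon
        if years is None:
            years = (5, horizon) if horizon >= 5 else (horizon,)
        rows = []
        for name in _RESULT_FIELDS:
            row: dict[str, object] = {"outcome": name}
            for y in years:
                s, a = self.slnb.at(y), self.alnd.at(y)
                row[f"SLNB_{y}y"] = s[name]
                row[f"ALND_{y}y"] = a[name]
                row[f"difference_{y}y"] = s[name] - a[name]
            rows.append(row)
        for discounted in (True, False):
            row = {"outcome": f"classification_{'disc' if discounted else 'undisc'}"}
            for y in years:
                label = self.classification(y, discounted=discounted)
                row[f"SLNB_{y}y"] = row[f"ALND_{y}y"] = ""
                row[f"difference_{y}y"] = label
            rows.append(row)
        return pd.DataFrame(rows)


def compare(slnb: ArmResult, alnd: ArmResult) -> Comparison:
    """Pair the two arm results, checking they share settings."""
    if slnb.settings != alnd.settings:
        raise ValueError("arms were run with different settings")
    return Comparison(slnb=slnb, alnd=alnd)


def run_strategy(
    strategy: StrategyId | str,
    params: ParameterSet,
    costs: CostSet,
    settings: ModelSettings,
    collect_trace: bool = False,
) -> ArmResult:
    """Convenience: build one arm's strata and run the cohort."""
    strata = build_strata(StrategyId(strategy), params, costs)
    return run_cohort(strata, params, costs, settings, collect_trace=collect_trace)


def run_comparison(
    params: ParameterSet | None = None,
    costs: CostSet | None = None,
    settings: ModelSettings | None = None,
) -> Comparison:
    """Run both arms at the given (default: base-case) inputs."""
    params = params or ParameterSet()
    costs = costs or CostSet()
    settings = settings or ModelSettings()
    slnb = run_strategy(StrategyId.SLNB, params, costs, settings)
    alnd = run_strategy(StrategyId.ALND, params, costs, settings)
    return compare(slnb, alnd)
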