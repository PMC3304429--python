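"""Patient-level microsimulation oracle and random parameter-set generator.

Simulates individual patients through the same staging decision tree and
yearly transition rules as the cohort engine, but with an independent,
rule-based implementation (per-patient history flags instead of an expanded
transition matrix): agreement between the two is evidence that both encode
the model correctly, which is the module's purpose.

Accounting differs from the cohort engine in one documented way: events are
realised at year end and accruals use the end-of-year state with no
half-cycle correction, so microsimulation means converge to a cohort run
with ``half_cycle_correction=False``; against the corrected cohort run the
difference is bounded by half of one cycle's re-weighted accrual.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .markov import halving_factor
from .parameters import (
    COST_RANGE_MULTIPLIER,
    PARAMETER_RANGES,
    CostSet,
    ModelSettings,
    ParameterSet,
)
from .staging import StrategyId

__all__ = [
    "SimulationConfig",
    "PatientRecord",
    "MicrosimResult",
    "simulate_arm",
    "draw_parameter_sets",
    "check_feasibility",
]

# Per-patient state codes (deliberately distinct from the engine's layout).
DF, LR, AX, DM, DEAD_CANCER, DEAD_OTHER = range(6)
_STATE_NAMES = {
    DF: "DISEASE_FREE",
    LR: "LOCAL_RECURRENCE",
    AX: "AXILLARY_RECURRENCE",
    DM: "DISTANT_METASTASES",
    DEAD_CANCER: "DEAD_CANCER",
    DEAD_OTHER: "DEAD_OTHER",
}

_PATHWAY_CODES = [
    "ALND_direct",
    "SLNB_true_negative",
    "SLNB_false_negative",
    "SLNB_positive_to_ALND",
    "SLNB_fail_to_ALND",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Reproducible microsimulation run description."""

    n_patients: int
    seed: int
    arm: StrategyId | str = StrategyId.SLNB
    overrides: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.seed is None:  # reproducibility contract
            raise ValueError("a seed is required; refusing an unseeded run")


@dataclass(frozen=True)
class PatientRecord:
    """One realised trajectory."""

    id: int
    arm: str
    nodal_status: str
    pathway: str
    lymphoedema: bool
    states: tuple[str, ...]  # end-of-year states, length <= horizon
    cost: float  # discounted AUD
    qaly: float  # discounted


@dataclass
class MicrosimResult:
    """Raw per-patient arrays plus a per-1000 summary."""

    config: SimulationConfig
    states: np.ndarray  # (n, horizon+1) int8, end-of-year states
    pathway: np.ndarray  # (n,) int8 index into _PATHWAY_CODES
    nodal_positive: np.ndarray  # (n,) bool
    lymphoedema: np.ndarray  # (n,) bool
    qaly_disc: np.ndarray
    qaly_undisc: np.ndarray
    cost_disc: np.ndarray
    cost_undisc: np.ndarray
    first_ax_year: np.ndarray  # 0 = never
    summary: dict[str, float]

    def records(self, limit: int | None = None) -> list[PatientRecord]:
        n = self.states.shape[0] if limit is None else min(limit, len(self.states))
        out = []
        for i in range(n):
            seq = self.states[i, 1:]
            # truncate after first year spent dead
            dead = np.nonzero(seq >= DEAD_CANCER)[0]
            stop = dead[0] + 1 if dead.size else seq.size
            out.append(
                PatientRecord(
                    id=i,
                    arm=StrategyId(self.config.arm).value,
                    nodal_status="positive" if self.nodal_positive[i] else "negative",
                    pathway=_PATHWAY_CODES[self.pathway[i]],
                    lymphoedema=bool(self.lymphoedema[i]),
                    states=tuple(_STATE_NAMES[s] for s in seq[:stop]),
                    cost=float(self.cost_disc[i]),
                    qaly=float(self.qaly_disc[i]),
                )
            )
        return out

    def records_frame(self, limit: int | None = None) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "id": r.id,
                    "arm": r.arm,
                    "nodal_status": r.nodal_status,
                    "pathway": r.pathway,
                    "lymphoedema": r.lymphoedema,
                    "states": "|".join(r.states),
                    "cost": r.cost,
                    "qaly": r.qaly,
                }
                for r in self.records(limit)
            ]
        )

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"quantity": k, "value": v} for k, v in self.summary.items()]
        )


def _mean_se(x: np.ndarray) -> tuple[float, float]:
    n = x.size
    se = float(x.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return float(x.mean()), se


def simulate_arm(
    config: SimulationConfig,
    params: ParameterSet | None = None,
    costs: CostSet | None = None,
    settings: ModelSettings | None = None,
) -> MicrosimResult:
    """Simulate one arm patient by patient; identical seeds give identical output."""
    params = (params or ParameterSet()).replace(**config.overrides)
    costs = costs or CostSet()
    settings = settings or ModelSettings()
    arm = StrategyId(config.arm)
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    T = settings.horizon

    # ---- staging decision tree -------------------------------------------
    positive = rng.random(n) < params.p_node_positive
    u_stage = rng.random(n)
    pathway = np.empty(n, dtype=np.int8)
    if arm is StrategyId.ALND:
        pathway[:] = _PATHWAY_CODES.index("ALND_direct")
        upfront = np.full(n, costs.c_alnd)
        p_lymph = np.full(n, params.p_lymph_alnd)
        fn_pathway = np.zeros(n, dtype=bool)
    else:
        f, fn = params.p_slnb_fail, params.p_slnb_fn
        fail = u_stage < f
        is_fn = positive & ~fail & (u_stage < f + fn)
        detected = positive & ~fail & ~is_fn
        tn = ~positive & ~fail
        pathway[fail] = _PATHWAY_CODES.index("SLNB_fail_to_ALND")
        pathway[is_fn] = _PATHWAY_CODES.index("SLNB_false_negative")
        pathway[detected] = _PATHWAY_CODES.index("SLNB_positive_to_ALND")
        pathway[tn] = _PATHWAY_CODES.index("SLNB_true_negative")
        upfront = np.where(
            fail,
            costs.c_slnb_fail_then_alnd,
            np.where(detected, costs.c_slnb_pos_then_alnd, costs.c_slnb_neg),
        )
        gets_alnd = fail | detected
        p_lymph = np.where(gets_alnd, params.p_lymph_alnd, params.p_lymph_slnb)
        fn_pathway = is_fn
    upfront = upfront + costs.adjuvant_cost(arm.value)
    lymph = rng.random(n) < p_lymph

    # ---- yearly transitions ----------------------------------------------
    states = np.zeros((n, T + 1), dtype=np.int8)
    had_local = np.zeros(n, dtype=bool)
    had_ax = np.zeros(n, dtype=bool)
    first_ax_year = np.zeros(n, dtype=np.int16)
    qaly_disc = np.zeros(n)
    qaly_undisc = np.zeros(n)
    cost_disc = np.zeros(n)
    cost_undisc = upfront.copy()
    cost_disc += upfront

    p_dm_first = np.where(
        positive, params.p_dm_first_node_pos, params.p_dm_first_node_neg
    )
    p_dm_local = np.where(
        positive, params.p_dm_after_local_pos, params.p_dm_after_local_neg
    )
    p_dm_ax = np.where(
        positive, params.p_dm_after_axillary_pos, params.p_dm_after_axillary_neg
    )
    util_of = {DF: params.u_disease_free, LR: params.u_recurrence,
               AX: params.u_recurrence, DM: params.u_dm}

    for t in range(1, T + 1):
        h = halving_factor(t)
        age = settings.start_age + (t - 1) * settings.cycle_length
        q = params.q_other(age)
        prev = states[:, t - 1]
        cur = prev.copy()
        u = rng.random(n)

        # disease free: competing dm / local / axillary / other-cause death
        in_df = prev == DF
        p_dm_df = np.where(had_ax, p_dm_ax, np.where(had_local, p_dm_local, p_dm_first))
        p_ax_df = h * np.where(
            fn_pathway & ~had_ax,
            params.p_axillary_recur_given_fn,
            params.p_axillary_recur_first,
        )
        p_lr_df = h * params.p_local_recur_first
        c1 = p_dm_df
        c2 = c1 + p_lr_df
        c3 = c2 + p_ax_df
        c4 = c3 + q
        cur[in_df & (u < c1)] = DM
        cur[in_df & (u >= c1) & (u < c2)] = LR
        cur[in_df & (u >= c2) & (u < c3)] = AX
        cur[in_df & (u >= c3) & (u < c4)] = DEAD_OTHER

        # acute recurrence states: progress, die, or recover to disease free
        in_lr = prev == LR
        p_dm_acute_lr = np.where(had_ax, p_dm_ax, p_dm_local)
        cur[in_lr & (u < p_dm_acute_lr)] = DM
        cur[in_lr & (u >= p_dm_acute_lr) & (u < p_dm_acute_lr + q)] = DEAD_OTHER
        cur[in_lr & (u >= p_dm_acute_lr + q)] = DF

        in_ax = prev == AX
        cur[in_ax & (u < p_dm_ax)] = DM
        cur[in_ax & (u >= p_dm_ax) & (u < p_dm_ax + q)] = DEAD_OTHER
        cur[in_ax & (u >= p_dm_ax + q)] = DF

        in_dm = prev == DM
        pd_ = params.p_death_after_dm
        cur[in_dm & (u < pd_)] = DEAD_CANCER
        cur[in_dm & (u >= pd_) & (u < pd_ + q)] = DEAD_OTHER

        states[:, t] = cur
        new_lr = in_df & (cur == LR)
        new_ax = (in_df & (cur == AX))
        first_ax = new_ax & ~had_ax
        first_ax_year[first_ax] = t
        had_local |= new_lr
        had_ax |= new_ax

        # ---- accrual on the end-of-year state (no half-cycle correction)
        alive = cur < DEAD_CANCER
        util = np.zeros(n)
        for s, us in util_of.items():
            util[cur == s] = us
        util[alive & lymph] -= params.lymphoedema_disutility
        c = np.zeros(n)
        c[alive & (cur != DM)] = costs.c_followup_annual
        c[cur == DM] = costs.c_dm_annual
        c[alive & lymph] += costs.c_lymph_annual
        c[new_lr] += costs.c_local_recur_event
        c[new_ax] += costs.c_axillary_recur_event
        c[in_dm & (cur == DEAD_CANCER)] += costs.c_death_cancer
        c[(prev < DEAD_CANCER) & (cur == DEAD_OTHER)] += costs.c_death_other
        disc = settings.discount_factor(t)
        qaly_undisc += util
        qaly_disc += util * disc
        cost_undisc += c
        cost_disc += c * disc

    # ---- summary ----------------------------------------------------------
    summary: dict[str, float] = {"n_patients": float(n)}
    for name, x in [
        ("qalys_discounted", qaly_disc),
        ("qalys_undiscounted", qaly_undisc),
        ("cost_discounted", cost_disc),
        ("cost_undiscounted", cost_undisc),
    ]:
        mean, se = _mean_se(x)
        summary[f"{name}_per_1000"] = 1000.0 * mean
        summary[f"{name}_se_per_1000"] = 1000.0 * se
    for year in (5, T):
        if year > T:
            continue
        hit = (first_ax_year > 0) & (first_ax_year <= year)
        mean, se = _mean_se(hit.astype(float))
        summary[f"axillary_recurrences_{year}y_per_1000"] = 1000.0 * mean
        summary[f"axillary_recurrences_{year}y_se_per_1000"] = 1000.0 * se
    ever_dm = (states == DM).any(axis=1) | (states == DEAD_CANCER).any(axis=1)
    mean, se = _mean_se(ever_dm.astype(float))
    summary["distant_metastases_per_1000"] = 1000.0 * mean
    summary["distant_metastases_se_per_1000"] = 1000.0 * se

    return MicrosimResult(
        config=config,
        states=states,
        pathway=pathway,
        nodal_positive=positive,
        lymphoedema=lymph,
        qaly_disc=qaly_disc,
        qaly_undisc=qaly_undisc,
        cost_disc=cost_disc,
        cost_undisc=cost_undisc,
        first_ax_year=first_ax_year,
        summary=summary,
    )


# --------------------------------------------------------------------------
# Random parameter sets within plausible ranges
# --------------------------------------------------------------------------

_COST_ITEMS = [
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
]


def check_feasibility(params: ParameterSet, settings: ModelSettings | None = None):
    """Raise ValueError if any state's competing probabilities can exceed 1."""
    settings = settings or ModelSettings()
    q_max = float(np.max(params.other_cause_mortality))
    rows = {
        "disease free (FN)": params.p_dm_first_node_pos
        + params.p_local_recur_first
        + params.p_axillary_recur_given_fn
        + q_max,
        "disease free, post axillary": max(
            params.p_dm_after_axillary_pos, params.p_dm_after_axillary_neg
        )
        + params.p_local_recur_first
        + params.p_axillary_recur_first
        + q_max,
        "distant metastases": params.p_death_after_dm + q_max,
        "staging tree": params.p_slnb_fail + params.p_slnb_fn,
    }
    for label, total in rows.items():
        if total > 1.0:
            raise ValueError(f"infeasible parameters: {label} sums to {total:.4f} > 1")


def draw_parameter_sets(
    n: int,
    seed: int,
    base_params: ParameterSet | None = None,
    base_costs: CostSet | None = None,
    ranges: dict | None = None,
    multiplier_range: tuple[float, float] = COST_RANGE_MULTIPLIER,
    max_retries: int = 100,
) -> list[tuple[ParameterSet, CostSet]]:
    """Independent uniform draws within each parameter's plausible range.

    Probabilities and utilities draw uniformly on [low, high] (``ranges``
    defaults to the published plausible ranges); each cost item draws a
    uniform multiplier on the +/-20% band.  Infeasible draws (competing
    probabilities exceeding 1) are redrawn up to ``max_retries`` times each.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    base_params = base_params or ParameterSet()
    base_costs = base_costs or CostSet()
    ranges = PARAMETER_RANGES if ranges is None else ranges
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        for attempt in range(max_retries + 1):
            kw = {
                name: float(rng.uniform(spec.low, spec.high))
                for name, spec in ranges.items()
            }
            lo, hi = multiplier_range
            ckw = {
                item: float(getattr(base_costs, item) * rng.uniform(lo, hi))
                for item in _COST_ITEMS
            }
            try:
                p = base_params.replace(**kw)
                check_feasibility(p)
                c = base_costs.replace(**ckw)
            except (ValueError, KeyError):
                if attempt == max_retries:
                    raise RuntimeError(
                        f"no feasible draw after {max_retries} retries"
                    )
                continue
            out.append((p, c))
            break
    return out
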