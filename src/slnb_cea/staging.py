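"""Upfront staging decision tree: cohort strata, surgical costs, lymphoedema.

Each arm of the comparison (SLNB-based staging versus ALND for everyone) is
decomposed into cohort strata defined by true nodal status and the staging
pathway the patient follows.  A stratum carries its cohort weight, its
upfront (surgery + adjuvant) cost, its lymphoedema probability and whether
its axillary-recurrence risk is elevated (the false-negative pathway).

Lymphoedema risk follows the axillary surgery actually received: SLNB-arm
patients whose biopsy is positive or fails proceed to completion ALND and
take the ALND lymphoedema probability; only patients staged negative by a
successful SLNB (true negatives and false negatives) retain the lower
SLNB-only risk.  Lymphoedema is assigned once at baseline and is permanent.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .parameters import CostSet, ParameterSet

__all__ = [
    "StrategyId",
    "Pathway",
    "NodalStatus",
    "StratumSpec",
    "build_strata",
    "arm_lymphoedema_probability",
    "expected_arm_lymphoedema_prevalence",
    "expected_upfront_cost",
    "strata_to_csv",
]

_WEIGHT_TOL = 1e-12


class StrategyId(str, enum.Enum):
    SLNB = "SLNB"
    ALND = "ALND"


class NodalStatus(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"


class Pathway(str, enum.Enum):
    ALND_DIRECT = "ALND_direct"
    SLNB_TRUE_NEGATIVE = "SLNB_true_negative"
    SLNB_FALSE_NEGATIVE = "SLNB_false_negative"
    SLNB_POSITIVE_TO_ALND = "SLNB_positive_to_ALND"
    SLNB_FAIL_TO_ALND = "SLNB_fail_to_ALND"


#: Pathways in which the patient ultimately undergoes ALND.
_ALND_PATHWAYS = {
    Pathway.ALND_DIRECT,
    Pathway.SLNB_POSITIVE_TO_ALND,
    Pathway.SLNB_FAIL_TO_ALND,
}


@dataclass(frozen=True)
class StratumSpec:
    """One cohort stratum: pathway x nodal status, with accrual rules."""

    strategy: StrategyId
    nodal_status: NodalStatus
    pathway: Pathway
    weight: float
    upfront_cost: float
    p_lymphoedema: float
    fn_elevated: bool = False

    def __post_init__(self) -> None:
        if self.fn_elevated and self.pathway is not Pathway.SLNB_FALSE_NEGATIVE:
            raise ValueError("fn_elevated profile is exclusive to the FN pathway")
        if self.pathway is Pathway.SLNB_FALSE_NEGATIVE and (
            self.strategy is not StrategyId.SLNB
            or self.nodal_status is not NodalStatus.POSITIVE
        ):
            raise ValueError("FN pathway requires SLNB strategy and positive nodes")


def arm_lymphoedema_probability(
    strategy: StrategyId, params: ParameterSet
) -> float:
    """Published arm-level moderate-severe lymphoedema probability.

    These are the two trial-reported input rates (0.176 after ALND, 0.119
    after SLNB at base case).  The model applies them per pathway, so the
    realised SLNB-arm prevalence is a mixture; see
    :func:`expected_arm_lymphoedema_prevalence`.
    """
    if StrategyId(strategy) is StrategyId.ALND:
        return params.p_lymph_alnd
    return params.p_lymph_slnb


def _pathway_lymphoedema(pathway: Pathway, params: ParameterSet) -> float:
    if pathway in _ALND_PATHWAYS:
        return params.p_lymph_alnd
    return params.p_lymph_slnb


def build_strata(
    strategy: StrategyId, params: ParameterSet, costs: CostSet
) -> list[StratumSpec]:
    """Split one arm's cohort into strata by nodal status and pathway.

    SLNB-arm weights follow the staging tree with p = probability of
    node-positive disease, f = probability of SLNB mapping failure, and
    fn = false-negative probability among node-positive patients (failed
    mappings convert to ALND, so the detected-positive branch carries the
    remaining 1 - f - fn).
    """
    strategy = StrategyId(strategy)
    p = params.p_node_positive
    adjuvant = costs.adjuvant_cost(strategy.value)

    if strategy is StrategyId.ALND:
        strata = [
            StratumSpec(
                strategy,
                status,
                Pathway.ALND_DIRECT,
                weight,
                costs.c_alnd + adjuvant,
                _pathway_lymphoedema(Pathway.ALND_DIRECT, params),
            )
            for status, weight in [
                (NodalStatus.POSITIVE, p),
                (NodalStatus.NEGATIVE, 1.0 - p),
            ]
        ]
    else:
        f = params.p_slnb_fail
        fn = params.p_slnb_fn
        if f + fn > 1.0:
            raise ValueError(
                f"p_slnb_fail + p_slnb_fn = {f + fn} > 1: the node-positive "
                "branches of the staging tree are infeasible"
            )
        rows = [
            (NodalStatus.NEGATIVE, Pathway.SLNB_FAIL_TO_ALND, (1 - p) * f,
             costs.c_slnb_fail_then_alnd, False),
            (NodalStatus.NEGATIVE, Pathway.SLNB_TRUE_NEGATIVE, (1 - p) * (1 - f),
             costs.c_slnb_neg, False),
            (NodalStatus.POSITIVE, Pathway.SLNB_FAIL_TO_ALND, p * f,
             costs.c_slnb_fail_then_alnd, False),
            (NodalStatus.POSITIVE, Pathway.SLNB_FALSE_NEGATIVE,
             p * fn, costs.c_slnb_neg, True),
            (NodalStatus.POSITIVE, Pathway.SLNB_POSITIVE_TO_ALND,
             p * (1 - f - fn), costs.c_slnb_pos_then_alnd, False),
        ]
        strata = [
            StratumSpec(
                strategy,
                status,
                pathway,
                weight,
                surgical + adjuvant,
                _pathway_lymphoedema(pathway, params),
                fn_elevated=elevated,
            )
            for status, pathway, weight, surgical, elevated in rows
        ]

    total = sum(s.weight for s in strata)
    if abs(total - 1.0) > _WEIGHT_TOL:
        raise ValueError(
            f"{strategy.value} stratum weights sum to {total!r}, expected 1"
        )
    return strata


def expected_arm_lymphoedema_prevalence(
    strategy: StrategyId, params: ParameterSet
) -> float:
    """Weight-averaged lymphoedema prevalence realised in one arm."""
    costs = CostSet()  # costs do not affect weights or lymphoedema
    strata = build_strata(strategy, params, costs)
    return sum(s.weight * s.p_lymphoedema for s in strata)


def expected_upfront_cost(
    strategy: StrategyId, params: ParameterSet, costs: CostSet
) -> float:
    """Expected upfront (surgery + adjuvant) cost per patient for one arm."""
    return sum(s.weight * s.upfront_cost for s in build_strata(strategy, params, costs))


def strata_to_csv(
    strata: list[StratumSpec], path: str | Path | None = None
) -> str:
    """Serialise strata to CSV for inspection (one row per stratum)."""
    df = pd.DataFrame(
        [
            {
                "strategy": s.strategy.value,
                "nodal_status": s.nodal_status.value,
                "pathway": s.pathway.value,
                "weight": s.weight,
                "upfront_cost": s.upfront_cost,
                "p_lymphoedema": s.p_lymphoedema,
                "fn_elevated": s.fn_elevated,
            }
            for s in strata
        ]
    )
    buf = io.StringIO()
    df.to_csv(buf, index=False)
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text
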