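"""Calibrate the built-in Gompertz background-mortality schedule.

Solves for (A, B) in q(age) = A * exp(B * (age - 58)) such that the ALND arm
of the base-case cohort accrues 18.4 other-cause deaths per 1000 by year 5
and 160.1 per 1000 by year 20.  The resulting constants are frozen in
``slnb_cea.parameters`` (_GOMPERTZ_A, _GOMPERTZ_B); rerun this script only
if the model structure changes.

Usage: python scripts/calibrate_mortality.py
"""

import numpy as np
from scipy.optimize import fsolve

from slnb_cea.markov import run_strategy
from slnb_cea.parameters import (
    MORTALITY_AGE_END,
    MORTALITY_AGE_START,
    CostSet,
    ModelSettings,
    ParameterSet,
)
from slnb_cea.staging import StrategyId

TARGET_5Y = 18.4
TARGET_20Y = 160.1


def other_deaths(log_a: float, b: float) -> tuple[float, float]:
    ages = np.arange(MORTALITY_AGE_START, MORTALITY_AGE_END + 1)
    q = np.exp(log_a) * np.exp(b * (ages - MORTALITY_AGE_START))
    params = ParameterSet(other_cause_mortality=q)
    res = run_strategy(StrategyId.ALND, params, CostSet(), ModelSettings())
    return res.at(5)["other_deaths"], res.at(20)["other_deaths"]


def residuals(x):
    d5, d20 = other_deaths(x[0], x[1])
    return [d5 - TARGET_5Y, d20 - TARGET_20Y]


if __name__ == "__main__":
    sol = fsolve(residuals, x0=[np.log(0.0035), 0.10], full_output=False, xtol=1e-12)
    log_a, b = sol
    a = float(np.exp(log_a))
    d5, d20 = other_deaths(log_a, b)
    print(f"_GOMPERTZ_A = {a:.6e}")
    print(f"_GOMPERTZ_B = {b:.6e}")
    print(f"other-cause deaths per 1000: 5y {d5:.3f} (target {TARGET_5Y}), "
          f"20y {d20:.3f} (target {TARGET_20Y})")
    q58 = a
    q77 = a * np.exp(b * 19)
    print(f"q(58) = {q58:.5f}, q(77) = {q77:.5f}")
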