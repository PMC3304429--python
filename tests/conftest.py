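import pytest

from slnb_cea.parameters import CostSet, ModelSettings, ParameterSet


@pytest.fixture
def base_params() -> ParameterSet:
    return ParameterSet()


@pytest.fixture
def base_costs() -> CostSet:
    return CostSet()


@pytest.fixture
def base_settings() -> ModelSettings:
    return ModelSettings()


@pytest.fixture
def symmetric_inputs() -> tuple[ParameterSet, CostSet, ModelSettings]:
    """Inputs under which the two arms are structurally identical.

    No mapping failures or false negatives, equal lymphoedema risk and
    equal surgical costs, so any SLNB-minus-ALND difference is a bug.
    """
    params = ParameterSet(p_slnb_fail=0.0, p_slnb_fn=0.0, p_lymph_slnb=0.176)
    costs = CostSet(
        c_slnb_neg=CostSet().c_alnd,
        c_slnb_pos_then_alnd=CostSet().c_alnd,
        c_slnb_fail_then_alnd=CostSet().c_alnd,
    )
    return params, costs, ModelSettings()
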