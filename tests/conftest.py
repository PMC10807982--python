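import dataclasses

import pytest
from hypothesis import strategies as st

from cultsim import DEFAULT_INITIAL, ModelParams, SimplexState


@pytest.fixture
def headline_params() -> ModelParams:
    """The canonical parameter set used throughout the analyses."""
    return ModelParams(mu=0.01, m=0.1, c=0.75, se=0.5, si=0.1)


@pytest.fixture
def all_inefficient() -> SimplexState:
    return DEFAULT_INITIAL


def replace(params: ModelParams, **kw) -> ModelParams:
    return dataclasses.replace(params, **kw)


@st.composite
def simplex_states(draw) -> SimplexState:
    n = draw(st.floats(0.0, 1.0, allow_nan=False))
    i = draw(st.floats(0.0, 1.0, allow_nan=False))
    total = n + i
    if total > 1.0:
        n, i = n / total, i / total
    e = 1.0 - n - i
    return SimplexState(n, i, max(e, 0.0))


@st.composite
def model_params(draw, se_gt_si: bool = False) -> ModelParams:
    si = draw(st.floats(0.0, 0.5, allow_nan=False))
    se_min = si + 1e-3 if se_gt_si else 0.0
    return ModelParams(
        mu=draw(st.floats(0.0, 0.1, allow_nan=False)),
        m=draw(st.floats(0.0, 1.0, allow_nan=False)),
        c=draw(st.floats(0.0, 1.0, allow_nan=False)),
        se=draw(st.floats(se_min, 1.0, allow_nan=False)),
        si=si,
    )
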