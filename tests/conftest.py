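import numpy as np
import pytest

from pkscale import ConcentrationProfile, OneCptOralParams, Regimen, closed_form_one_cpt_oral


@pytest.fixture
def one_cpt_params() -> OneCptOralParams:
    """dose=100, ka=1/h, V=10, CL=1 L/h -> ke=0.1/h; the worked reference case."""
    return OneCptOralParams(ka=1.0, V_over_F=10.0, CL_over_F=1.0)


@pytest.fixture
def dense_one_cpt_profile(one_cpt_params) -> ConcentrationProfile:
    """Noise-free dense profile over ten-plus half-lives (0-120 h, 0.1 h grid)."""
    times = np.arange(0.0, 120.0 + 1e-9, 0.1)
    conc = closed_form_one_cpt_oral(one_cpt_params, 100.0, times)
    return ConcentrationProfile("parent", times, conc, subject_id="dense")


@pytest.fixture
def single_dose_regimen() -> Regimen:
    return Regimen.single(100.0)
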