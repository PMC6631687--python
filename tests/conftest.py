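import numpy as np
import pytest

from ivivekit import PROFILES, NoiseConfig


# published reference values used as fixed inputs in several tests:
# (log P, in vitro t1/2 min, CL_int mL/min/kg, predicted CL_p,
#  observed CL_p, V_d mL/kg, terminal t1/2 min)
REFERENCE = {
    "CBX": dict(log_p=2.19, t_half=35.1, cl_int=106.1, cl_p_pred=2.72,
                cl_p_obs=3.22, v_d=356.0, t_half_term=76.5),
    "MCBX": dict(log_p=2.82, t_half=19.8, cl_int=204.1, cl_p_pred=7.76,
                 cl_p_obs=9.10, v_d=715.0, t_half_term=54.5),
    "CPFPX": dict(log_p=2.93, t_half=14.0, cl_int=295.0, cl_p_pred=4.70,
                  cl_p_obs=7.10, v_d=523.0, t_half_term=51.0),
}

Q_RAT = 55.0  # hepatic blood flow, mL/min/kg


@pytest.fixture(scope="session")
def profiles():
    return PROFILES


@pytest.fixture
def noiseless():
    return NoiseConfig.noiseless()


@pytest.fixture
def default_grid():
    return np.array(
        [1, 2, 3, 5, 7.5, 10, 15, 20, 30, 40, 60, 90, 120, 150, 180],
        dtype=float,
    )
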