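import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy.optimize import brentq

import rubiscotherm as rt

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def kinetics_table():
    """Bundled reference in vitro kinetics (labels 10C, 20C, 30C)."""
    return rt.builtin_kinetics()


@pytest.fixture(scope="session")
def reference_values():
    """Bundled leaf-level reference means for the 2x2 design."""
    return rt.builtin_reference_values()


@pytest.fixture(scope="session")
def noiseless_truth():
    """Default study truth with gas-exchange noise switched off."""
    return rt.default_truth(seed=3, noise_sd_gas=0.0)


def fixed_point_assimilation(p: rt.FvCBParameters, c_i: float) -> float:
    """Independent oracle: solve A = assimilation_cc(C_i - A/g_m) by
    bracketed root finding (never via the quadratic under test)."""

    def gap(a):
        cc = c_i - a / p.g_m
        return a - rt.assimilation_cc(p, max(cc, 0.0)).a_net

    hi = min(p.v_cmax, p.j_max / 4.0) + 1.0
    return brentq(gap, -p.r_d - 50.0, hi, xtol=1e-13, rtol=8.9e-16)


@pytest.fixture(scope="session")
def fp_oracle():
    return fixed_point_assimilation


def random_fvcb_parameters(rng: np.random.Generator) -> rt.FvCBParameters:
    return rt.FvCBParameters(
        v_cmax=rng.uniform(20.0, 150.0),
        j_max=rng.uniform(40.0, 300.0),
        r_d=rng.uniform(0.5, 4.0),
        g_m=rng.uniform(0.05, 0.5),
        gamma_star=rng.uniform(20.0, 80.0),
        k_m=rng.uniform(300.0, 1200.0),
    )
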