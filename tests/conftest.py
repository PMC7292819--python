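import numpy as np
import pytest

from binaryswitch import BinarySwitchParams, CalibrationTheta


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def logistic_params():
    """No-switch parameters: collapses to logistic growth with capacity 1 - alpha."""
    return BinarySwitchParams(r=1.0, R=1.0, alpha=0.2, beta=0.2, M=3)


@pytest.fixture
def reference_truth():
    """Best published parameter set for the U87 growth curves (threshold M=1),
    with the printed seeding densities as initial conditions."""
    return CalibrationTheta(M=1, r=0.0168, R=0.0345, alpha=0.0608,
                            beta=0.0692, C0=(0.02, 0.06, 0.2))


def random_params(rng, n, M_values=(0, 1, 2, 3, 4, 5), r_max=2.0, R_max=3.0):
    """Stream of n random parameter sets over the admissible ranges."""
    for _ in range(n):
        yield BinarySwitchParams(
            r=float(rng.uniform(0.0, r_max)), R=float(rng.uniform(0.0, R_max)),
            alpha=float(rng.uniform()), beta=float(rng.uniform()),
            M=int(rng.choice(M_values)))
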