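import numpy as np
import pytest

from scsol import builtin_dataset
from scsol.fitting import OptimizerConfig

#: generating parameter sets of realistic magnitude for every model
#: (taken from correlations of methyldopa-like solubility data)
TRUE_PARAMS = {
    "chrastil": (5.8, -4800.0, -25.5),
    "bartle": (17.1, -7270.0, 0.0101),
    "kumar_johnston": (0.17, 0.0065, -4876.0),
    "mst_binary": (-9720.0, 3.356, 17.45),
    "mst_ternary": (-9700.0, 3.0, 17.5, 15000.0),
    "sodeifian_sajadian": (-1.77, -0.5815, 0.0177, 0.9367),
    "gonzalez": (3.27, 0.955, -4547.2, -12.075),
    "soltani_mazloumi": (-1.306, -5668.5, 1.215, 0.162, 0.972),
    "jouyban": (-63.57, 53.19, -0.0144, -0.00195, 0.000479, -0.00599, 9.51),
    "garlapati_madras": (2.903, 1.295, 0.003, -4908.2, 0.424, 1.44, -0.477),
}

COSOLVENT_LEVELS = (0.01, 0.03)


@pytest.fixture(scope="session")
def binary():
    return builtin_dataset("binary")


@pytest.fixture(scope="session")
def ternary():
    return builtin_dataset("ternary")


@pytest.fixture(scope="session")
def ethanol1():
    return builtin_dataset("ethanol-1%")


@pytest.fixture(scope="session")
def ethanol3():
    return builtin_dataset("ethanol-3%")


@pytest.fixture(scope="session")
def fast_config():
    """Small but convergent annealing budget for unit tests."""
    return OptimizerConfig(seed=7, n_restarts=2, steps_per_temp=40, n_temps=40)


def relative_error(fitted, truth):
    fitted = np.asarray(fitted, dtype=float)
    truth = np.asarray(truth, dtype=float)
    return np.abs(fitted - truth) / np.abs(truth)
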