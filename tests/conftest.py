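import numpy as np
import pytest

from cgmdissect import (
    ARModel,
    PopulationConfig,
    SensorTruth,
    SessionConfig,
    SessionTruth,
    generate_session,
)

# Published population parameters used as generative truth throughout.
TAU_MEAN = 9.4
GAIN_MEAN = np.array([1.1, -0.0009])
OFFSET_MEAN = np.array([-11.2, 0.09])
CC_COEFFS = np.array([1.584, -0.8842, 0.1798])
CC_VAR = 3.98
SSC_COEFFS = np.array([1.367, -0.4816])
SSC_VAR = 2.54

# Yule-Walker stationary variances of the two population processes,
# computed once from the 3x3 / 2x2 autocorrelation systems.
CC_STAT_VAR = 38.558255920875546
SSC_STAT_VAR = 22.237379385805813


def yule_walker_variance(coeffs, innov_var):
    """Independent oracle: solve the YW system for the stationary variance."""
    c = np.asarray(coeffs, dtype=float)
    p = c.size
    A = np.eye(p)
    b = np.zeros(p)
    for k in range(1, p + 1):
        for j in range(1, p + 1):
            m = abs(k - j)
            if m == 0:
                b[k - 1] += c[j - 1]
            else:
                A[k - 1, m - 1] -= c[j - 1]
    rho = np.linalg.solve(A, b)
    return innov_var / (1.0 - c @ rho)


@pytest.fixture(scope="session")
def mean_truth():
    """Session truth pinned at the published mean linear-model parameters."""
    sensors = [SensorTruth(GAIN_MEAN, OFFSET_MEAN) for _ in range(2)]
    return SessionTruth(TAU_MEAN, sensors)


@pytest.fixture(scope="session")
def quiet_truth():
    """Identity calibration, no kinetic lag, (near-)zero noise."""
    tiny = ARModel([0.0], 1e-20)
    sensors = [SensorTruth([1.0], [0.0], tiny) for _ in range(2)]
    return SessionTruth(0.0, sensors, tiny)


@pytest.fixture(scope="session")
def noisy_session(mean_truth):
    return generate_session(mean_truth, SessionConfig(), seed=11, session_id="s001",
                            subject_id="p01")


@pytest.fixture(scope="session")
def quiet_session(quiet_truth):
    return generate_session(quiet_truth, SessionConfig(), seed=12, session_id="s002",
                            subject_id="p01")


@pytest.fixture(scope="session")
def fixed_population():
    """Population with all dispersion off: every session at the mean truth."""
    return PopulationConfig(tau_sd=0.0, a0_sd=0.0, a1_sd=0.0, b0_sd=0.0, b1_sd=0.0)
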