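from datetime import date

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dfi.types import (
    CageCalibration,
    DfiConfig,
    LightCycle,
    MeasurementPeriod,
    SECONDS_PER_DAY,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: POSIX time of 2022-03-01T00:00:00Z, the synthetic study epoch.
EPOCH = 1646092800.0


@pytest.fixture
def calib() -> CageCalibration:
    return CageCalibration()


@pytest.fixture
def cycle() -> LightCycle:
    return LightCycle()


@pytest.fixture
def config() -> DfiConfig:
    return DfiConfig()


def make_period(n_days: int = 2, mouse_id: str = "m000") -> MeasurementPeriod:
    return MeasurementPeriod(
        mouse_id=mouse_id,
        first_full_day=date(2022, 3, 1),
        n_full_days=n_days,
        start=EPOCH,
        end=EPOCH + n_days * SECONDS_PER_DAY,
    )


@pytest.fixture
def period() -> MeasurementPeriod:
    return make_period()


def brute_force_viterbi_logprob(p_top: np.ndarray, p_stay: float,
                                p_init_top: float = 0.5) -> float:
    """Max path log-probability by exhaustive enumeration over all 2^L
    state paths (independent oracle for the Viterbi decoder)."""
    import itertools

    p_top = np.asarray(p_top, float)
    L = p_top.size
    best = -np.inf
    log_init = np.log([1 - p_init_top, p_init_top])
    with np.errstate(divide="ignore"):
        log_e = np.log(np.stack([1 - p_top, p_top], axis=1))
    log_stay = np.log(p_stay)
    log_switch = np.log(1 - p_stay)
    for path in itertools.product((0, 1), repeat=L):
        lp = log_init[path[0]] + log_e[0, path[0]]
        for t in range(1, L):
            lp += log_stay if path[t] == path[t - 1] else log_switch
            lp += log_e[t, path[t]]
        best = max(best, lp)
    return float(best)


def path_logprob(path: np.ndarray, p_top: np.ndarray, p_stay: float,
                 p_init_top: float = 0.5) -> float:
    """Log-probability of one specific state path."""
    p_top = np.asarray(p_top, float)
    with np.errstate(divide="ignore"):
        log_e = np.log(np.stack([1 - p_top, p_top], axis=1))
    lp = np.log([1 - p_init_top, p_init_top])[path[0]] + log_e[0, path[0]]
    for t in range(1, len(path)):
        lp += np.log(p_stay) if path[t] == path[t - 1] else np.log(1 - p_stay)
        lp += log_e[t, path[t]]
    return float(lp)
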