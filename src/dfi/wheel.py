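"""Wheel-derived measurements: Viterbi decoding of noisy per-frame wheel-
marker classifications into rotation events, and the three wheel components
of the DFI (distance/day, gait speed, circadian dark fraction).

The running wheel carries a single stripe; a classifier emits, per video
frame, the probability that the stripe is in the "top" position. A
two-state hidden Markov model (states top/bottom, symmetric self-transition
probability ``p_stay``) smooths classifier noise; each decoded
bottom-to-top transition is one wheel revolution.
"""

from __future__ import annotations

import numpy as np

from .types import (
    CageCalibration,
    HmmParams,
    LightCycle,
    MeasurementPeriod,
    local_hours,
)

BOTTOM, TOP = 0, 1

try:  # optional jitted kernel; the pure-Python path is complete
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _viterbi_kernel(log_e: np.ndarray, log_stay: float, log_switch: float,
                    log_init: np.ndarray) -> np.ndarray:
    """Backtraced MAP path for a symmetric two-state HMM.

    log_e: (n, 2) emission log-likelihoods. Ties broken toward staying in
    the previous state.
    """
    n = log_e.shape[0]
    back = np.zeros((n, 2), dtype=np.uint8)
    s0 = log_init[0] + log_e[0, 0]
    s1 = log_init[1] + log_e[0, 1]
    for t in range(1, n):
        # state 0: from 0 (stay) vs from 1 (switch); stay wins ties
        a = s0 + log_stay
        b = s1 + log_switch
        if a >= b:
            n0 = a + log_e[t, 0]
            back[t, 0] = 0
        else:
            n0 = b + log_e[t, 0]
            back[t, 0] = 1
        a = s1 + log_stay
        b = s0 + log_switch
        if a >= b:
            n1 = a + log_e[t, 1]
            back[t, 1] = 1
        else:
            n1 = b + log_e[t, 1]
            back[t, 1] = 0

        s0, s1 = n0, n1
    states = np.empty(n, dtype=np.uint8)
    states[n - 1] = 1 if s1 >= s0 else 0
    for t in range(n - 1, 0, -1):
        states[t - 1] = back[t, states[t]]
    return states


if _HAVE_NUMBA:
    _viterbi_kernel_jit = _njit(cache=False)(_viterbi_kernel)
else:  # pragma: no cover
    _viterbi_kernel_jit = _viterbi_kernel


def viterbi_decode(emissions: np.ndarray, params: HmmParams) -> np.ndarray:
    """Maximum-a-posteriori top/bottom state path for per-frame P(top).

    Emission likelihoods are P(obs|top) = p_top and P(obs|bottom) =
    1 - p_top. Computation is in log space (certain emissions give -inf
    log-likelihoods, handled exactly). Returns an array over
    {BOTTOM=0, TOP=1}.
    """
    p = np.asarray(emissions, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("emissions must be a non-empty 1-D array")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("emission probabilities must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        log_e = np.stack([np.log(1.0 - p), np.log(p)], axis=1)
        log_stay = float(np.log(params.p_stay))
        log_switch = float(np.log(1.0 - params.p_stay))
        log_init = np.log(
            np.array([1.0 - params.p_init_top, params.p_init_top])
        )
    return _viterbi_kernel_jit(log_e, log_stay, log_switch, log_init).astype(np.int8)


def rotations_from_states(states: np.ndarray, frame_times: np.ndarray) -> np.ndarray:
    """Rotation event times: one per bottom-to-top transition (single
    stripe, so one such transition per revolution; direction is not
    distinguishable). Returns times of the frames at which the path enters
    the top state."""
    states = np.asarray(states)
    frame_times = np.asarray(frame_times, dtype=float)
    if states.shape != frame_times.shape:
        raise ValueError("states and frame_times must have equal length")
    if states.size < 2:
        return np.empty(0, dtype=float)
    rising = (states[1:] == TOP) & (states[:-1] == BOTTOM)
    return frame_times[1:][rising]


def wheel_distance_per_day(
    events: np.ndarray, period: MeasurementPeriod, calib: CageCalibration
) -> float:
    """Average per-day distance run on the wheel, meters/day."""
    n = int(np.asarray(events).size)
    return n * calib.wheel_circumference_m / period.n_full_days


def wheel_gait_speed(
    events: np.ndarray,
    calib: CageCalibration,
    bout_gap_s: float = 2.0,
    percentile: float = 90.0,
) -> float | None:
    """Peak rotation speed on the wheel, m/s.

    Per-rotation speed = circumference / inter-event interval, computed
    only within running bouts (consecutive events at most ``bout_gap_s``
    apart); returns the configured percentile of those speeds, or None
    (missing) if no in-bout interval exists.
    """
    events = np.asarray(events, dtype=float)
    if events.size < 2:
        return None
    intervals = np.diff(events)
    in_bout = intervals <= bout_gap_s
    if not np.any(in_bout):
        return None
    speeds = calib.wheel_circumference_m / intervals[in_bout]
    return float(np.percentile(speeds, percentile))


def circadian_dark_fraction(
    weights: np.ndarray,
    times: np.ndarray,
    cycle: LightCycle,
    utc_offset_hours: float = 0.0,
    min_activity: float = 0.0,
) -> float | None:
    """Fraction of activity weight falling in the dark phase.

    ``weights`` are per-event (e.g. one per rotation) or per-bin activity
    amounts at ``times``. Returns None (missing: insufficient activity)
    when the total weight does not exceed ``min_activity``.
    """
    weights = np.asarray(weights, dtype=float)
    times = np.asarray(times, dtype=float)
    if weights.shape != times.shape:
        raise ValueError("weights and times must have equal length")
    total = float(weights.sum())
    if total <= min_activity:
        return None
    dark = cycle.is_dark(local_hours(times, utc_offset_hours))
    return float(weights[dark].sum() / total)
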