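"""Frailty parameterization and DFI aggregation.

Each of the eight raw measurements is mapped onto [0, 1] by a
threshold-linear function anchored at a "healthy" value (score 0) and a
"frail" value (score 1), with intermediate values linearly interpolated
and out-of-range values clamped — mirroring the 0/0.5/1 deficit semantics
of manual frailty indexes in continuous form. The DFI is the mean of the
eight scores; an optimized DFI averages a named 5-component subset, and a
combined FI averages paired MFI and DFI values.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import body, floor, nest, wheel
from .types import (
    AnnotationChannel,
    CageCalibration,
    COMPONENT_UNITS,
    COMPONENTS,
    ComponentResult,
    DEFAULT_OPTIMIZED_COMPONENTS,
    DfiConfig,
    DfiResult,
    MeasurementPeriod,
)

logger = logging.getLogger("dfi")


class MissingComponentError(ValueError):
    """Raised under the strict policy when any component is missing."""

    def __init__(self, missing: Sequence[str]):
        self.missing = list(missing)
        super().__init__(f"missing components: {', '.join(missing)}")


def parameterize(value: float, v_healthy: float, v_frail: float) -> float:
    """Threshold-linear frailty score: 0 at ``v_healthy``, 1 at
    ``v_frail``, linear between, clamped outside. The threshold ordering
    encodes the deficit direction."""
    if v_healthy == v_frail:
        raise ValueError("v_healthy and v_frail must differ")
    return float(np.clip((value - v_healthy) / (v_frail - v_healthy), 0.0, 1.0))


def aggregate_dfi(
    components: Mapping[str, ComponentResult],
    policy: str = "strict",
    min_components: int = 1,
) -> float:
    """Overall DFI: arithmetic mean of present component scores.

    strict: all eight components must be present, else
    MissingComponentError listing the absentees. lenient: at least
    ``min_components`` present; mean of those present.
    """
    missing = [name for name in COMPONENTS if components[name].missing]
    present = [components[name].score for name in COMPONENTS
               if not components[name].missing]
    if policy == "strict":
        if missing:
            raise MissingComponentError(missing)
    elif policy == "lenient":
        if len(present) < min_components:
            raise MissingComponentError(missing)
    else:
        raise ValueError("policy must be 'strict' or 'lenient'")
    return float(np.mean(present))


def optimized_dfi(
    components: Mapping[str, ComponentResult],
    selected: Sequence[str] = DEFAULT_OPTIMIZED_COMPONENTS,
) -> float:
    """Mean score of a named 5-component subset (the best-performing
    components)."""
    if len(selected) != 5 or len(set(selected)) != 5:
        raise ValueError("optimized DFI requires exactly 5 distinct components")
    scores = []
    for name in selected:
        if name not in components:
            raise ValueError(f"unknown component {name!r}")
        cr = components[name]
        if cr.missing:
            raise MissingComponentError([name])
        scores.append(cr.score)
    return float(np.mean(scores))


def combined_fi(mfi_overall: float, dfi_overall: float) -> float:
    """Combined frailty index: mean of a paired MFI and DFI value."""
    for name, v in (("mfi", mfi_overall), ("dfi", dfi_overall)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} value {v} outside [0, 1]")
    return (mfi_overall + dfi_overall) / 2.0


# ---------------------------------------------------------------------------
# Per-period orchestration


def _component(name: str, raw: float | None, config: DfiConfig,
               reason: str = "measurement unavailable") -> ComponentResult:
    units = COMPONENT_UNITS[name]
    if raw is None:
        return ComponentResult(name, None, units, None, reason)
    th = config.thresholds[name]
    return ComponentResult(name, raw, units,
                           parameterize(raw, th.v_healthy, th.v_frail))


def measure_period(
    channels: Mapping[str, AnnotationChannel],
    period: MeasurementPeriod,
    config: DfiConfig,
    calib: CageCalibration,
) -> dict[str, ComponentResult]:
    """Run the eight measurements for one mouse-period and parameterize
    each. Channels are sliced to the period before measuring; absent
    channels yield missing components."""
    results: dict[str, ComponentResult] = {}
    off = config.utc_offset_hours
    cycle = config.light_cycle

    # --- wheel (3 components)
    if "wheel_emission" in channels and len(channels["wheel_emission"]):
        ch = channels["wheel_emission"].slice(period.start, period.end)
        if len(ch):
            p_top = ch.samples["p_top"].to_numpy(float)
            times = ch.samples["time"].to_numpy(float)
            states = wheel.viterbi_decode(p_top, config.hmm)
            events = wheel.rotations_from_states(states, times)
            results["wheel_distance"] = _component(
                "wheel_distance",
                wheel.wheel_distance_per_day(events, period, calib), config)
            results["wheel_gait_speed"] = _component(
                "wheel_gait_speed",
                wheel.wheel_gait_speed(events, calib, config.bout_gap_s,
                                       config.wheel_speed_percentile),
                config, "fewer than 2 in-bout rotations")
            results["wheel_circadian"] = _component(
                "wheel_circadian",
                wheel.circadian_dark_fraction(
                    np.ones_like(events), events, cycle, off,
                    config.wheel_min_activity_rot),
                config, "insufficient activity")
    for name in ("wheel_distance", "wheel_gait_speed", "wheel_circadian"):
        results.setdefault(
            name, _component(name, None, config, "no wheel data in period"))

    # --- floor (2 components)
    if "track" in channels and len(channels["track"]):
        ch = channels["track"].slice(period.start, period.end)
        if len(ch):
            segments = floor.clean_track(ch, calib, config.conf_min,
                                         config.max_jump_cm, config.max_gap_s)
            results["floor_gait_speed"] = _component(
                "floor_gait_speed",
                floor.floor_gait_speed(segments, config.speed_window_s,
                                       config.move_threshold_cm_s,
                                       config.floor_speed_percentile,
                                       config.min_step_cm),
                config, "no above-threshold movement window")
            bin_times, bin_dist = floor.distance_binned(
                segments, config.circadian_bin_s, period.start, period.end,
                config.min_step_cm)
            results["floor_circadian"] = _component(
                "floor_circadian",
                floor.floor_circadian(bin_dist, bin_times, cycle, off,
                                      config.floor_min_activity_cm),
                config, "insufficient activity")
    for name in ("floor_gait_speed", "floor_circadian"):
        results.setdefault(
            name, _component(name, None, config, "no track data in period"))

    # --- body condition (2 components)
    if "weight" in channels and len(channels["weight"]):
        results["weight_change"] = _component(
            "weight_change",
            body.weight_rate_of_change(channels["weight"], period),
            config, "degenerate weight regression")
    results.setdefault(
        "weight_change",
        _component("weight_change", None, config, "no weight data in period"))

    if "coat" in channels and len(channels["coat"]):
        results["coat_roughness"] = _component(
            "coat_roughness",
            body.coat_metric(channels["coat"], period, config.coat_min_samples),
            config, "too few coat samples")
    results.setdefault(
        "coat_roughness",
        _component("coat_roughness", None, config, "no coat data in period"))

    # --- nest (1 component)
    if "nest" in channels and len(channels["nest"]):
        results["nest_movement"] = _component(
            "nest_movement",
            nest.nest_displacement(channels["nest"], calib, period,
                                   config.nest_min_area_px, config.nest_max_gap_h),
            config, "fewer than 2 qualifying nest samples")
    results.setdefault(
        "nest_movement",
        _component("nest_movement", None, config, "no nest data in period"))

    return results


def score_period(
    channels: Mapping[str, AnnotationChannel],
    period: MeasurementPeriod,
    config: DfiConfig,
    calib: CageCalibration,
) -> DfiResult:
    """Compute the full DFI for one mouse-period: eight measurements,
    parameterization, and aggregation. Pure function of its inputs."""
    components = measure_period(channels, period, config, calib)
    overall = aggregate_dfi(components, config.missing_policy,
                            config.min_components)
    n_missing = sum(cr.missing for cr in components.values())
    logger.info("scored %s @ %s: DFI=%.3f (%d missing)",
                period.mouse_id, period.first_full_day, overall, n_missing)
    return DfiResult(mouse_id=period.mouse_id, period=period,
                     components=components, overall=overall,
                     n_missing=n_missing)


def results_to_frame(results: Sequence[DfiResult]) -> pd.DataFrame:
    """One row per mouse-period: raw values, scores, overall DFI."""
    rows = []
    for r in results:
        row: dict[str, object] = {
            "mouse_id": r.mouse_id,
            "date": r.period.first_full_day,
            "n_full_days": r.period.n_full_days,
            "dfi": r.overall,
            "n_missing": r.n_missing,
        }
        for name in COMPONENTS:
            cr = r.components[name]
            row[f"{name}_raw"] = cr.raw_value
            row[f"{name}_score"] = cr.score
        rows.append(row)
    return pd.DataFrame(rows)
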