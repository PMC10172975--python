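"""Nest-material dynamics: displacement rate of the nest-mask centroid.

Nesting material (cotton) is segmented per sampled frame; its centroid and
mask area form the nest channel. The nest-movement measurement is the mean
centroid speed across consecutive valid samples, in cm/hour — reduced nest
redistribution is read as a deficit.
"""

from __future__ import annotations

import numpy as np

from .types import AnnotationChannel, CageCalibration, MeasurementPeriod


def nest_displacement(
    channel: AnnotationChannel,
    calib: CageCalibration,
    period: MeasurementPeriod,
    min_area_px: float = 100.0,
    max_gap_h: float = 2.0,
) -> float | None:
    """Average nest-centroid speed over the period, cm/hour.

    Samples whose mask area is at most ``min_area_px`` are discarded
    (segmentation dropouts); consecutive qualifying samples more than
    ``max_gap_h`` hours apart do not form a pair. The result is the mean
    over pairs of centroid displacement (cm) divided by elapsed hours, or
    None (missing) with fewer than two qualifying samples or no valid pair.
    """
    if channel.kind != "nest":
        raise ValueError(f"expected a nest channel, got {channel.kind!r}")
    df = channel.slice(period.start, period.end).samples
    ok = df["area_px"].to_numpy(float) > min_area_px
    t = df["time"].to_numpy(float)[ok]
    if t.size < 2:
        return None
    x = df["centroid_x_px"].to_numpy(float)[ok] / calib.px_per_cm
    y = df["centroid_y_px"].to_numpy(float)[ok] / calib.px_per_cm
    dt_h = np.diff(t) / 3600.0
    pair_ok = dt_h <= max_gap_h
    if not np.any(pair_ok):
        return None
    disp_cm = np.hypot(np.diff(x), np.diff(y))[pair_ok]
    return float(np.mean(disp_cm / dt_h[pair_ok]))
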