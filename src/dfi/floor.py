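"""Floor-of-cage measurements from centroid tracking: distance traveled,
floor gait speed, and the floor circadian component.

The tracker reports a per-frame centroid (pixels) with a confidence;
cleaning drops low-confidence detections and splits the track at temporal
gaps and physically impossible jumps before any distance is accumulated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import AnnotationChannel, CageCalibration, LightCycle
from .wheel import circadian_dark_fraction


@dataclass(frozen=True)
class TrackSegment:
    """A contiguous run of confident track samples, in physical units."""

    times: np.ndarray   # POSIX seconds
    x_cm: np.ndarray
    y_cm: np.ndarray

    def __len__(self) -> int:
        return len(self.times)

    @property
    def step_lengths_cm(self) -> np.ndarray:
        return np.hypot(np.diff(self.x_cm), np.diff(self.y_cm))


def clean_track(
    channel: AnnotationChannel,
    calib: CageCalibration,
    conf_min: float = 0.5,
    max_jump_cm: float = 20.0,
    max_gap_s: float = 2.0,
) -> list[TrackSegment]:
    """Filter and segment a raw centroid track.

    Samples with confidence below ``conf_min`` are dropped; the remaining
    track is split wherever adjacent samples are more than ``max_gap_s``
    apart in time or more than ``max_jump_cm`` apart in space (detector
    glitches / identity teleports). May return an empty list.
    """
    if channel.kind != "track":
        raise ValueError(f"expected a track channel, got {channel.kind!r}")
    df = channel.samples
    keep = df["confidence"].to_numpy(float) >= conf_min
    t = df["time"].to_numpy(float)[keep]
    x = df["x_px"].to_numpy(float)[keep] / calib.px_per_cm
    y = df["y_px"].to_numpy(float)[keep] / calib.px_per_cm
    if t.size == 0:
        return []
    dt = np.diff(t)
    jump = np.hypot(np.diff(x), np.diff(y))
    cut = np.nonzero((dt > max_gap_s) | (jump > max_jump_cm))[0] + 1
    segments = []
    for idx in np.split(np.arange(t.size), cut):
        if idx.size:
            segments.append(TrackSegment(t[idx], x[idx], y[idx]))
    return segments


def distance_binned(
    segments: list[TrackSegment],
    bin_s: float,
    t0: float,
    t1: float,
    min_step_cm: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Distance traveled (cm) per time bin over [t0, t1).

    Steps never span segment boundaries; a step spanning a bin boundary is
    assigned to the bin of its earlier sample. Steps shorter than
    ``min_step_cm`` count as zero (sub-pixel tracker jitter would
    otherwise accumulate into spurious distance). Returns
    (bin_start_times, distances).
    """
    n_bins = int(np.ceil((t1 - t0) / bin_s))
    dist = np.zeros(n_bins)
    for seg in segments:
        if len(seg) < 2:
            continue
        steps = seg.step_lengths_cm
        if min_step_cm > 0:
            steps = np.where(steps < min_step_cm, 0.0, steps)
        idx = np.floor((seg.times[:-1] - t0) / bin_s).astype(int)
        ok = (idx >= 0) & (idx < n_bins)
        np.add.at(dist, idx[ok], steps[ok])
    return t0 + bin_s * np.arange(n_bins), dist


def floor_gait_speed(
    segments: list[TrackSegment],
    window_s: float = 1.0,
    move_threshold_cm_s: float = 0.5,
    percentile: float = 90.0,
    min_step_cm: float = 0.0,
) -> float | None:
    """Peak locomotion speed on the cage floor, cm/s.

    Each segment is tiled with ``window_s`` windows from its start; a
    window's speed is its in-window path length divided by the window
    length. The configured percentile of above-threshold window speeds is
    returned, or None (missing) when no window qualifies.
    """
    speeds = []
    for seg in segments:
        if len(seg) < 2:
            continue
        steps = seg.step_lengths_cm
        if min_step_cm > 0:
            steps = np.where(steps < min_step_cm, 0.0, steps)
        idx = np.floor((seg.times[:-1] - seg.times[0]) / window_s).astype(int)
        w = np.zeros(idx.max() + 1)
        np.add.at(w, idx, steps)
        speeds.append(w / window_s)
    if not speeds:
        return None
    all_speeds = np.concatenate(speeds)
    moving = all_speeds[all_speeds > move_threshold_cm_s]
    if moving.size == 0:
        return None
    return float(np.percentile(moving, percentile))


def floor_circadian(
    bin_distances: np.ndarray,
    bin_times: np.ndarray,
    cycle: LightCycle,
    utc_offset_hours: float = 0.0,
    min_activity_cm: float = 10.0,
) -> float | None:
    """Dark-phase fraction of floor movement: identical contract to the
    wheel circadian measurement, with per-bin distance as the activity
    weight."""
    return circadian_dark_fraction(
        bin_distances, bin_times, cycle, utc_offset_hours, min_activity_cm
    )
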