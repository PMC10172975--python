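"""Domain types shared across the Digital Frailty Index (DFI) pipeline.

The pipeline converts per-frame home-cage video annotations (wheel-marker
classifications, centroid tracks, body-weight estimates, coat-roughness
samples, nest-material tracks) into eight behavioural/physiological
measurements per mouse-period, parameterizes each into a [0, 1] frailty
score, and averages them into a DFI value comparable to a manually
administered frailty index (MFI).

Times are POSIX seconds (UTC) internally; calendar logic (full observation
days, light/dark phase) is evaluated in a configurable fixed local offset.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta, timezone
from typing import Mapping

import numpy as np
import pandas as pd

SECONDS_PER_DAY = 86_400

#: The eight DFI components, in canonical order.
COMPONENTS = (
    "wheel_distance",      # average per-day distance run on the wheel (m/day)
    "wheel_gait_speed",    # peak rotation speed on the wheel (m/s)
    "floor_gait_speed",    # peak locomotion speed on the cage floor (cm/s)
    "wheel_circadian",     # dark-phase fraction of wheel activity
    "floor_circadian",     # dark-phase fraction of floor movement
    "weight_change",       # body-weight rate of change (g/day)
    "coat_roughness",      # Sobel-gradient image roughness over the mouse mask
    "nest_movement",       # displacement rate of nesting material (cm/h)
)

#: Units for each component's raw measurement.
COMPONENT_UNITS: Mapping[str, str] = {
    "wheel_distance": "m/day",
    "wheel_gait_speed": "m/s",
    "floor_gait_speed": "cm/s",
    "wheel_circadian": "fraction",
    "floor_circadian": "fraction",
    "weight_change": "g/day",
    "coat_roughness": "intensity/px",
    "nest_movement": "cm/h",
}

#: Default optimized-DFI selection: the three gait/wheel components plus the
#: two circadian components, the arenas with the strongest benchmark
#: correlations.
DEFAULT_OPTIMIZED_COMPONENTS = (
    "wheel_distance",
    "wheel_gait_speed",
    "floor_gait_speed",
    "wheel_circadian",
    "floor_circadian",
)

CHANNEL_KINDS = ("wheel_emission", "track", "weight", "coat", "nest")

#: Payload columns per channel kind (every channel also has a "time" column,
#: POSIX seconds).
CHANNEL_COLUMNS: Mapping[str, tuple[str, ...]] = {
    "wheel_emission": ("p_top",),
    "track": ("x_px", "y_px", "confidence"),
    "weight": ("grams", "weight_w"),
    "coat": ("roughness",),
    "nest": ("centroid_x_px", "centroid_y_px", "area_px"),
}


# ---------------------------------------------------------------------------
# Light cycle and calibration


@dataclass(frozen=True)
class LightCycle:
    """Dark/light partition of the local day.

    ``dark_onset_hour`` is the local hour-of-day at which the dark phase
    begins; ``dark_duration_h`` its length in hours. The default 18:00 +
    12 h models a standard 12:12 vivarium cycle.
    """

    dark_onset_hour: float = 18.0
    dark_duration_h: float = 12.0

    def __post_init__(self) -> None:
        if not 0 <= self.dark_onset_hour < 24:
            raise ValueError("dark_onset_hour must be in [0, 24)")
        if not 0 < self.dark_duration_h < 24:
            raise ValueError("dark_duration_h must be in (0, 24)")

    def is_dark(self, local_hour: np.ndarray | float) -> np.ndarray | bool:
        """Whether local hour-of-day value(s) fall in the dark phase."""
        return (np.asarray(local_hour) - self.dark_onset_hour) % 24.0 < self.dark_duration_h


@dataclass(frozen=True)
class CageCalibration:
    """Scalar geometry of one video cage.

    Image convention: origin top-left, x rightward, y downward. The paper's
    cages use fixed overhead cameras, so a single px/cm scalar suffices.
    """

    px_per_cm: float = 18.0
    wheel_circumference_m: float = 0.4

    def __post_init__(self) -> None:
        if self.px_per_cm <= 0:
            raise ValueError("px_per_cm must be positive")
        if self.wheel_circumference_m <= 0:
            raise ValueError("wheel_circumference_m must be positive")


# ---------------------------------------------------------------------------
# Occupancy and measurement periods


@dataclass(frozen=True)
class OccupancyRecord:
    """One interval during which a mouse occupied a camera-equipped cage
    position. Times are POSIX seconds."""

    device_id: str
    cage_position: str
    mouse_id: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"occupancy interval for {self.mouse_id!r} has start >= end"
            )


@dataclass(frozen=True)
class MeasurementPeriod:
    """A contiguous run of full local observation days for one mouse, over
    which one DFI value is computed."""

    mouse_id: str
    first_full_day: date
    n_full_days: int
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.n_full_days < 1:
            raise ValueError("n_full_days must be >= 1")
        if abs((self.end - self.start) - self.n_full_days * SECONDS_PER_DAY) > 1e-6:
            raise ValueError("period must span exactly n_full_days whole days")

    @property
    def duration_days(self) -> float:
        return (self.end - self.start) / SECONDS_PER_DAY


# ---------------------------------------------------------------------------
# Annotation channels


@dataclass
class AnnotationChannel:
    """A time-stamped sample stream for one sensor-derived quantity of one
    cage.

    ``samples`` is a DataFrame with a ``time`` column (POSIX seconds,
    strictly increasing) plus the payload columns for ``kind`` (see
    :data:`CHANNEL_COLUMNS`).
    """

    kind: str
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.kind not in CHANNEL_COLUMNS:
            raise ValueError(f"unknown channel kind {self.kind!r}")
        required = ("time",) + CHANNEL_COLUMNS[self.kind]
        missing = [c for c in required if c not in self.samples.columns]
        if missing:
            raise ValueError(f"{self.kind} channel missing columns {missing}")
        if tuple(self.samples.columns) != required:  # avoid needless copy
            self.samples = self.samples.loc[:, list(required)].reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        """Raise ValueError naming the offending row on any invariant breach."""
        df = self.samples
        t = df["time"].to_numpy(float)
        if len(t) > 1:
            bad = np.nonzero(np.diff(t) <= 0)[0]
            if bad.size:
                raise ValueError(
                    f"{self.kind} channel: non-increasing timestamp at row {bad[0] + 1}"
                )
        checks: dict[str, tuple[float, float]] = {}
        if self.kind == "wheel_emission":
            checks["p_top"] = (0.0, 1.0)
        elif self.kind == "track":
            checks["confidence"] = (0.0, 1.0)
        elif self.kind == "weight":
            g = df["grams"].to_numpy(float)
            bad = np.nonzero(~(g > 0))[0]
            if bad.size:
                raise ValueError(f"weight channel: non-positive grams at row {bad[0]}")
            checks["weight_w"] = (0.0, np.inf)
        elif self.kind == "coat":
            checks["roughness"] = (0.0, np.inf)
        elif self.kind == "nest":
            checks["area_px"] = (0.0, np.inf)
        for col, (lo, hi) in checks.items():
            v = df[col].to_numpy(float)
            bad = np.nonzero((v < lo) | (v > hi))[0]
            if bad.size:
                raise ValueError(
                    f"{self.kind} channel: {col}={v[bad[0]]} out of range "
                    f"[{lo}, {hi}] at row {bad[0]}"
                )

    def __len__(self) -> int:
        return len(self.samples)

    def slice(self, start: float, end: float) -> "AnnotationChannel":
        """Samples with start <= time < end (no re-validation needed)."""
        df = self.samples
        t = df["time"].to_numpy(float)
        lo, hi = np.searchsorted(t, [start, end], side="left")
        out = AnnotationChannel.__new__(AnnotationChannel)
        out.kind = self.kind
        if lo == 0 and hi == len(df):
            out.samples = df
        else:
            out.samples = df.iloc[lo:hi].reset_index(drop=True)
        return out


# ---------------------------------------------------------------------------
# MFI


N_MFI_ITEMS = 29
_MFI_ALLOWED = (0.0, 0.5, 1.0)


@dataclass(frozen=True)
class MfiRecord:
    """One manually administered frailty assessment: 29 clinical items each
    scored 0 / 0.5 / 1; the overall MFI is their mean."""

    mouse_id: str
    assay_date: date
    item_scores: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.item_scores) != N_MFI_ITEMS:
            raise ValueError(
                f"MFI record needs exactly {N_MFI_ITEMS} items, "
                f"got {len(self.item_scores)}"
            )
        for i, v in enumerate(self.item_scores):
            if v not in _MFI_ALLOWED:
                raise ValueError(
                    f"MFI item {i} for {self.mouse_id!r} is {v}; "
                    "allowed values are 0, 0.5, 1"
                )

    @property
    def overall(self) -> float:
        return float(np.mean(self.item_scores))


# ---------------------------------------------------------------------------
# Configuration


@dataclass(frozen=True)
class HmmParams:
    """Two-state (wheel-marker top/bottom) HMM used by Viterbi decoding.

    ``p_stay`` is the symmetric self-transition probability; emissions are
    the classifier's per-frame P(marker is top).
    """

    p_stay: float = 0.98
    p_init_top: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.p_stay < 1:
            raise ValueError("p_stay must be in (0, 1)")
        if not 0 <= self.p_init_top <= 1:
            raise ValueError("p_init_top must be in [0, 1]")


@dataclass(frozen=True)
class ComponentThresholds:
    """Anchors of the threshold-linear frailty parameterization: the raw
    value mapping to score 0 (healthy) and to score 1 (frail). Direction is
    encoded by the ordering; values between are linearly interpolated and
    clamped."""

    v_healthy: float
    v_frail: float

    def __post_init__(self) -> None:
        if self.v_healthy == self.v_frail:
            raise ValueError("v_healthy and v_frail must differ")


def _default_thresholds() -> dict[str, ComponentThresholds]:
    # Placeholder anchors calibrated on the package's synthetic-cage
    # simulator (healthy vs frail phenotype endpoints); the study's own
    # values were set ad hoc on age-stratified training cohorts and belong
    # in a site config.
    return {
        "wheel_distance": ComponentThresholds(1350.0, 240.0),
        "wheel_gait_speed": ComponentThresholds(0.105, 0.052),
        "floor_gait_speed": ComponentThresholds(8.0, 2.1),
        "wheel_circadian": ComponentThresholds(0.87, 0.62),
        "floor_circadian": ComponentThresholds(0.83, 0.64),
        "weight_change": ComponentThresholds(0.0, -0.5),
        "coat_roughness": ComponentThresholds(10.0, 20.0),
        "nest_movement": ComponentThresholds(4.9, 0.7),
    }


@dataclass(frozen=True)
class DfiConfig:
    """All tunable settings of the scoring pipeline.

    Defaults are documented in docs/methods.md; the threshold anchors ship
    as simulator-calibrated placeholders.
    """

    thresholds: Mapping[str, ComponentThresholds] = field(
        default_factory=_default_thresholds
    )
    light_cycle: LightCycle = field(default_factory=LightCycle)
    utc_offset_hours: float = 0.0
    hmm: HmmParams = field(default_factory=HmmParams)
    # wheel
    bout_gap_s: float = 15.0
    wheel_speed_percentile: float = 90.0
    wheel_min_activity_rot: float = 10.0
    # floor
    conf_min: float = 0.5
    max_jump_cm: float = 20.0
    max_gap_s: float = 2.0
    min_step_cm: float = 0.2
    speed_window_s: float = 1.0
    move_threshold_cm_s: float = 0.5
    floor_speed_percentile: float = 90.0
    circadian_bin_s: float = 3600.0
    floor_min_activity_cm: float = 10.0
    # body condition
    coat_min_samples: int = 100
    # nest
    nest_min_area_px: float = 100.0
    nest_max_gap_h: float = 2.0
    # aggregation
    missing_policy: str = "strict"  # "strict" (all 8) or "lenient"
    min_components: int = 4  # lenient mode: minimum present components

    def __post_init__(self) -> None:
        missing = [c for c in COMPONENTS if c not in self.thresholds]
        if missing:
            raise ValueError(f"thresholds missing for components {missing}")
        if self.missing_policy not in ("strict", "lenient"):
            raise ValueError("missing_policy must be 'strict' or 'lenient'")


# ---------------------------------------------------------------------------
# Results


@dataclass(frozen=True)
class ComponentResult:
    """One raw DFI measurement plus its parameterized frailty score.

    Either ``score`` is set (in [0, 1]) or ``missing_reason`` explains why
    the measurement could not be taken.
    """

    name: str
    raw_value: float | None
    units: str
    score: float | None
    missing_reason: str | None = None

    def __post_init__(self) -> None:
        if self.score is not None and not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1] for {self.name}")
        if (self.score is None) == (self.missing_reason is None):
            raise ValueError("exactly one of score / missing_reason must be set")

    @property
    def missing(self) -> bool:
        return self.score is None


@dataclass(frozen=True)
class DfiResult:
    """The eight component results and their mean for one mouse-period."""

    mouse_id: str
    period: MeasurementPeriod
    components: Mapping[str, ComponentResult]
    overall: float
    n_missing: int = 0

    def component_scores(self) -> dict[str, float | None]:
        return {name: cr.score for name, cr in self.components.items()}


@dataclass(frozen=True)
class RegressionResult:
    """Least-squares fit summary (Pearson R, two-sided p from the t
    statistic with n-2 df)."""

    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    n: int


@dataclass(frozen=True)
class PairedMeasurement:
    """A DFI measurement matched to the same mouse's nearest-in-time MFI."""

    mouse_id: str
    dfi_date: date
    mfi_date: date
    dfi: float
    mfi: float
    age_days: int | None = None
    sex: str | None = None

    def __post_init__(self) -> None:
        if abs((self.dfi_date - self.mfi_date).days) >= 8:
            raise ValueError("paired measurements must be fewer than 8 days apart")


# ---------------------------------------------------------------------------
# Time helpers


def to_posix(dt: datetime) -> float:
    """POSIX seconds for a datetime (naive datetimes are taken as UTC)."""
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=timezone.utc)
    return dt.timestamp()


def local_midnight_on_or_after(t: float, utc_offset_hours: float) -> float:
    """First local-midnight instant at or after POSIX time ``t``."""
    shift = utc_offset_hours * 3600.0
    local = t + shift
    return float(np.ceil(local / SECONDS_PER_DAY) * SECONDS_PER_DAY - shift)


def local_midnight_on_or_before(t: float, utc_offset_hours: float) -> float:
    """Last local-midnight instant at or before POSIX time ``t``."""
    shift = utc_offset_hours * 3600.0
    local = t + shift
    return float(np.floor(local / SECONDS_PER_DAY) * SECONDS_PER_DAY - shift)


def local_date_of(t: float, utc_offset_hours: float) -> date:
    """Local calendar date containing POSIX time ``t``."""
    local = datetime.fromtimestamp(t, tz=timezone.utc) + timedelta(
        hours=utc_offset_hours
    )
    return local.date()


def local_hours(times: np.ndarray, utc_offset_hours: float) -> np.ndarray:
    """Local hour-of-day in [0, 24) for an array of POSIX times."""
    return (np.asarray(times, float) + utc_offset_hours * 3600.0) % SECONDS_PER_DAY / 3600.0
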