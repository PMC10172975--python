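"""Synthetic home-cage data generator.

Emulates the statistical structure of the video-derived annotation
channels the DFI pipeline consumes — noisy wheel-marker classifications,
centroid tracks, per-minute body-weight estimates with confidence weights,
coat-roughness samples, and nest-centroid traces — with controllable
frailty effects and full ground truth, so every pipeline stage is testable
without video.

A mouse's behaviour is summarized by a :class:`MousePhenotype`; a latent
frailty value in [0, 1] linearly interpolates between a healthy and a
frail endpoint phenotype. Wheel running occurs in bouts (bout initiations
follow a piecewise-constant-rate Poisson process, dark vs light);
floor movement alternates rest and move bouts; weight follows a linear
trajectory with noise; coat roughness and nest movement are stationary.
All randomness flows from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from pathlib import Path
import numpy as np
import pandas as pd

from .types import (
    AnnotationChannel,
    CageCalibration,
    LightCycle,
    MeasurementPeriod,
    MfiRecord,
    N_MFI_ITEMS,
    OccupancyRecord,
    SECONDS_PER_DAY,
    local_hours,
    to_posix,
)

# ---------------------------------------------------------------------------
# Phenotypes and noise


@dataclass(frozen=True)
class MousePhenotype:
    """Ground-truth behavioural parameters of one simulated mouse.

    Wheel running: long-run mean rotation rates per circadian phase plus
    the in-bout rotation speed (which sets wheel gait speed). Floor
    movement: locomotion speed and move-bout initiation rates per phase.
    """

    wheel_rate_dark: float = 300.0    # rotations/hour, dark phase
    wheel_rate_light: float = 30.0    # rotations/hour, light phase
    wheel_speed_m_s: float = 0.08     # in-bout rotation speed (slowed
    # relative to real mice so marker phases span several frames at 4 Hz)
    floor_speed_cm_s: float = 8.0
    activity_bout_rate_dark: float = 32.0   # floor move-bouts/hour
    activity_bout_rate_light: float = 6.0
    weight0_g: float = 35.0
    weight_slope_g_day: float = 0.0
    coat_roughness_mean: float = 10.0
    nest_speed_cm_h: float = 5.0
    frailty_latent: float = 0.0
    sex: str = "F"
    age_days: float = 200.0

    def __post_init__(self) -> None:
        for name in ("wheel_rate_dark", "wheel_rate_light", "wheel_speed_m_s",
                     "floor_speed_cm_s", "activity_bout_rate_dark",
                     "activity_bout_rate_light", "nest_speed_cm_h"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.weight0_g <= 0:
            raise ValueError("weight0_g must be positive")


#: Endpoint phenotypes between which latent frailty interpolates.
HEALTHY = MousePhenotype()
FRAIL = MousePhenotype(
    wheel_rate_dark=30.0,
    wheel_rate_light=15.0,
    wheel_speed_m_s=0.04,
    floor_speed_cm_s=2.0,
    activity_bout_rate_dark=12.0,
    activity_bout_rate_light=6.0,
    weight0_g=30.0,
    weight_slope_g_day=-0.5,
    coat_roughness_mean=20.0,
    nest_speed_cm_h=0.5,
    frailty_latent=1.0,
)

_INTERP_FIELDS = (
    "wheel_rate_dark", "wheel_rate_light", "wheel_speed_m_s",
    "floor_speed_cm_s", "activity_bout_rate_dark", "activity_bout_rate_light",
    "weight0_g", "weight_slope_g_day", "coat_roughness_mean", "nest_speed_cm_h",
)


def phenotype_from_latent(
    latent: float, age_days: float = 200.0, sex: str = "F"
) -> MousePhenotype:
    """Phenotype interpolated between the healthy (latent 0) and frail
    (latent 1) endpoints."""
    f = float(np.clip(latent, 0.0, 1.0))
    vals = {
        name: (1 - f) * getattr(HEALTHY, name) + f * getattr(FRAIL, name)
        for name in _INTERP_FIELDS
    }
    return MousePhenotype(frailty_latent=f, age_days=age_days, sex=sex, **vals)


@dataclass(frozen=True)
class NoiseModel:
    """Observation-noise parameters applied on top of a phenotype."""

    emission_flip_prob: float = 0.1   # wheel-marker classifier flip noise
    emission_conf: float = 0.9        # p_top emitted for the observed state
    track_jitter_px: float = 0.9
    conf_lo: float = 0.6              # tracker confidence range
    conf_hi: float = 1.0
    dropout_rate_per_h: float = 10.0  # low-confidence tracker bursts
    dropout_max_s: float = 1.5
    weight_sd_g: float = 1.5          # per-frame weight-estimate noise
    weight_conf_zero_frac: float = 0.05
    coat_sd: float = 2.0
    nest_jitter_cm: float = 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.emission_flip_prob < 0.5:
            raise ValueError("emission_flip_prob must be in [0, 0.5)")
        if self.track_jitter_px < 0 or self.weight_sd_g < 0:
            raise ValueError("noise scales must be non-negative")


@dataclass(frozen=True)
class Cadence:
    """Sampling rates of the simulated channels. The wheel channel is the
    densest (marker-phase resolution); tracking needs less."""

    wheel_frame_hz: float = 4.0
    track_frame_hz: float = 2.0
    weight_period_s: float = 60.0
    coat_period_s: float = 600.0
    nest_period_s: float = 600.0


CAGE_W_CM = 40.0
CAGE_H_CM = 20.0
ROTATIONS_PER_BOUT = 20.0
MOVE_BOUT_MEAN_S = 10.0
MAX_MARKER_DWELL_S = 2.5


# ---------------------------------------------------------------------------
# Low-level generators


def _piecewise_poisson(
    rng: np.random.Generator,
    t0: float,
    t1: float,
    rate_dark_per_s: float,
    rate_light_per_s: float,
    cycle: LightCycle,
    utc_offset_hours: float,
) -> np.ndarray:
    """Event times of a Poisson process whose rate switches between the
    dark and light phases (thinning)."""
    rmax = max(rate_dark_per_s, rate_light_per_s)
    if rmax <= 0:
        return np.empty(0)
    n = rng.poisson(rmax * (t1 - t0))
    t = np.sort(rng.uniform(t0, t1, n))
    dark = cycle.is_dark(local_hours(t, utc_offset_hours))
    rate = np.where(dark, rate_dark_per_s, rate_light_per_s)
    return t[rng.random(n) < rate / rmax]


def simulate_wheel_events(
    phen: MousePhenotype,
    t0: float,
    t1: float,
    cycle: LightCycle,
    rng: np.random.Generator,
    utc_offset_hours: float = 0.0,
    interval_jitter_sigma: float = 0.15,
) -> np.ndarray:
    """Ground-truth rotation-event times over [t0, t1).

    Running bouts initiate as a piecewise Poisson process whose per-phase
    rates reproduce the phenotype's mean rotation rates; each bout holds a
    geometric number of rotations at the phenotype's in-bout speed with
    log-normal interval jitter.
    """
    if t1 <= t0:
        raise ValueError("zero-length simulation window")
    if phen.wheel_speed_m_s <= 0:
        return np.empty(0)
    per_bout = ROTATIONS_PER_BOUT
    bout_starts = _piecewise_poisson(
        rng, t0, t1,
        phen.wheel_rate_dark / 3600.0 / per_bout,
        phen.wheel_rate_light / 3600.0 / per_bout,
        cycle, utc_offset_hours,
    )
    if bout_starts.size == 0:
        return np.empty(0)
    base_interval = 0.4 / phen.wheel_speed_m_s  # circumference fixed at 0.4 m
    n_rot = rng.geometric(1.0 / per_bout, bout_starts.size)
    total = int(n_rot.sum())
    jitter = np.exp(rng.normal(0.0, interval_jitter_sigma, total))
    intervals = base_interval * jitter
    # grouped cumulative sum: event k of bout b at start_b + cumsum of its
    # own intervals
    cum = np.cumsum(intervals)
    bout_idx = np.repeat(np.arange(bout_starts.size), n_rot)
    first = np.concatenate(([0], np.cumsum(n_rot)[:-1]))
    cum0 = np.concatenate(([0.0], cum))[first]
    events = np.repeat(bout_starts, n_rot) + (cum - cum0[bout_idx])
    # rotations within a second of the window edges are unobservable
    # (no frames sample their marker phases); exclude them from truth
    events = np.sort(events[(events >= t0 + 1.0) & (events < t1 - 1.0)])
    if events.size > 1:
        # overlapping bouts can interleave events too tightly for the
        # marker phases to be sampled; merge anything closer than 0.8 s
        keep = np.concatenate(([True], np.diff(events) >= 0.8))
        events = events[keep]
    return events


def wheel_marker_emissions(
    events: np.ndarray,
    t0: float,
    t1: float,
    frame_hz: float,
    flip_prob: float,
    rng: np.random.Generator,
    conf: float = 0.9,
    max_dwell_s: float = MAX_MARKER_DWELL_S,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-frame classifier output for a rotation-event stream.

    The marker enters "top" at each event time and stays for
    min(half the gap to the next event, ``max_dwell_s``); frames sample
    that state, then flip noise corrupts it. Returns (frame_times, p_top,
    true_states).
    """
    n = int(np.floor((t1 - t0) * frame_hz))
    frames = t0 + np.arange(n) / frame_hz
    events = np.asarray(events, float)
    if events.size:
        gaps = np.diff(events)
        dwell = np.minimum(
            0.5 * np.concatenate([gaps, [2 * max_dwell_s]]), max_dwell_s
        )
        idx = np.searchsorted(events, frames, side="right") - 1
        valid = idx >= 0
        top = np.zeros(n, dtype=bool)
        top[valid] = (frames[valid] - events[idx[valid]]) < dwell[idx[valid]]
    else:
        top = np.zeros(n, dtype=bool)
    if flip_prob > 0:
        obs = top ^ (rng.random(n) < flip_prob)
    else:
        obs = top
    p_top = np.where(obs, conf, 1.0 - conf)
    return frames, p_top, top


def _reflect(x: np.ndarray, width: float) -> np.ndarray:
    """Fold unbounded coordinates into [0, width] by reflection."""
    f = np.mod(x, 2 * width)
    return np.where(f > width, 2 * width - f, f)


def simulate_track(
    phen: MousePhenotype,
    noise: NoiseModel,
    t0: float,
    t1: float,
    cycle: LightCycle,
    calib: CageCalibration,
    rng: np.random.Generator,
    frame_hz: float = 2.0,
    utc_offset_hours: float = 0.0,
) -> pd.DataFrame:
    """Centroid track: alternating rest/move bouts with heading random
    walk, reflected inside the cage floor, plus pixel jitter and a tracker
    confidence stream with occasional low-confidence bursts."""
    n = int(np.floor((t1 - t0) * frame_hz))
    frames = t0 + np.arange(n) / frame_hz
    starts = _piecewise_poisson(
        rng, t0, t1,
        phen.activity_bout_rate_dark / 3600.0,
        phen.activity_bout_rate_light / 3600.0,
        cycle, utc_offset_hours,
    )
    durations = rng.exponential(MOVE_BOUT_MEAN_S, starts.size)
    ends = starts + durations
    # merge overlapping bouts into a flat boundary list
    moving = np.zeros(n, dtype=bool)
    if starts.size:
        order = np.argsort(starts)
        s, e = starts[order], ends[order]
        merged_s, merged_e = [s[0]], [e[0]]
        for i in range(1, s.size):
            if s[i] <= merged_e[-1]:
                merged_e[-1] = max(merged_e[-1], e[i])
            else:
                merged_s.append(s[i])
                merged_e.append(e[i])
        bounds = np.empty(2 * len(merged_s))
        bounds[0::2] = merged_s
        bounds[1::2] = merged_e
        moving = np.searchsorted(bounds, frames, side="right") % 2 == 1
    n_mov = int(moving.sum())
    dx = np.zeros(n)
    dy = np.zeros(n)
    if n_mov:
        theta = rng.uniform(0, 2 * np.pi) + np.cumsum(
            rng.normal(0.0, 0.4, n_mov)
        )
        step = phen.floor_speed_cm_s / frame_hz
        dx[moving] = step * np.cos(theta)
        dy[moving] = step * np.sin(theta)
    x = _reflect(CAGE_W_CM / 2 + np.cumsum(dx), CAGE_W_CM)
    y = _reflect(CAGE_H_CM / 2 + np.cumsum(dy), CAGE_H_CM)
    jitter = noise.track_jitter_px
    x_px = x * calib.px_per_cm + rng.normal(0.0, jitter, n)
    y_px = y * calib.px_per_cm + rng.normal(0.0, jitter, n)
    conf = rng.uniform(noise.conf_lo, noise.conf_hi, n)
    n_drop = rng.poisson(noise.dropout_rate_per_h * (t1 - t0) / 3600.0)
    if n_drop:
        b0 = rng.integers(0, n, n_drop)
        blen = rng.integers(1, max(2, int(noise.dropout_max_s * frame_hz) + 1),
                            n_drop)
        for b, l in zip(b0, blen):
            conf[b:b + l] = 0.2
    return pd.DataFrame(
        {"time": frames, "x_px": x_px, "y_px": y_px, "confidence": conf}
    )


def simulate_weight(
    phen: MousePhenotype,
    noise: NoiseModel,
    t0: float,
    t1: float,
    rng: np.random.Generator,
    period_s: float = 60.0,
) -> pd.DataFrame:
    """Once-per-minute weight estimates: linear trajectory plus Gaussian
    estimate noise, with confidence weights (a fraction exactly zero,
    emulating frames rejected by error detection)."""
    n = int(np.floor((t1 - t0) / period_s))
    t = t0 + np.arange(n) * period_s
    days = (t - t0) / SECONDS_PER_DAY
    grams = phen.weight0_g + phen.weight_slope_g_day * days + rng.normal(
        0.0, noise.weight_sd_g, n
    )
    grams = np.maximum(grams, 1.0)
    w = rng.uniform(0.2, 1.0, n)
    w[rng.random(n) < noise.weight_conf_zero_frac] = 0.0
    return pd.DataFrame({"time": t, "grams": grams, "weight_w": w})


def simulate_coat(
    phen: MousePhenotype,
    noise: NoiseModel,
    t0: float,
    t1: float,
    rng: np.random.Generator,
    period_s: float = 600.0,
) -> pd.DataFrame:
    n = int(np.floor((t1 - t0) / period_s))
    t = t0 + np.arange(n) * period_s
    r = np.maximum(
        rng.normal(phen.coat_roughness_mean, noise.coat_sd, n), 0.0
    )
    return pd.DataFrame({"time": t, "roughness": r})


def simulate_nest(
    phen: MousePhenotype,
    noise: NoiseModel,
    t0: float,
    t1: float,
    calib: CageCalibration,
    rng: np.random.Generator,
    period_s: float = 600.0,
) -> pd.DataFrame:
    """Nest-centroid random walk at the phenotype's displacement rate,
    reflected inside the cage, with area fluctuation and occasional
    segmentation dropouts (tiny area)."""
    n = int(np.floor((t1 - t0) / period_s))
    t = t0 + np.arange(n) * period_s
    step_cm = phen.nest_speed_cm_h * (period_s / 3600.0)
    theta = rng.uniform(0, 2 * np.pi, n)
    dx = step_cm * np.cos(theta)
    dy = step_cm * np.sin(theta)
    dx[0] = dy[0] = 0.0
    x = _reflect(CAGE_W_CM / 2 + np.cumsum(dx), CAGE_W_CM)
    y = _reflect(CAGE_H_CM / 2 + np.cumsum(dy), CAGE_H_CM)
    x_px = x * calib.px_per_cm + rng.normal(0, noise.nest_jitter_cm * calib.px_per_cm, n)
    y_px = y * calib.px_per_cm + rng.normal(0, noise.nest_jitter_cm * calib.px_per_cm, n)
    area = np.maximum(rng.normal(5000.0, 300.0, n), 10.0)
    area[rng.random(n) < 0.03] = 50.0  # below the min-area filter
    return pd.DataFrame(
        {"time": t, "centroid_x_px": x_px, "centroid_y_px": y_px, "area_px": area}
    )


# ---------------------------------------------------------------------------
# Whole-mouse simulation


def simulate_mouse(
    phen: MousePhenotype,
    noise: NoiseModel,
    period: MeasurementPeriod,
    cycle: LightCycle,
    calib: CageCalibration,
    seed: int | np.random.Generator,
    cadence: Cadence = Cadence(),
    utc_offset_hours: float = 0.0,
) -> tuple[dict[str, AnnotationChannel], dict]:
    """Generate the full channel set for one mouse-period plus its
    ground-truth record (generating parameters and true event counts)."""
    if period.end <= period.start:
        raise ValueError("zero-length period")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    t0, t1 = period.start, period.end

    events = simulate_wheel_events(phen, t0, t1, cycle, rng, utc_offset_hours)
    frames, p_top, _ = wheel_marker_emissions(
        events, t0, t1, cadence.wheel_frame_hz, noise.emission_flip_prob, rng,
        conf=noise.emission_conf,
    )
    channels = {
        "wheel_emission": AnnotationChannel(
            "wheel_emission", pd.DataFrame({"time": frames, "p_top": p_top})
        ),
        "track": AnnotationChannel(
            "track",
            simulate_track(phen, noise, t0, t1, cycle, calib, rng,
                           cadence.track_frame_hz, utc_offset_hours),
        ),
        "weight": AnnotationChannel(
            "weight",
            simulate_weight(phen, noise, t0, t1, rng, cadence.weight_period_s),
        ),
        "coat": AnnotationChannel(
            "coat", simulate_coat(phen, noise, t0, t1, rng, cadence.coat_period_s)
        ),
        "nest": AnnotationChannel(
            "nest",
            simulate_nest(phen, noise, t0, t1, calib, rng, cadence.nest_period_s),
        ),
    }
    truth = {
        "mouse_id": period.mouse_id,
        "n_rotations_true": int(events.size),
        "frailty_latent": phen.frailty_latent,
        "age_days": phen.age_days,
        "sex": phen.sex,
        **{name: getattr(phen, name) for name in _INTERP_FIELDS},
    }
    return channels, truth


# ---------------------------------------------------------------------------
# Cohorts


@dataclass(frozen=True)
class EffectModel:
    """Maps age (plus a non-age latent component) to latent frailty.

    latent = clip(base + span * age_effect * age_norm + N(0, latent_sd)),
    with age_norm the position of the mouse's age inside the cohort age
    range. ``age_effect`` 0 gives a null cohort; ``latent_sd`` injects the
    shared non-age frailty component that both MFI and DFI observe.
    """

    age_effect: float = 1.0
    latent_sd: float = 0.15
    base: float = 0.1
    span: float = 0.8


@dataclass(frozen=True)
class SimulatedMouse:
    mouse_id: str
    phenotype: MousePhenotype
    dob: date
    period: MeasurementPeriod
    mfi: MfiRecord
    occupancy: OccupancyRecord
    seed: int


@dataclass
class CohortSim:
    """A simulated cohort: per-mouse phenotypes, periods, MFI records and
    reproducible channel seeds. Channels are generated on demand (they are
    large) via :meth:`channels_for`."""

    mice: list[SimulatedMouse]
    cycle: LightCycle
    calib: CageCalibration
    noise: NoiseModel
    cadence: Cadence
    utc_offset_hours: float = 0.0

    def channels_for(self, mouse: SimulatedMouse) -> dict[str, AnnotationChannel]:
        channels, _ = simulate_mouse(
            mouse.phenotype, self.noise, mouse.period, self.cycle, self.calib,
            mouse.seed, self.cadence, self.utc_offset_hours,
        )
        return channels

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mouse_id": [m.mouse_id for m in self.mice],
                "age_days": [m.phenotype.age_days for m in self.mice],
                "sex": [m.phenotype.sex for m in self.mice],
                "frailty_latent": [m.phenotype.frailty_latent for m in self.mice],
                "dob": [m.dob for m in self.mice],
            }
        )

    def mfi_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mouse_id": [m.mouse_id for m in self.mice],
                "date": [m.mfi.assay_date for m in self.mice],
                "mfi": [m.mfi.overall for m in self.mice],
            }
        )

    def dob_map(self) -> dict[str, date]:
        return {m.mouse_id: m.dob for m in self.mice}


def simulate_mfi_items(
    latent: float, rng: np.random.Generator
) -> tuple[float, ...]:
    """29 MFI items from latent frailty: each item non-zero with
    probability increasing in the latent; non-zero items are 0.5 (mild,
    more likely) or 1 (severe)."""
    p_nonzero = float(np.clip(0.02 + 0.55 * latent, 0.0, 1.0))
    nonzero = rng.random(N_MFI_ITEMS) < p_nonzero
    severe = rng.random(N_MFI_ITEMS) < 0.3
    items = np.where(nonzero, np.where(severe, 1.0, 0.5), 0.0)
    return tuple(float(v) for v in items)


_EPOCH_DATE = date(2022, 3, 1)
_EPOCH = 1646092800.0  # 2022-03-01T00:00:00Z


def generate_cohort(
    n_mice: int,
    age_range: tuple[float, float] = (150.0, 900.0),
    effect: EffectModel = EffectModel(),
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    n_full_days: int = 2,
    cycle: LightCycle = LightCycle(),
    calib: CageCalibration = CageCalibration(),
    cadence: Cadence = Cadence(),
) -> CohortSim:
    """Simulate a cross-sectional aging cohort.

    Each mouse gets an age uniform over ``age_range``, a latent frailty
    from the effect model, one MFI assessment shortly before video, and
    one measurement period of ``n_full_days`` full days. All randomness
    derives from ``seed``.
    """
    if n_mice < 2:
        raise ValueError("need at least 2 mice")
    root = np.random.SeedSequence(seed)
    master = np.random.default_rng(root.spawn(1)[0])
    child_seeds = root.generate_state(n_mice + 1)[1:] % (2**31)
    lo, hi = age_range
    mice = []
    for i in range(n_mice):
        age = float(master.uniform(lo, hi))
        age_norm = (age - lo) / (hi - lo) if hi > lo else 0.0
        latent = float(np.clip(
            effect.base + effect.span * effect.age_effect * age_norm
            + master.normal(0.0, effect.latent_sd),
            0.0, 1.0,
        ))
        sex = "F" if master.random() < 0.5 else "M"
        phen = phenotype_from_latent(latent, age_days=age, sex=sex)
        mouse_id = f"m{i:03d}"
        start = _EPOCH
        period = MeasurementPeriod(
            mouse_id=mouse_id,
            first_full_day=_EPOCH_DATE,
            n_full_days=n_full_days,
            start=start,
            end=start + n_full_days * SECONDS_PER_DAY,
        )
        dob = _EPOCH_DATE - timedelta(days=int(round(age)))
        mfi_date = _EPOCH_DATE - timedelta(days=int(master.integers(0, 7)))
        mfi = MfiRecord(mouse_id, mfi_date, simulate_mfi_items(latent, master))
        occ = OccupancyRecord(
            device_id=f"cam{i:03d}",
            cage_position=f"pos{i:03d}",
            mouse_id=mouse_id,
            start=start - 0.3 * SECONDS_PER_DAY,
            end=start + (n_full_days + 0.25) * SECONDS_PER_DAY,
        )
        mice.append(
            SimulatedMouse(mouse_id, phen, dob, period, mfi, occ,
                           int(child_seeds[i]))
        )
    return CohortSim(mice, cycle, calib, noise, cadence)


def score_cohort(cohort: CohortSim, config) -> pd.DataFrame:
    """Run the full scoring pipeline over a simulated cohort.

    Channels are generated and scored one mouse at a time (they are large)
    and discarded. Returns one row per mouse-period: mouse_id, date, dfi,
    age_days, latent truth, and per-component raw values and scores.
    """
    from .io import compute_age
    from .scoring import results_to_frame, score_period

    results = []
    ages = []
    latents = []
    for mouse in cohort.mice:
        channels = cohort.channels_for(mouse)
        results.append(score_period(channels, mouse.period, config, cohort.calib))
        ages.append(compute_age(mouse.dob, mouse.period.first_full_day))
        latents.append(mouse.phenotype.frailty_latent)
    frame = results_to_frame(results)
    frame["age_days"] = ages
    frame["frailty_latent"] = latents
    return frame


def write_cohort(cohort: CohortSim, outdir: str | Path) -> None:
    """Write a cohort to disk as plain CSV tables: per-mouse channel
    files, occupancy, MFI, DOB and ground-truth tables."""
    from .io import write_channel_table, write_mfi_table, write_occupancy_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for mouse in cohort.mice:
        for kind, channel in cohort.channels_for(mouse).items():
            write_channel_table(channel, outdir / f"{mouse.mouse_id}_{kind}.csv")
    write_occupancy_table([m.occupancy for m in cohort.mice],
                          outdir / "occupancy.csv")
    write_mfi_table([m.mfi for m in cohort.mice], outdir / "mfi.csv")
    truth = cohort.truth_frame()
    truth.to_csv(outdir / "truth.csv", index=False)
    truth[["mouse_id", "dob"]].to_csv(outdir / "dob.csv", index=False)
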