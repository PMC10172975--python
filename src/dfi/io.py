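"""Table I/O, configuration files, measurement-period derivation, and age
computation.

File dialect: UTF-8 comma-delimited text with a header row; timestamps are
ISO-8601 UTC (microsecond precision); one channel kind per file.
"""

from __future__ import annotations

import dataclasses
import logging
from datetime import date
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .types import (
    SECONDS_PER_DAY,
    AnnotationChannel,
    CHANNEL_COLUMNS,
    COMPONENTS,
    ComponentThresholds,
    DfiConfig,
    HmmParams,
    LightCycle,
    CageCalibration,
    MeasurementPeriod,
    MfiRecord,
    N_MFI_ITEMS,
    OccupancyRecord,
    local_date_of,
    local_midnight_on_or_after,
    local_midnight_on_or_before,
)

logger = logging.getLogger("dfi")

_ISO_FMT = "%Y-%m-%dT%H:%M:%S.%f%z"


def _times_to_iso(t: np.ndarray) -> pd.Series:
    dt = pd.to_datetime(np.round(np.asarray(t, float) * 1e6).astype("int64"),
                        unit="us", utc=True)
    return pd.Series(dt).dt.strftime(_ISO_FMT)


def _iso_to_times(s: pd.Series) -> np.ndarray:
    dt = pd.to_datetime(s, utc=True, format="ISO8601")
    return dt.astype("int64").to_numpy() / 1e9


# ---------------------------------------------------------------------------
# Channel tables


def write_channel_table(channel: AnnotationChannel, path: str | Path) -> None:
    """Write one channel to CSV with ISO-8601 timestamps."""
    df = channel.samples.copy()
    df["time"] = _times_to_iso(df["time"].to_numpy(float))
    df.to_csv(path, index=False)


def read_channel_table(path: str | Path, kind: str) -> AnnotationChannel:
    """Read a channel CSV; validates ranges and timestamp monotonicity,
    raising ValueError naming the offending row."""
    if kind not in CHANNEL_COLUMNS:
        raise ValueError(f"unknown channel kind {kind!r}")
    df = pd.read_csv(path)
    required = ("time",) + CHANNEL_COLUMNS[kind]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing} for kind {kind!r}")
    if len(df):
        df["time"] = _iso_to_times(df["time"])
    else:
        df = pd.DataFrame({c: pd.Series(dtype=float) for c in required})
    return AnnotationChannel(kind=kind, samples=df)


# ---------------------------------------------------------------------------
# Occupancy tables

_OCC_DEFAULT_COLS = {
    "device_id": "device_id",
    "cage_position": "cage_position",
    "mouse_id": "mouse_id",
    "start": "start",
    "end": "end",
}


def write_occupancy_table(records: Sequence[OccupancyRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "device_id": [r.device_id for r in records],
            "cage_position": [r.cage_position for r in records],
            "mouse_id": [r.mouse_id for r in records],
            "start": _times_to_iso(np.array([r.start for r in records], float))
            if records else pd.Series(dtype=str),
            "end": _times_to_iso(np.array([r.end for r in records], float))
            if records else pd.Series(dtype=str),
        }
    )
    df.to_csv(path, index=False)


def read_occupancy_table(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> list[OccupancyRecord]:
    """Read occupancy intervals.

    ``column_map`` maps the canonical names (device_id, cage_position,
    mouse_id, start, end) to the file's column names, accommodating
    externally produced interval tables.
    """
    cols = dict(_OCC_DEFAULT_COLS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path)
    missing = [v for v in cols.values() if v not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    starts = _iso_to_times(df[cols["start"]]) if len(df) else np.array([])
    ends = _iso_to_times(df[cols["end"]]) if len(df) else np.array([])
    return [
        OccupancyRecord(
            device_id=str(df[cols["device_id"]].iat[i]),
            cage_position=str(df[cols["cage_position"]].iat[i]),
            mouse_id=str(df[cols["mouse_id"]].iat[i]),
            start=float(starts[i]),
            end=float(ends[i]),
        )
        for i in range(len(df))
    ]


# ---------------------------------------------------------------------------
# MFI tables


def write_mfi_table(records: Sequence[MfiRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        row: dict[str, object] = {"mouse_id": r.mouse_id,
                                  "date": r.assay_date.isoformat()}
        for i, v in enumerate(r.item_scores, start=1):
            row[f"item_{i:02d}"] = v
        rows.append(row)
    cols = ["mouse_id", "date"] + [f"item_{i:02d}" for i in range(1, N_MFI_ITEMS + 1)]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_mfi_table(path: str | Path) -> list[MfiRecord]:
    """Read an MFI table: mouse_id, date, then exactly 29 item columns with
    values in {0, 0.5, 1}."""
    df = pd.read_csv(path)
    for c in ("mouse_id", "date"):
        if c not in df.columns:
            raise ValueError(f"{path}: missing column {c!r}")
    item_cols = [c for c in df.columns if c not in ("mouse_id", "date")]
    if len(item_cols) != N_MFI_ITEMS:
        raise ValueError(
            f"{path}: expected {N_MFI_ITEMS} item columns, found {len(item_cols)}"
        )
    records = []
    for i, row in df.iterrows():
        records.append(
            MfiRecord(
                mouse_id=str(row["mouse_id"]),
                assay_date=date.fromisoformat(str(row["date"])),
                item_scores=tuple(float(row[c]) for c in item_cols),
            )
        )
    return records


def mfi_to_frame(records: Sequence[MfiRecord]) -> pd.DataFrame:
    """Summary frame with one row per assessment (mouse_id, date, mfi)."""
    return pd.DataFrame(
        {
            "mouse_id": [r.mouse_id for r in records],
            "date": [r.assay_date for r in records],
            "mfi": [r.overall for r in records],
        }
    )


# ---------------------------------------------------------------------------
# Measurement-period derivation


def _merge_intervals(
    intervals: Sequence[tuple[float, float]], bridge_gap_s: float
) -> list[tuple[float, float]]:
    """Union of intervals, bridging gaps smaller than ``bridge_gap_s``."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s - out[-1][1] < bridge_gap_s:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _intersect(
    a: Sequence[tuple[float, float]], b: Sequence[tuple[float, float]]
) -> list[tuple[float, float]]:
    out = []
    for s1, e1 in a:
        for s2, e2 in b:
            s, e = max(s1, s2), min(e1, e2)
            if s < e:
                out.append((s, e))
    return sorted(out)


def derive_periods(
    occupancy: Sequence[OccupancyRecord],
    coverage: Mapping[str, Sequence[tuple[float, float]]] | None = None,
    mode: str = "jdo",
    max_days: int = 6,
    utc_offset_hours: float = 0.0,
    bridge_gap_s: float = 60.0,
    max_periods: int = 3,
) -> list[MeasurementPeriod]:
    """Derive DFI measurement periods from cage-occupancy episodes.

    An episode is an occupancy interval intersected with the cage's recorded
    coverage (if given); sub-minute coverage dropouts are bridged. Incomplete
    local days at the start and end of an episode are excluded.

    mode="jdo": each episode yields at most one period of
    min(full_days, max_days) days, dropped if fewer than 2 full days are
    covered; the measurement date is the first full day.

    mode="consecutive": up to ``max_periods`` back-to-back 6-day (144 h)
    periods starting at the first full day.

    Raises ValueError if occupancy intervals for one cage position overlap.
    """
    if mode not in ("jdo", "consecutive"):
        raise ValueError("mode must be 'jdo' or 'consecutive'")
    by_cage: dict[str, list[OccupancyRecord]] = {}
    for rec in occupancy:
        by_cage.setdefault(rec.cage_position, []).append(rec)
    for cage, recs in by_cage.items():
        recs.sort(key=lambda r: r.start)
        for a, b in zip(recs, recs[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping occupancy for cage position {cage!r}: "
                    f"{a.mouse_id!r} and {b.mouse_id!r}"
                )

    periods: list[MeasurementPeriod] = []
    n_dropped = 0
    for rec in occupancy:
        episode = [(rec.start, rec.end)]
        if coverage is not None:
            cov = _merge_intervals(list(coverage.get(rec.cage_position, [])),
                                   bridge_gap_s)
            episode = _intersect(episode, cov)
            episode = _merge_intervals(episode, bridge_gap_s)
        for ep_start, ep_end in episode:
            day0 = local_midnight_on_or_after(ep_start, utc_offset_hours)
            day_end = local_midnight_on_or_before(ep_end, utc_offset_hours)
            n_full = int(round((day_end - day0) / SECONDS_PER_DAY))
            if mode == "jdo":
                n = min(n_full, max_days)
                if n < 2:
                    n_dropped += 1
                    continue
                periods.append(
                    MeasurementPeriod(
                        mouse_id=rec.mouse_id,
                        first_full_day=local_date_of(day0 + 1, utc_offset_hours),
                        n_full_days=n,
                        start=day0,
                        end=day0 + n * SECONDS_PER_DAY,
                    )
                )
            else:
                k = min(n_full // 6, max_periods)
                if k < 1:
                    n_dropped += 1
                for j in range(k):
                    start = day0 + j * 6 * SECONDS_PER_DAY
                    periods.append(
                        MeasurementPeriod(
                            mouse_id=rec.mouse_id,
                            first_full_day=local_date_of(start + 1, utc_offset_hours),
                            n_full_days=6,
                            start=start,
                            end=start + 6 * SECONDS_PER_DAY,
                        )
                    )
    if n_dropped:
        logger.info("derive_periods: %d occupancy episode(s) too short, dropped",
                    n_dropped)
    return periods


def compute_age(cohort_dob: date, event_date: date) -> int:
    """Age in whole days between a cohort's date of birth and an assay date."""
    if event_date < cohort_dob:
        raise ValueError("event date precedes date of birth")
    return (event_date - cohort_dob).days


# ---------------------------------------------------------------------------
# Config files (YAML)


def config_to_dict(config: DfiConfig, calib: CageCalibration | None = None) -> dict:
    d: dict = {
        "thresholds": {
            name: {"v_healthy": th.v_healthy, "v_frail": th.v_frail}
            for name, th in config.thresholds.items()
        },
        "light_cycle": {
            "dark_onset_hour": config.light_cycle.dark_onset_hour,
            "dark_duration_h": config.light_cycle.dark_duration_h,
        },
        "hmm": {"p_stay": config.hmm.p_stay, "p_init_top": config.hmm.p_init_top},
    }
    for f in dataclasses.fields(DfiConfig):
        if f.name in ("thresholds", "light_cycle", "hmm"):
            continue
        d[f.name] = getattr(config, f.name)
    if calib is not None:
        d["calibration"] = {
            "px_per_cm": calib.px_per_cm,
            "wheel_circumference_m": calib.wheel_circumference_m,
        }
    return d


def config_from_dict(d: Mapping) -> tuple[DfiConfig, CageCalibration]:
    kwargs: dict = {}
    if "thresholds" in d:
        kwargs["thresholds"] = {
            name: ComponentThresholds(**vals) for name, vals in d["thresholds"].items()
        }
    if "light_cycle" in d:
        kwargs["light_cycle"] = LightCycle(**d["light_cycle"])
    if "hmm" in d:
        kwargs["hmm"] = HmmParams(**d["hmm"])
    simple = {f.name for f in dataclasses.fields(DfiConfig)} - {
        "thresholds", "light_cycle", "hmm"
    }
    for k in simple:
        if k in d:
            kwargs[k] = d[k]
    calib = CageCalibration(**d.get("calibration", {}))
    return DfiConfig(**kwargs), calib


def write_config(path: str | Path, config: DfiConfig,
                 calib: CageCalibration | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_to_dict(config, calib), fh, sort_keys=False)


def read_config(path: str | Path) -> tuple[DfiConfig, CageCalibration]:
    with open(path, encoding="utf-8") as fh:
        return config_from_dict(yaml.safe_load(fh) or {})
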