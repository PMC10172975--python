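"""Cohort-level benchmarking of DFI against MFI and chronological age:
nearest-date pairing, Pearson regressions, age-normalized residual
correlation, component correlation matrices, and WPGMA hierarchical
clustering of the correlation structure.
"""

from __future__ import annotations

import logging
from datetime import date
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .types import PairedMeasurement, RegressionResult

logger = logging.getLogger("dfi")

MAX_PAIR_GAP_DAYS = 8  # strict upper bound: pairs must be fewer than 8 days apart


def linregress(xs: np.ndarray, ys: np.ndarray) -> RegressionResult:
    """Ordinary least squares with Pearson R and the two-sided p value from
    the t statistic with n-2 degrees of freedom.

    Raises ValueError("degenerate") on zero variance in either variable.
    """
    xs = np.asarray(xs, float)
    ys = np.asarray(ys, float)
    if xs.size != ys.size or xs.size < 2:
        raise ValueError("need at least 2 paired observations")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValueError("degenerate: zero variance")
    res = stats.linregress(xs, ys)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        p_value=float(res.pvalue),
        n=int(xs.size),
    )


def pair_mfi_dfi(
    dfi_records: pd.DataFrame,
    mfi_records: pd.DataFrame,
    ages: Mapping[str, date] | None = None,
    sexes: Mapping[str, str] | None = None,
) -> list[PairedMeasurement]:
    """Match each DFI measurement to the same mouse's closest-in-date MFI.

    ``dfi_records`` needs columns (mouse_id, date, dfi); ``mfi_records``
    (mouse_id, date, mfi); dates are datetime.date (the DFI date is the
    first full day of video). A pair is kept only when the whole-day date
    difference is strictly less than 8; equidistant candidates resolve to
    the earlier MFI. One pair at most per DFI record; unpairable records
    are dropped (counted in the log). ``ages`` optionally maps mouse_id to
    date of birth for age annotation.
    """
    mfi_by_mouse: dict[str, list[tuple[date, float]]] = {}
    for _, row in mfi_records.iterrows():
        mfi_by_mouse.setdefault(str(row["mouse_id"]), []).append(
            (row["date"], float(row["mfi"]))
        )
    for lst in mfi_by_mouse.values():
        lst.sort()

    pairs: list[PairedMeasurement] = []
    n_dropped = 0
    for _, row in dfi_records.iterrows():
        mouse = str(row["mouse_id"])
        d_date = row["date"]
        candidates = mfi_by_mouse.get(mouse, [])
        if not candidates:
            n_dropped += 1
            continue
        # min |date delta|; ties -> earlier MFI (candidates are sorted)
        best = min(candidates, key=lambda m: (abs((d_date - m[0]).days), m[0]))
        delta = abs((d_date - best[0]).days)
        if delta >= MAX_PAIR_GAP_DAYS:
            n_dropped += 1
            continue
        age_days = None
        if ages is not None and mouse in ages:
            age_days = (d_date - ages[mouse]).days
        pairs.append(
            PairedMeasurement(
                mouse_id=mouse,
                dfi_date=d_date,
                mfi_date=best[0],
                dfi=float(row["dfi"]),
                mfi=best[1],
                age_days=age_days,
                sex=None if sexes is None else sexes.get(mouse),
            )
        )
    if n_dropped:
        logger.info("pair_mfi_dfi: %d DFI record(s) unpairable, dropped", n_dropped)
    return pairs


def pairs_to_frame(pairs: Sequence[PairedMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mouse_id": [p.mouse_id for p in pairs],
            "dfi_date": [p.dfi_date for p in pairs],
            "mfi_date": [p.mfi_date for p in pairs],
            "dfi": [p.dfi for p in pairs],
            "mfi": [p.mfi for p in pairs],
            "age_days": [p.age_days for p in pairs],
            "sex": [p.sex for p in pairs],
        }
    )


def age_residual_correlation(
    pairs: pd.DataFrame,
) -> tuple[RegressionResult, np.ndarray, np.ndarray]:
    """Correlation of age-normalized MFI and DFI.

    On the paired subset, MFI and DFI are each regressed against age; the
    MFI residuals are then regressed against the DFI residuals (DFI
    residuals on the x axis). Returns (residual regression, dfi_residuals,
    mfi_residuals). Raises ValueError when a regression or the residual
    correlation is degenerate.
    """
    required = {"age_days", "mfi", "dfi"}
    if not required.issubset(pairs.columns):
        raise ValueError(f"pairs frame needs columns {sorted(required)}")
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs")
    age = pairs["age_days"].to_numpy(float)
    mfi = pairs["mfi"].to_numpy(float)
    dfi = pairs["dfi"].to_numpy(float)
    mfi_fit = linregress(age, mfi)
    dfi_fit = linregress(age, dfi)
    mfi_res = mfi - (mfi_fit.intercept + mfi_fit.slope * age)
    dfi_res = dfi - (dfi_fit.intercept + dfi_fit.slope * age)
    return linregress(dfi_res, mfi_res), dfi_res, mfi_res


def component_correlation_matrix(
    table: pd.DataFrame,
    mfi_item_columns: Sequence[str] = (),
    mfi_item_filter_min_nonzero: int = 5,
) -> pd.DataFrame:
    """All-by-all Pearson correlation of trait columns.

    Missing values are handled by pairwise-complete deletion (minimum 3
    complete pairs, else NaN). MFI item columns observed non-zero at most
    ``mfi_item_filter_min_nonzero`` times are excluded (strict '>'
    inclusion rule); constant columns yield NaN correlations.
    """
    keep = []
    for col in table.columns:
        if col in mfi_item_columns:
            n_nonzero = int((table[col].fillna(0) != 0).sum())
            if n_nonzero <= mfi_item_filter_min_nonzero:
                continue
        keep.append(col)
    sub = table.loc[:, keep].astype(float)
    corr = sub.corr(method="pearson", min_periods=3)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def wpgma_cluster(
    corr: pd.DataFrame, transform: str = "one_minus_r"
) -> pd.DataFrame:
    """WPGMA (weighted average linkage) clustering of a correlation matrix.

    Correlations become distances via d = 1 - R (default) or d = 1 - |R|;
    under WPGMA the distance from a merged cluster to any other is the
    unweighted mean of its two children's distances. Returns the merge
    table: columns (left, right, height, size), ordered by merge step with
    non-decreasing heights; leaf indices 0..n-1 follow the input column
    order, internal nodes continue from n.

    Raises ValueError on a non-symmetric matrix or off-unit diagonal.
    """
    mat = np.asarray(corr, float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(mat, mat.T, atol=1e-10, equal_nan=True):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(mat), 1.0):
        raise ValueError("correlation matrix must have unit diagonal")
    if np.isnan(mat).any():
        raise ValueError("correlation matrix contains missing values; "
                         "drop sparse columns first")
    if transform == "one_minus_r":
        dist = 1.0 - mat
    elif transform == "one_minus_abs_r":
        dist = 1.0 - np.abs(mat)
    else:
        raise ValueError("transform must be 'one_minus_r' or 'one_minus_abs_r'")
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    z = hierarchy.linkage(condensed, method="weighted")
    return pd.DataFrame(
        {
            "left": z[:, 0].astype(int),
            "right": z[:, 1].astype(int),
            "height": z[:, 2],
            "size": z[:, 3].astype(int),
        }
    )


def merges_to_newick(merges: pd.DataFrame, labels: Sequence[str]) -> str:
    """Newick dendrogram string from a WPGMA merge table."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    nodes: dict[int, str] = {i: str(labels[i]) for i in range(n)}
    for step, row in merges.iterrows():
        node_id = n + step
        h = float(row["height"])
        li, ri = int(row["left"]), int(row["right"])
        bl_l = h - heights[li]
        bl_r = h - heights[ri]
        nodes[node_id] = f"({nodes[li]}:{bl_l:g},{nodes[ri]}:{bl_r:g})"
        heights[node_id] = h
    root = n + len(merges) - 1 if len(merges) else 0
    return nodes[root] + ";"
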