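"""Body-condition measurements: weighted-regression body-weight trend and
Sobel-gradient coat roughness.

Per-frame body-weight estimates arrive with confidence weights from the
upstream vision pipeline; the weight trend over a measurement period is the
slope of a weighted least-squares line with frame time (in days) as the
independent variable. Coat condition is the median of per-frame image
roughness, where roughness is the mean Sobel gradient magnitude over the
mouse's segmentation mask.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .types import AnnotationChannel, MeasurementPeriod, SECONDS_PER_DAY

# Standard 3x3 Sobel kernels (correlation convention; x rightward across
# columns, y downward across rows).
SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
SOBEL_Y = SOBEL_X.T


def weighted_linear_slope(
    xs: np.ndarray, ys: np.ndarray, ws: np.ndarray
) -> tuple[float, float]:
    """Closed-form weighted least squares line fit.

    Minimizes sum_i w_i (y_i - a - b x_i)^2 and returns (slope b,
    intercept a). Raises ValueError("degenerate regression") when fewer
    than two positively weighted points, or no x-spread among them.
    """
    xs = np.asarray(xs, float)
    ys = np.asarray(ys, float)
    ws = np.asarray(ws, float)
    if not (xs.shape == ys.shape == ws.shape):
        raise ValueError("xs, ys, ws must have equal length")
    if np.any(ws < 0):
        raise ValueError("weights must be non-negative")
    pos = ws > 0
    x, y, w = xs[pos], ys[pos], ws[pos]
    if x.size < 2 or np.unique(x).size < 2:
        raise ValueError("degenerate regression")
    W = w.sum()
    xb = (w * x).sum() / W
    yb = (w * y).sum() / W
    sxx = (w * (x - xb) ** 2).sum()
    if sxx == 0:
        raise ValueError("degenerate regression")
    slope = (w * (x - xb) * (y - yb)).sum() / sxx
    return float(slope), float(yb - slope * xb)


def weight_rate_of_change(
    channel: AnnotationChannel, period: MeasurementPeriod
) -> float | None:
    """Body-weight rate of change over the period, grams/day.

    Returns None (missing) when the weighted regression is degenerate
    (e.g. all confidence weights zero).
    """
    if channel.kind != "weight":
        raise ValueError(f"expected a weight channel, got {channel.kind!r}")
    df = channel.slice(period.start, period.end).samples
    x_days = (df["time"].to_numpy(float) - period.start) / SECONDS_PER_DAY
    try:
        slope, _ = weighted_linear_slope(
            x_days, df["grams"].to_numpy(float), df["weight_w"].to_numpy(float)
        )
    except ValueError:
        return None
    return slope


def sobel_roughness(image: np.ndarray, mask: np.ndarray) -> float:
    """Mean Sobel gradient magnitude sqrt(Gx^2 + Gy^2) over the masked
    interior of a grayscale image.

    The 1-pixel image border is excluded so that every contributing pixel
    has a full 3x3 neighborhood (no padding dialect). Raises ValueError on
    an empty effective mask.
    """
    image = np.asarray(image, float)
    mask = np.asarray(mask, bool)
    if image.ndim != 2 or image.shape != mask.shape:
        raise ValueError("image and mask must be 2-D arrays of equal shape")
    interior = np.zeros_like(mask)
    interior[1:-1, 1:-1] = mask[1:-1, 1:-1]
    if not interior.any():
        raise ValueError("mask has no interior pixels")
    gx = ndimage.correlate(image, SOBEL_X, mode="constant")
    gy = ndimage.correlate(image, SOBEL_Y, mode="constant")
    mag = np.hypot(gx, gy)
    return float(mag[interior].mean())


def coat_metric(
    channel: AnnotationChannel,
    period: MeasurementPeriod,
    min_samples: int = 100,
) -> float | None:
    """Coat-condition summary: median per-frame roughness within the
    period; None (missing) with fewer than ``min_samples`` samples."""
    if channel.kind != "coat":
        raise ValueError(f"expected a coat channel, got {channel.kind!r}")
    r = channel.slice(period.start, period.end).samples["roughness"].to_numpy(float)
    if r.size < min_samples:
        return None
    return float(np.median(r))
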