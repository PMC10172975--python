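"""Weighted regression, weight trend, Sobel roughness, coat summary."""

import numpy as np
import pandas as pd
import pytest

from dfi import body
from dfi.types import AnnotationChannel

from conftest import make_period


def normal_equations_oracle(xs, ys, ws):
    """Independent WLS solve via the weighted normal equations."""
    X = np.column_stack([np.ones_like(xs), xs])
    W = np.diag(ws)
    beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ ys)
    return beta[1], beta[0]  # slope, intercept


class TestWeightedLinearSlope:
    def test_exact_line_recovered(self):
        xs = np.array([0.0, 1, 2, 3, 4])
        ws = np.array([1.0, 2, 0.5, 1, 3])
        slope, intercept = body.weighted_linear_slope(xs, 3 + 2 * xs, ws)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(3.0)

    def test_constant_y_gives_zero_slope(self):
        xs = np.arange(10.0)
        slope, _ = body.weighted_linear_slope(xs, np.full(10, 7.0),
                                              np.ones(10))
        assert slope == pytest.approx(0.0)

    def test_matches_normal_equations_on_random_instances(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            n = int(rng.integers(3, 60))
            xs = rng.normal(0, 5, n)
            ys = rng.normal(0, 3, n)
            ws = rng.uniform(0.01, 4, n)
            slope, intercept = body.weighted_linear_slope(xs, ys, ws)
            s2, i2 = normal_equations_oracle(xs, ys, ws)
            assert slope == pytest.approx(s2, rel=1e-9)
            assert intercept == pytest.approx(i2, rel=1e-9)

    @pytest.mark.parametrize("xs,ws", [
        (np.array([1.0, 2, 3]), np.zeros(3)),          # all weights zero
        (np.array([2.0, 2, 2]), np.ones(3)),           # single distinct x
        (np.array([1.0, 2, 3]), np.array([0, 0, 1.0])),  # one weighted point
    ])
    def test_degenerate_inputs_rejected(self, xs, ws):
        with pytest.raises(ValueError, match="degenerate"):
            body.weighted_linear_slope(xs, xs, ws)

    def test_equivariances(self):
        rng = np.random.default_rng(3)
        xs = rng.normal(0, 2, 30)
        ys = rng.normal(0, 1, 30)
        ws = rng.uniform(0.5, 2, 30)
        slope, intercept = body.weighted_linear_slope(xs, ys, ws)
        # scaling x by c scales slope by 1/c
        s2, _ = body.weighted_linear_slope(3 * xs, ys, ws)
        assert s2 == pytest.approx(slope / 3)
        # adding a constant to y leaves slope unchanged
        s3, i3 = body.weighted_linear_slope(xs, ys + 11, ws)
        assert s3 == pytest.approx(slope)
        assert i3 == pytest.approx(intercept + 11)
        # duplicating every point leaves the fit unchanged
        s4, i4 = body.weighted_linear_slope(
            np.tile(xs, 2), np.tile(ys, 2), np.tile(ws, 2))
        assert s4 == pytest.approx(slope)
        assert i4 == pytest.approx(intercept)


def weight_channel(t, grams, w):
    return AnnotationChannel("weight", pd.DataFrame(
        {"time": t, "grams": grams, "weight_w": w}))


class TestWeightRate:
    def test_uniform_loss_unit_conversion(self):
        # losing 0.001 g per minute = 1.44 g/day
        period = make_period(2)
        t = period.start + 60.0 * np.arange(2880)
        grams = 35.0 - 0.001 * np.arange(2880)
        ch = weight_channel(t, grams, np.ones(2880))
        assert body.weight_rate_of_change(ch, period) == pytest.approx(-1.44)

    def test_constant_weight(self):
        period = make_period(2)
        t = period.start + 60.0 * np.arange(200)
        ch = weight_channel(t, np.full(200, 30.0), np.ones(200))
        assert body.weight_rate_of_change(ch, period) == pytest.approx(0.0)

    def test_noisy_heteroskedastic_matches_oracle_and_truth(self):
        period = make_period(2)
        rng = np.random.default_rng(17)
        t = period.start + 60.0 * np.arange(2880)
        days = (t - period.start) / 86400
        ws = rng.uniform(0.1, 1.0, 2880)
        grams = 32.0 - 0.5 * days + rng.normal(0, 1.0 / np.sqrt(ws))
        ch = weight_channel(t, np.maximum(grams, 1.0), ws)
        got = body.weight_rate_of_change(ch, period)
        s_oracle, _ = normal_equations_oracle(days, ch.samples["grams"].to_numpy(), ws)
        assert got == pytest.approx(s_oracle, rel=1e-9)
        assert got == pytest.approx(-0.5, abs=0.15)

    def test_slope_recovery_bias_under_5pct(self):
        # known -0.5 g/day truth with confidence-weighted noise: mean
        # recovered slope over 100 seeded replicates within 5% of truth
        period = make_period(2)
        t = period.start + 300.0 * np.arange(576)
        days = (t - period.start) / 86400
        slopes = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            ws = rng.uniform(0.1, 1.0, 576)
            grams = 32.0 - 0.5 * days + rng.normal(0, 0.8 / np.sqrt(ws))
            ch = weight_channel(t, np.maximum(grams, 1.0), ws)
            slopes.append(body.weight_rate_of_change(ch, period))
        bias = abs(np.mean(slopes) - (-0.5)) / 0.5
        assert bias < 0.05

    def test_all_zero_weights_missing(self):
        period = make_period(2)
        t = period.start + 60.0 * np.arange(100)
        ch = weight_channel(t, np.full(100, 30.0), np.zeros(100))
        assert body.weight_rate_of_change(ch, period) is None


def sobel_oracle(image, mask):
    """Hand per-pixel 3x3 convolution over the masked interior."""
    kx = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], float)
    ky = kx.T
    vals = []
    for i in range(1, image.shape[0] - 1):
        for j in range(1, image.shape[1] - 1):
            if not mask[i, j]:
                continue
            patch = image[i - 1:i + 2, j - 1:j + 2].astype(float)
            gx = (patch * kx).sum()
            gy = (patch * ky).sum()
            vals.append(np.hypot(gx, gy))
    return float(np.mean(vals))


class TestSobelRoughness:
    def test_constant_image_zero(self):
        img = np.full((10, 12), 80.0)
        mask = np.ones((10, 12), bool)
        assert body.sobel_roughness(img, mask) == 0.0

    def test_vertical_step_matches_hand_convolution(self):
        img = np.zeros((8, 8))
        img[:, 4:] = 255.0
        mask = np.zeros((8, 8), bool)
        mask[1:-1, 1:-1] = True
        assert body.sobel_roughness(img, mask) == pytest.approx(
            sobel_oracle(img, mask))

    def test_random_images_match_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            img = rng.integers(0, 256, (16, 16)).astype(float)
            mask = rng.random((16, 16)) < 0.6
            mask[1:-1, 1:-1] |= True  # guarantee interior pixels
            assert body.sobel_roughness(img, mask) == pytest.approx(
                sobel_oracle(img, mask), rel=1e-12)

    def test_border_only_mask_rejected(self):
        img = np.zeros((6, 6))
        mask = np.ones((6, 6), bool)
        mask[1:-1, 1:-1] = False
        with pytest.raises(ValueError):
            body.sobel_roughness(img, mask)

    def test_intensity_shift_invariance_and_contrast_scaling(self):
        rng = np.random.default_rng(13)
        img = rng.uniform(0, 200, (12, 12))
        mask = np.ones((12, 12), bool)
        base = body.sobel_roughness(img, mask)
        assert body.sobel_roughness(img + 30, mask) == pytest.approx(base)
        assert body.sobel_roughness(img * 2.5, mask) == pytest.approx(
            2.5 * base)


class TestCoatMetric:
    def coat(self, t, r):
        return AnnotationChannel("coat", pd.DataFrame(
            {"time": t, "roughness": r}))

    def test_identical_samples(self):
        period = make_period(2)
        t = period.start + 60.0 * np.arange(150)
        ch = self.coat(t, np.full(150, 12.5))
        assert body.coat_metric(ch, period, min_samples=100) == 12.5

    def test_median_is_middle_order_statistic(self):
        period = make_period(2)
        vals = np.array([5.0, 1.0, 9.0, 3.0, 7.0] * 21)  # 105 samples
        t = period.start + 60.0 * np.arange(105)
        got = body.coat_metric(self.coat(t, vals), period, min_samples=100)
        assert got == sorted(vals)[52]

    def test_matches_sort_based_median_oracle(self):
        period = make_period(2)
        rng = np.random.default_rng(19)
        vals = rng.gamma(4, 3, 200)
        t = period.start + 60.0 * np.arange(200)
        got = body.coat_metric(self.coat(t, vals), period)
        s = np.sort(vals)
        assert got == pytest.approx((s[99] + s[100]) / 2)

    def test_too_few_samples_missing(self):
        period = make_period(2)
        t = period.start + 60.0 * np.arange(50)
        assert body.coat_metric(self.coat(t, np.full(50, 5.0)), period,
                                min_samples=100) is None
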