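"""Pairing, regressions, residual correlation, correlation matrices, WPGMA."""

from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dfi import cohort


def textbook_linregress_oracle(xs, ys):
    """Pearson R and two-sided p from the raw formulas (independent of
    scipy.stats.linregress)."""
    n = len(xs)
    xs = np.asarray(xs, float)
    ys = np.asarray(ys, float)
    sxy = ((xs - xs.mean()) * (ys - ys.mean())).sum()
    sxx = ((xs - xs.mean()) ** 2).sum()
    syy = ((ys - ys.mean()) ** 2).sum()
    slope = sxy / sxx
    intercept = ys.mean() - slope * xs.mean()
    r = sxy / np.sqrt(sxx * syy)
    t = r * np.sqrt((n - 2) / (1 - r * r))
    p = 2 * stats.t.sf(abs(t), n - 2)
    return slope, intercept, r, p


class TestLinregress:
    def test_exact_line(self):
        xs = np.arange(10.0)
        res = cohort.linregress(xs, 2 * xs + 1)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.pearson_r == pytest.approx(1.0)

    def test_constant_y_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            cohort.linregress(np.arange(5.0), np.full(5, 3.0))
        with pytest.raises(ValueError, match="degenerate"):
            cohort.linregress(np.full(5, 3.0), np.arange(5.0))

    def test_matches_textbook_formula_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            xs = rng.normal(0, 3, 30)
            ys = 0.5 * xs + rng.normal(0, 1, 30)
            res = cohort.linregress(xs, ys)
            slope, intercept, r, p = textbook_linregress_oracle(xs, ys)
            assert res.slope == pytest.approx(slope, rel=1e-9)
            assert res.intercept == pytest.approx(intercept, rel=1e-9)
            assert res.pearson_r == pytest.approx(r, rel=1e-9)
            assert res.p_value == pytest.approx(p, rel=1e-9)


def dfi_frame(rows):
    return pd.DataFrame(rows, columns=["mouse_id", "date", "dfi"])


def mfi_frame(rows):
    return pd.DataFrame(rows, columns=["mouse_id", "date", "mfi"])


class TestPairing:
    d0 = date(2022, 3, 1)

    def test_closest_mfi_chosen(self):
        dfi = dfi_frame([("m1", self.d0 + timedelta(days=10), 0.3)])
        mfi = mfi_frame([("m1", self.d0 + timedelta(days=5), 0.1),
                         ("m1", self.d0 + timedelta(days=16), 0.2)])
        pairs = cohort.pair_mfi_dfi(dfi, mfi)
        assert len(pairs) == 1
        assert pairs[0].mfi_date == self.d0 + timedelta(days=5)

    def test_eight_day_gap_excluded(self):
        dfi = dfi_frame([("m1", self.d0 + timedelta(days=10), 0.3)])
        mfi = mfi_frame([("m1", self.d0 + timedelta(days=18), 0.1)])
        assert cohort.pair_mfi_dfi(dfi, mfi) == []

    def test_seven_day_gap_kept(self):
        dfi = dfi_frame([("m1", self.d0 + timedelta(days=10), 0.3)])
        mfi = mfi_frame([("m1", self.d0 + timedelta(days=17), 0.1)])
        assert len(cohort.pair_mfi_dfi(dfi, mfi)) == 1

    def test_equidistant_tie_resolves_to_earlier_mfi(self):
        dfi = dfi_frame([("m1", self.d0 + timedelta(days=10), 0.3)])
        mfi = mfi_frame([("m1", self.d0 + timedelta(days=7), 0.1),
                         ("m1", self.d0 + timedelta(days=13), 0.2)])
        pairs = cohort.pair_mfi_dfi(dfi, mfi)
        assert pairs[0].mfi_date == self.d0 + timedelta(days=7)

    def test_cross_mouse_pairing_forbidden(self):
        dfi = dfi_frame([("m1", self.d0, 0.3)])
        mfi = mfi_frame([("m2", self.d0, 0.1)])
        assert cohort.pair_mfi_dfi(dfi, mfi) == []

    def test_output_size_and_gap_invariants(self):
        rng = np.random.default_rng(41)
        dfi_rows = [(f"m{i % 9}", self.d0 + timedelta(days=int(rng.integers(0, 60))),
                     float(rng.random())) for i in range(40)]
        mfi_rows = [(f"m{i % 7}", self.d0 + timedelta(days=int(rng.integers(0, 60))),
                     float(rng.random())) for i in range(25)]
        pairs = cohort.pair_mfi_dfi(dfi_frame(dfi_rows), mfi_frame(mfi_rows))
        assert len(pairs) <= len(dfi_rows)
        for p in pairs:
            assert abs((p.dfi_date - p.mfi_date).days) < 8


class TestResidualCorrelation:
    def test_exact_linear_functions_of_age_degenerate(self):
        age = np.arange(10.0)
        pairs = pd.DataFrame({"age_days": age, "mfi": 0.001 * age + 0.1,
                              "dfi": 0.002 * age})
        with pytest.raises(ValueError, match="degenerate"):
            cohort.age_residual_correlation(pairs)

    def test_shared_latent_survives_age_normalization(self):
        rng = np.random.default_rng(51)
        n = 80
        age = rng.uniform(150, 900, n)
        latent = rng.normal(0, 1, n)  # non-age frailty component
        mfi = 0.0003 * age + 0.05 * latent + rng.normal(0, 0.02, n)
        dfi = 0.0004 * age + 0.08 * latent + rng.normal(0, 0.03, n)
        pairs = pd.DataFrame({"age_days": age, "mfi": mfi, "dfi": dfi})
        res, dfi_res, mfi_res = cohort.age_residual_correlation(pairs)
        assert res.pearson_r > 0.3
        assert res.p_value < 0.01
        # residuals are centered and age-orthogonal
        assert abs(np.mean(mfi_res)) < 1e-10
        assert abs(np.corrcoef(age, mfi_res)[0, 1]) < 1e-8

    def test_permutation_breaks_residual_correlation(self):
        rng = np.random.default_rng(52)
        n = 80
        age = rng.uniform(150, 900, n)
        latent = rng.normal(0, 1, n)
        pairs = pd.DataFrame({
            "age_days": age,
            "mfi": 0.0003 * age + 0.05 * latent + rng.normal(0, 0.02, n),
            "dfi": 0.0004 * age + 0.08 * latent + rng.normal(0, 0.03, n),
        })
        _, dfi_res, mfi_res = cohort.age_residual_correlation(pairs)
        rs = []
        for _ in range(100):
            perm = rng.permutation(n)
            rs.append(cohort.linregress(dfi_res[perm], mfi_res).pearson_r)
        assert abs(np.mean(rs)) < 0.1


class TestCorrelationMatrix:
    def test_duplicated_column_perfect_correlation(self):
        rng = np.random.default_rng(61)
        a = rng.normal(0, 1, 30)
        table = pd.DataFrame({"a": a, "b": a.copy(), "c": rng.normal(0, 1, 30)})
        corr = cohort.component_correlation_matrix(table)
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert np.allclose(corr.values.T, corr.values)
        assert np.allclose(np.diag(corr), 1.0)

    def test_sparse_mfi_item_filter_is_strict(self):
        base = np.zeros(30)
        five = base.copy()
        five[:5] = 0.5
        six = base.copy()
        six[:6] = 0.5
        table = pd.DataFrame({"dfi": np.random.default_rng(1).random(30),
                              "item_a": five, "item_b": six})
        corr = cohort.component_correlation_matrix(
            table, mfi_item_columns=["item_a", "item_b"])
        assert "item_a" not in corr.columns  # exactly 5 non-zero: excluded
        assert "item_b" in corr.columns      # 6 non-zero: included

    def test_matches_pairwise_linregress_oracle(self):
        rng = np.random.default_rng(62)
        table = pd.DataFrame(rng.normal(0, 1, (25, 4)),
                             columns=list("wxyz"))
        table.loc[3, "x"] = np.nan  # pairwise-complete deletion
        corr = cohort.component_correlation_matrix(table)
        for a in "wxyz":
            for b in "wxyz":
                if a == b:
                    continue
                sub = table[[a, b]].dropna()
                oracle = cohort.linregress(sub[a].to_numpy(),
                                           sub[b].to_numpy()).pearson_r
                assert corr.loc[a, b] == pytest.approx(oracle, rel=1e-9)

    def test_constant_column_yields_missing(self):
        table = pd.DataFrame({"a": np.arange(10.0), "b": np.full(10, 2.0)})
        corr = cohort.component_correlation_matrix(table)
        assert np.isnan(corr.loc["a", "b"])


class TestWpgma:
    def hand_matrix(self):
        # distances d = 1 - R chosen for a fully hand-checkable merge path
        d = np.array([
            [0.0, 0.1, 0.4, 0.7],
            [0.1, 0.0, 0.5, 0.8],
            [0.4, 0.5, 0.0, 0.9],
            [0.7, 0.8, 0.9, 0.0],
        ])
        return pd.DataFrame(1.0 - d, index=list("ABCD"), columns=list("ABCD"))

    def test_hand_worked_merge_order_and_heights(self):
        merges = cohort.wpgma_cluster(self.hand_matrix())
        # step 1: A,B at 0.1 -> E; d(E,C) = (0.4+0.5)/2 = 0.45,
        #         d(E,D) = (0.7+0.8)/2 = 0.75
        # step 2: E,C at 0.45 -> F; d(F,D) = (0.75+0.9)/2 = 0.825
        # step 3: F,D at 0.825
        assert {int(merges.loc[0, "left"]), int(merges.loc[0, "right"])} == {0, 1}
        assert merges.loc[0, "height"] == pytest.approx(0.1)
        assert {int(merges.loc[1, "left"]), int(merges.loc[1, "right"])} == {2, 4}
        assert merges.loc[1, "height"] == pytest.approx(0.45)
        assert {int(merges.loc[2, "left"]), int(merges.loc[2, "right"])} == {3, 5}
        assert merges.loc[2, "height"] == pytest.approx(0.825)

    def test_identical_traits_merge_first_at_zero(self):
        rng = np.random.default_rng(71)
        a = rng.normal(0, 1, 40)
        table = pd.DataFrame({"a": a, "b": a.copy(),
                              "c": rng.normal(0, 1, 40),
                              "d": rng.normal(0, 1, 40)})
        corr = cohort.component_correlation_matrix(table)
        merges = cohort.wpgma_cluster(corr)
        assert {int(merges.loc[0, "left"]), int(merges.loc[0, "right"])} == {0, 1}
        assert merges.loc[0, "height"] == pytest.approx(0.0, abs=1e-12)

    def test_equal_distances_all_heights_equal(self):
        r = np.full((4, 4), 0.3)
        np.fill_diagonal(r, 1.0)
        merges = cohort.wpgma_cluster(pd.DataFrame(r))
        assert np.allclose(merges["height"], 0.7)

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(72)
        table = pd.DataFrame(rng.normal(0, 1, (30, 6)))
        table.columns = [f"t{i}" for i in range(6)]
        corr = cohort.component_correlation_matrix(table)
        merges = cohort.wpgma_cluster(corr)
        h = merges["height"].to_numpy()
        assert (np.diff(h) >= -1e-12).all()

    def test_non_symmetric_rejected(self):
        m = self.hand_matrix()
        m.iloc[0, 1] = 0.123
        with pytest.raises(ValueError, match="symmetric"):
            cohort.wpgma_cluster(m)

    def test_newick_output_parses(self):
        merges = cohort.wpgma_cluster(self.hand_matrix())
        nwk = cohort.merges_to_newick(merges, list("ABCD"))
        assert nwk.endswith(";")
        for leaf in "ABCD":
            assert leaf in nwk
        # round-trip through a standard tree parser
        from io import StringIO

        from Bio import Phylo

        tree = Phylo.read(StringIO(nwk), "newick")
        assert tree.count_terminals() == 4
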