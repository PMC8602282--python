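import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mbtemporal import variability as vb
from tests.conftest import make_table


def brute_force_icc(values, groups):
    """Independent variance-components computation by explicit summation."""
    df = pd.DataFrame({"v": values, "g": groups})
    sizes = df.groupby("g").size()
    df = df[df["g"].isin(sizes[sizes >= 2].index)]
    k = df["g"].nunique()
    N = len(df)
    grand = df["v"].mean()
    ssb = ssw = 0.0
    for g, sub in df.groupby("g"):
        ssb += len(sub) * (sub["v"].mean() - grand) ** 2
        for v in sub["v"]:
            ssw += (v - sub["v"].mean()) ** 2
    msb, msw = ssb / (k - 1), ssw / (N - k)
    k0 = (N - sum(len(sub) ** 2 for _, sub in df.groupby("g")) / N) / (k - 1)
    va = (msb - msw) / k0
    return va / (va + msw)


class TestICC:
    def test_hand_anova(self):
        """Groups {1,2,3} and {4,5,6}: MSB=13.5, MSW=1, var_among=4.1667."""
        r = vb.icc([1, 2, 3, 4, 5, 6], ["a", "a", "a", "b", "b", "b"])
        assert r.var_within == pytest.approx(1.0)
        assert r.var_among == pytest.approx(4.1667, abs=1e-4)
        assert r.icc == pytest.approx(0.8065, abs=1e-4)

    def test_constant_within_participant(self):
        r = vb.icc([2, 2, 5, 5, 9, 9], ["a", "a", "b", "b", "c", "c"])
        assert r.var_within == 0
        assert r.icc == pytest.approx(1.0)

    def test_zero_total_variance_null(self):
        r = vb.icc([3, 3, 3, 3], ["a", "a", "b", "b"])
        assert r.icc is None

    def test_matches_brute_force_on_all_balanced_shapes(self, rng):
        """Exact agreement with an explicit-sum oracle, 2..6 groups x 2..6
        reps, random values."""
        for k in range(2, 7):
            for n in range(2, 7):
                vals = rng.normal(size=k * n) + np.repeat(rng.normal(size=k) * 2, n)
                groups = np.repeat([f"g{i}" for i in range(k)], n)
                r = vb.icc(vals, groups)
                assert r.icc == pytest.approx(brute_force_icc(vals, groups), abs=1e-10)

    def test_matches_brute_force_unbalanced(self, rng):
        for _ in range(50):
            sizes = rng.integers(2, 8, size=rng.integers(2, 6))
            vals, groups = [], []
            for i, n in enumerate(sizes):
                vals.extend(rng.normal(loc=i, size=n))
                groups.extend([f"g{i}"] * n)
            r = vb.icc(vals, groups)
            assert r.icc == pytest.approx(brute_force_icc(vals, groups), abs=1e-10)


class TestCV:
    def test_hand_values(self):
        ab = np.array([[1], [2], [3]])
        table = make_table(ab, ["p", "p", "p"], [0, 1, 2])
        df, summary = vb.cv_per_genus(table)
        assert df["cv"].iloc[0] == pytest.approx(0.5)

    def test_constant_series(self):
        ab = np.array([[5], [5], [5]])
        table = make_table(ab, ["p", "p", "p"], [0, 1, 2])
        df, _ = vb.cv_per_genus(table)
        assert df["cv"].iloc[0] == pytest.approx(0.0)


class TestFoldChanges:
    def test_constant_positive_series(self):
        mo, mc = vb.fold_changes_series([4, 4, 4])
        assert mo == 1.0 and mc == 1.0

    def test_hand_series(self):
        mo, mc = vb.fold_changes_series([10, 1000, 50])
        assert mo == 100.0 and mc == 100.0

    def test_too_few_positive(self):
        assert vb.fold_changes_series([0, 7, 0]) == (None, None)

    @given(st.lists(st.integers(min_value=0, max_value=1000), min_size=2, max_size=12))
    @settings(deadline=None, max_examples=200)
    def test_matches_exhaustive_pairs(self, series):
        """Fold statistics agree with exhaustive pair enumeration."""
        mo, mc = vb.fold_changes_series(series)
        pos = [(i, v) for i, v in enumerate(series) if v > 0]
        pairs = [max(a, b) / min(a, b) for _, a in pos for _, b in pos if a is not b] or None
        if len(pos) < 2:
            assert mo is None and mc is None
            return
        vals = [v for _, v in pos]
        expected_overall = max(max(a, b) / min(a, b)
                               for i, a in enumerate(vals) for b in vals[i + 1:])
        assert mo == pytest.approx(expected_overall)
        adj = [max(series[i], series[i + 1]) / min(series[i], series[i + 1])
               for i in range(len(series) - 1)
               if series[i] > 0 and series[i + 1] > 0]
        if adj:
            assert mc == pytest.approx(max(adj))
        else:
            assert mc is None
        if mc is not None:
            assert mc <= mo + 1e-12

    def test_rank_span(self):
        ab = np.array([[100, 10, 1], [1, 10, 100], [100, 10, 1]])
        table = make_table(ab, ["p", "p", "p"], [0, 1, 2])
        df = vb.fold_changes(table)
        spans = df.set_index("genus_id")["rank_span"]
        assert spans["g0"] == 3  # ranks 1 and 3 covered
        assert spans["g1"] == 1  # always rank 2


class TestADF:
    def test_stationary_ar1_rejected(self):
        """AR(1) with coefficient 0.2, n=40: unit root rejected >= 80%."""
        rng = np.random.default_rng(0)
        hits = 0
        reps = 500
        for _ in range(reps):
            x = np.empty(40)
            x[0] = rng.normal()
            for t in range(1, 40):
                x[t] = 0.2 * x[t - 1] + rng.normal()
            hits += vb.adf_stationarity(x).stationary
        assert hits / reps >= 0.8

    def test_random_walk_not_rejected(self):
        rng = np.random.default_rng(1)
        hits = 0
        reps = 500
        for _ in range(reps):
            x = np.cumsum(rng.normal(size=40))
            hits += vb.adf_stationarity(x).stationary
        assert hits / reps <= 0.1

    def test_presence_filter_skips(self):
        ab = np.zeros((12, 2))
        ab[:, 0] = np.arange(1, 13)
        ab[:3, 1] = 1
        table = make_table(ab.astype(int), ["p"] * 12, list(range(12)))
        res = vb.adf_per_genus(table, presence_threshold=0.6)
        assert bool(res.set_index("genus_id").loc["g1", "skipped"])
        assert not bool(res.set_index("genus_id").loc["g0", "skipped"])


class TestTaylor:
    def test_constant_cv_exact(self):
        fit = vb.taylor_fit([10, 100, 1000, 20, 50], [100, 10000, 1e6, 400, 2500])
        assert fit.slope == pytest.approx(2.0)
        assert fit.adj_r2 == pytest.approx(1.0)

    def test_hand_least_squares(self):
        # (log m, log v) = (0,0),(1,1.5),(2,3.4) plus two repeats to reach 5 pts
        m = 10.0 ** np.array([0, 1, 2, 0, 2])
        v = 10.0 ** np.array([0, 1.5, 3.4, 0, 3.4])
        fit = vb.taylor_fit(m, v)
        x = np.log10(m); y = np.log10(v)
        expected = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        assert fit.slope == pytest.approx(expected)

    def test_too_few_points(self):
        fit = vb.taylor_fit([1, 10], [1, 100])
        assert fit.slope is None

    def test_scale_invariance(self, rng):
        m = rng.uniform(1, 100, size=8)
        v = m**2.3 * rng.uniform(0.5, 2, size=8)
        f1 = vb.taylor_fit(m, v)
        f2 = vb.taylor_fit(m * 1e-9, v * 1e-18)  # rescale abundances by 1e-9
        assert f1.slope == pytest.approx(f2.slope, rel=1e-9)

    def test_rank_contrast(self):
        slopes = pd.Series({"a": 2.0, "b": 2.1, "c": 1.9, "d": 1.5, "e": 1.4, "f": 1.6})
        ranks = pd.Series({"a": 1, "b": 2, "c": 3, "d": 4, "e": 5, "f": 6})
        t, p = vb.taylor_rank_contrast(slopes, ranks, top_n=3)
        from scipy.stats import ttest_ind
        te, pe = ttest_ind([2.0, 2.1, 1.9], [1.5, 1.4, 1.6], equal_var=False)
        assert t == pytest.approx(te) and p == pytest.approx(pe)

    def test_rank_contrast_identical_groups(self):
        slopes = pd.Series({"a": 2.0, "b": 2.0, "c": 2.0, "d": 2.0})
        ranks = pd.Series({"a": 1, "b": 2, "c": 3, "d": 4})
        t, p = vb.taylor_rank_contrast(slopes, ranks, top_n=2)
        assert t == 0.0 and p == 1.0
        with pytest.raises(ValueError):
            vb.taylor_rank_contrast(slopes, ranks, top_n=4)


class TestMedianErrorCurve:
    def test_constant_series_zero_error(self):
        ab = np.tile([[10, 5]], (8, 1))
        table = make_table(ab, ["p"] * 8, list(range(8)))
        curve, _ = vb.median_error_curve(table, n_points=range(1, 9), reps=50)
        assert np.allclose(curve.to_numpy(), 0.0)

    def test_full_length_zero_error(self, rng):
        ab = rng.integers(1, 100, size=(8, 3))
        table = make_table(ab, ["p"] * 8, list(range(8)))
        curve, _ = vb.median_error_curve(table, n_points=[8], reps=20)
        assert curve.loc[8] == 0.0

    def test_non_increasing_in_expectation(self, rng):
        ab = rng.lognormal(3, 1, size=(20, 5)).astype(int) + 1
        table = make_table(ab, ["p"] * 20, list(range(20)))
        curve, elbow = vb.median_error_curve(table, n_points=range(1, 21),
                                             reps=500, seed=1)
        # allow small Monte-Carlo wiggle
        diffs = np.diff(curve.to_numpy())
        assert (diffs <= curve.max() * 0.05).all()
        assert 1 <= elbow <= 20
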