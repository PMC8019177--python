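"""Accuracy detectors: fence oracles, affine invariance, seeded
simulation checks of type-I error, power and parameter recovery."""

import statistics

import numpy as np
import pandas as pd
import pytest

from dqframe.accuracy import (
    OUTLIER_RULES,
    distribution_descriptor,
    end_digits,
    loess_trend,
    margins,
    multivariate_outliers,
    outlier_fences,
    shape_or_scale,
    univariate_outliers,
    varcomp,
)


# ---------------------------------------------------------------------------
# Brute-force oracles (kept deliberately naive and independent)
# ---------------------------------------------------------------------------

def quantile_type7(sorted_x, p):
    n = len(sorted_x)
    h = (n - 1) * p
    lo = int(np.floor(h))
    hi = min(lo + 1, n - 1)
    return sorted_x[lo] + (h - lo) * (sorted_x[hi] - sorted_x[lo])


def brute_fences(x, rule):
    xs = sorted(float(v) for v in x)
    q1 = quantile_type7(xs, 0.25)
    q3 = quantile_type7(xs, 0.75)
    iqr = q3 - q1
    if rule == "tukey":
        return q1 - 1.5 * iqr, q3 + 1.5 * iqr
    if rule == "six-sigma":
        m = statistics.fmean(xs)
        s = statistics.stdev(xs)
        return m - 3 * s, m + 3 * s
    if rule == "mad-rule":
        med = quantile_type7(xs, 0.5)
        mad = quantile_type7(sorted(abs(v - med) for v in xs), 0.5)
        return med - 3 * 1.4826 * mad, med + 3 * 1.4826 * mad
    raise AssertionError(rule)


def brute_medcouple(x):
    """Literal O(n^2) medcouple kernel; a value equal to the median
    pairs with itself with kernel 0."""
    xs = np.sort(np.asarray(x, dtype=float))
    med = quantile_type7(list(xs), 0.5)
    lo = xs[xs <= med]
    hi = xs[xs >= med]
    vals = [
        ((xj - med) - (med - xi)) / (xj - xi) if xj != xi else 0.0
        for xi in lo
        for xj in hi
    ]
    return float(np.median(vals))


class TestOutlierFences:
    def test_exactly_four_rules(self):
        assert len(OUTLIER_RULES) == 4

    @pytest.mark.parametrize("rule", ["tukey", "six-sigma", "mad-rule"])
    def test_fences_match_brute_force(self, rule):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = int(rng.integers(11, 201))
            x = rng.normal(rng.uniform(-50, 50), rng.uniform(0.5, 20), n)
            lo, hi = outlier_fences(x, rule)
            blo, bhi = brute_fences(x, rule)
            assert lo == pytest.approx(blo, rel=1e-9, abs=1e-9)
            assert hi == pytest.approx(bhi, rel=1e-9, abs=1e-9)

    def test_hubert_equals_tukey_on_symmetric_sample(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            half = rng.normal(0, 1, 25)
            x = np.concatenate([half, -half]) + rng.uniform(-10, 10)
            assert outlier_fences(x, "hubert") == pytest.approx(
                outlier_fences(x, "tukey"), rel=1e-9, abs=1e-9
            )

    def test_hubert_uses_exact_medcouple(self):
        rng = np.random.default_rng(3)
        x = rng.gamma(2.0, 3.0, 61)  # odd n, distinct values: no ties
        mc = brute_medcouple(x)
        q1, q3 = np.quantile(x, [0.25, 0.75])
        iqr = q3 - q1
        if mc >= 0:
            expect = (q1 - 1.5 * np.exp(-4 * mc) * iqr,
                      q3 + 1.5 * np.exp(3 * mc) * iqr)
        else:
            expect = (q1 - 1.5 * np.exp(-3 * mc) * iqr,
                      q3 + 1.5 * np.exp(4 * mc) * iqr)
        assert outlier_fences(x, "hubert") == pytest.approx(expect, rel=1e-9)


class TestUnivariateOutliers:
    def test_tukey_flags_planted_extreme(self):
        # [1..10, 100]: type-7 quartiles 3.5/8.5 -> fences -4 and 16
        col = pd.Series(list(range(1, 11)) + [100], dtype=float)
        lo, hi = outlier_fences(col.to_numpy(), "tukey")
        assert (lo, hi) == (-4.0, 16.0)
        res, verdicts = univariate_outliers(col, rules=("tukey",))
        assert res.n_flagged == 1
        assert verdicts[0].value == 100
        assert verdicts[0].direction == "high"

    def test_constant_column_has_no_outliers(self):
        col = pd.Series([5.0] * 20)
        res, _ = univariate_outliers(col)
        assert res.n_flagged == 0

    def test_below_floor_not_applicable(self):
        res, _ = univariate_outliers(pd.Series([1.0, 2.0]))
        assert res.grading == "not-applicable"

    def test_every_verdict_names_its_rules(self):
        rng = np.random.default_rng(0)
        col = pd.Series(np.append(rng.normal(0, 1, 100), 50.0))
        _, verdicts = univariate_outliers(col)
        assert verdicts and all(v.rules_fired for v in verdicts)


class TestMultivariateOutliers:
    def test_identity_covariance_distance_is_z_norm(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 400)
        b = rng.normal(0, 1, 400)
        df = pd.DataFrame({"a": a, "b": b})
        _, dist = multivariate_outliers(df)
        za = (a - a.mean()) / a.std(ddof=1)
        zb = (b - b.mean()) / b.std(ddof=1)
        # weak correlation only: distances close to sqrt(za^2+zb^2)
        approx = np.sqrt(za**2 + zb**2)
        assert np.corrcoef(dist, approx)[0, 1] > 0.99

    def test_centroid_point_has_zero_distance(self):
        df = pd.DataFrame(
            {"a": [1.0, 3.0, 2.0, 2.0, 2.0],
             "b": [10.0, 30.0, 10.0, 30.0, 20.0]}
        )  # last point is exactly the centroid
        _, dist = multivariate_outliers(df)
        assert dist.iloc[4] == pytest.approx(0.0, abs=1e-8)

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (200, 3))
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        A = np.array([[2.0, 0.3, 0.0], [0.1, 1.5, 0.2], [0.0, 0.4, 3.0]])
        dft = pd.DataFrame(X @ A.T + [5, -3, 7], columns=["a", "b", "c"])
        _, d1 = multivariate_outliers(df)
        _, d2 = multivariate_outliers(dft)
        np.testing.assert_allclose(d1.to_numpy(), d2.to_numpy(), rtol=1e-8)

    def test_planted_five_sigma_point_flagged(self):
        rng = np.random.default_rng(11)
        X = rng.normal(0, 1, (500, 2))
        X[0] = [5.0, 5.0]
        res, _ = multivariate_outliers(pd.DataFrame(X, columns=["a", "b"]))
        assert "0" in {r for r, _ in res.flagged_cells}

    def test_singular_covariance_names_collinear_pair(self):
        a = np.arange(50.0)
        df = pd.DataFrame({"a": a, "b": 2 * a, "c": np.random.default_rng(0).normal(size=50)})
        with pytest.raises(ValueError, match="collinear"):
            multivariate_outliers(df)


class TestDistributionDescriptor:
    def test_histogram_counts_sum_to_n(self):
        x = np.random.default_rng(0).normal(0, 1, 137)
        payload = distribution_descriptor(x)
        assert sum(payload["counts"]) == 137

    def test_ecdf_ends_at_one_and_group_identity(self):
        x = list(range(10)) * 2
        g = ["u"] * 10 + ["v"] * 10
        payload = distribution_descriptor(x, group=pd.Series(g))
        ec = payload["ecdf_by_group"]
        assert ec["u"]["F"][-1] == 1.0
        assert ec["u"] == ec["v"]


class TestShapeOrScale:
    def test_expected_counts_sum_to_n(self):
        x = np.random.default_rng(0).normal(10, 2, 500)
        res = shape_or_scale(x, "normal")
        assert sum(res.descriptor["expected"]) == pytest.approx(500, abs=0.5)

    def test_normal_data_vs_uniform_family_rejected(self):
        rng = np.random.default_rng(5)
        rejections = sum(
            shape_or_scale(rng.normal(0, 1, 1000), "uniform").n_flagged
            for _ in range(20)
        )
        assert rejections == 20  # power ~ 1

    def test_uniform_null_type_one_error_controlled(self):
        rng = np.random.default_rng(6)
        ok = 0
        reps = 60
        for _ in range(reps):
            res = shape_or_scale(rng.uniform(0, 10, 1000), "uniform",
                                 alpha=0.01)
            ok += res.descriptor["pvalue"] > 0.01
        assert ok / reps >= 0.95

    def test_unsupported_family_is_config_error(self):
        with pytest.raises(ValueError):
            shape_or_scale(np.ones(100), "cauchy")


class TestEndDigits:
    def test_exactly_uniform_digits_zero_statistic(self):
        values = [10 * k + d for d in range(10) for k in range(10)]
        res = end_digits(pd.Series(values, dtype=float))
        assert res.descriptor["chi2"] == 0.0

    def test_all_zero_digits_chi2_900(self):
        values = [10.0 * k for k in range(100)]
        res = end_digits(pd.Series(values))
        assert res.descriptor["chi2"] == pytest.approx(900.0)

    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(8)
        reps = 100
        rejections = sum(
            end_digits(pd.Series(rng.integers(0, 1000, 500).astype(float))).n_flagged
            for _ in range(reps)
        )
        # 99% binomial CI around 0.05 at 100 reps: [0, 0.11]
        assert rejections / reps <= 0.11


def make_examiner_data(rng, n_classes=5, n_per_class=100, shift_class=None,
                       shift_sd=0.0):
    rows = []
    for c in range(1, n_classes + 1):
        age = rng.uniform(20, 80, n_per_class)
        y = 100 + 0.2 * age + rng.normal(0, 5.0, n_per_class)
        if shift_class == c:
            y = y + shift_sd * 5.0
        for a, v in zip(age, y):
            rows.append({"y": v, "examiner": str(c), "age": a})
    return pd.DataFrame(rows)


class TestMargins:
    def test_no_covariates_reduces_to_raw_class_means(self):
        rng = np.random.default_rng(9)
        data = make_examiner_data(rng)
        mres, _ = margins(data, "y", "examiner", covariates=[])
        raw = data.groupby("examiner")["y"].mean()
        for cls, row in mres.per_class.iterrows():
            assert row["mean"] == pytest.approx(raw[cls], rel=1e-9)

    def test_type_one_error_flag_rate(self):
        rng = np.random.default_rng(10)
        flags = classes = 0
        for _ in range(60):
            data = make_examiner_data(rng)
            mres, _ = margins(data, "y", "examiner", covariates=["age"])
            flags += len(mres.flagged_classes)
            classes += len(mres.per_class)
        assert flags / classes <= 0.075

    def test_power_on_shifted_examiner(self):
        rng = np.random.default_rng(12)
        hits = 0
        reps = 40
        for _ in range(reps):
            data = make_examiner_data(rng, shift_class=3, shift_sd=1.0)
            mres, _ = margins(data, "y", "examiner", covariates=["age"])
            hits += "3" in mres.flagged_classes
        assert hits / reps >= 0.95

    def test_binary_response_uses_logistic_family(self):
        rng = np.random.default_rng(13)
        data = make_examiner_data(rng)
        data["y"] = (rng.random(len(data)) < 0.3).astype(float)
        mres, res = margins(data, "y", "examiner")
        assert mres.family == "logistic"
        assert res.indicator_id == "DQI-4006"
        assert ((mres.per_class["ci_low"] <= mres.per_class["mean"])
                & (mres.per_class["mean"] <= mres.per_class["ci_high"])).all()

    def test_single_class_not_applicable(self):
        data = pd.DataFrame({"y": [1.0] * 20, "examiner": ["1"] * 20})
        mres, res = margins(data, "y", "examiner")
        assert mres is None
        assert res.grading == "not-applicable"


class TestVarcomp:
    def test_icc_parameter_recovery(self):
        # class effects standardised to realised variance 1 and residuals
        # to variance 4, so the estimator is tested against the exact
        # realised components: ICC = 1/(1+4) = 0.2
        rng = np.random.default_rng(14)
        mu = rng.normal(0, 1.0, 20)
        mu = (mu - mu.mean()) / mu.std()
        rows = []
        for c in range(20):
            e = rng.normal(0, 1.0, 50)
            e = (e - e.mean()) / e.std() * 2.0
            for v in mu[c] + e:
                rows.append({"y": v, "cls": str(c)})
        res = varcomp(pd.DataFrame(rows), "y", "cls")
        assert res.descriptor["icc"] == pytest.approx(0.2, abs=0.05)

    def test_null_icc_small(self):
        rng = np.random.default_rng(15)
        ok = 0
        reps = 20
        for _ in range(reps):
            rows = [
                {"y": v, "cls": str(c)}
                for c in range(10)
                for v in rng.normal(0, 1.0, 40)
            ]
            res = varcomp(pd.DataFrame(rows), "y", "cls")
            ok += res.descriptor["icc"] <= 0.02
        assert ok / reps >= 0.95

    def test_icc_bounded(self):
        rng = np.random.default_rng(16)
        rows = [
            {"y": v, "cls": str(c)}
            for c in range(4)
            for v in rng.normal(c * 10.0, 0.1, 30)
        ]
        res = varcomp(pd.DataFrame(rows), "y", "cls")
        assert 0.0 <= res.descriptor["icc"] <= 1.0
        assert res.grading == "issue"

    def test_single_class_not_applicable(self):
        res = varcomp(
            pd.DataFrame({"y": [1.0, 2.0], "cls": ["a", "a"]}), "y", "cls"
        )
        assert res.grading == "not-applicable"

    def test_agrees_with_anova_method_of_moments(self):
        # balanced one-way design: sigma2_b = (MSB - MSW) / n_per_class
        rng = np.random.default_rng(21)
        n_cls, n_per = 15, 40
        data = pd.DataFrame(
            {
                "y": np.concatenate(
                    [rng.normal(mu, 1.5, n_per)
                     for mu in rng.normal(0, 0.8, n_cls)]
                ),
                "cls": np.repeat([str(c) for c in range(n_cls)], n_per),
            }
        )
        res = varcomp(data, "y", "cls")
        groups = data.groupby("cls")["y"]
        grand = data["y"].mean()
        msb = n_per * ((groups.mean() - grand) ** 2).sum() / (n_cls - 1)
        msw = groups.var(ddof=1).mean()
        s2b = max((msb - msw) / n_per, 0.0)
        icc_anova = s2b / (s2b + msw)
        assert res.descriptor["icc"] == pytest.approx(icc_anova, abs=0.01)


class TestLoessTrend:
    def _data(self, rng, n=200, drift=0.0):
        t = pd.date_range("2000-01-01", periods=n, freq="D")
        y = 50 + rng.normal(0, 1.0, n) + drift * np.linspace(0, 1, n)
        return pd.DataFrame(
            {"y": y, "t": t.strftime("%Y-%m-%d"), "cls": ["a"] * n}
        )

    def test_constant_response_zero_residual(self):
        data = self._data(np.random.default_rng(17), 100, 0.0)
        data["y"] = 42.0
        payload = loess_trend(data, "y", "t", class_var="cls")
        smoothed = payload["series"]["a"]["smoothed_residual"]
        assert max(abs(v) for v in smoothed) < 1e-9

    def test_injected_drift_yields_monotone_trend(self):
        data = self._data(np.random.default_rng(18), 400, drift=5.0)
        payload = loess_trend(data, "y", "t", class_var="cls")
        sm = np.array(payload["series"]["a"]["smoothed_residual"])
        diffs = np.diff(sm)
        assert (diffs > -1e-6).mean() > 0.95  # monotone within noise

    def test_smoothed_values_within_residual_range(self):
        data = self._data(np.random.default_rng(19), 300)
        payload = loess_trend(data, "y", "t", class_var="cls")
        sm = np.array(payload["series"]["a"]["smoothed_residual"])
        resid = data["y"] - data["y"].mean()
        assert sm.min() >= resid.min() - 1e-9
        assert sm.max() <= resid.max() + 1e-9

    def test_degenerate_time_not_applicable(self):
        data = pd.DataFrame(
            {"y": [1.0, 2.0], "t": ["2000-01-01", "2000-01-01"]}
        )
        payload = loess_trend(data, "y", "t")
        assert payload["series"] == {}
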