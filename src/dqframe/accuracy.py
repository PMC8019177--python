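"""Accuracy: statistical detectors for unexpected distributions,
process-variable effects and reliability.

Univariate outliers combine four rules (Tukey fences, six sigma,
Hubert's skewness-adjusted fences via the medcouple, and a robust MAD
rule); multivariate outliers apply the same rules to Mahalanobis
distances.  Distributional shape is tested against a declared family
with a Pearson chi-square on equal-probability bins and visualised as
hanging-rootogram residuals; end-digit preference is a chi-square
goodness-of-fit against uniform digits.  Examiner/device effects are
screened with covariate-adjusted marginal means (linear, logistic or
Poisson models by response type) and with a random-intercept variance
decomposition (ICC).  Time trends are LOESS-smoothed descriptors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.stattools import medcouple

from .core_model import IndicatorResult, VariableMetadata

__all__ = [
    "OUTLIER_RULES",
    "OutlierVerdict",
    "outlier_fences",
    "univariate_outliers",
    "multivariate_outliers",
    "distribution_descriptor",
    "shape_or_scale",
    "end_digits",
    "MarginsResult",
    "margins",
    "varcomp",
    "loess_trend",
]

OUTLIER_RULES = ("tukey", "six-sigma", "hubert", "mad-rule")


@dataclass
class OutlierVerdict:
    record_id: object
    value: float
    rules_fired: tuple
    direction: str  # low | high


def outlier_fences(values: np.ndarray, rule: str) -> tuple[float, float]:
    """(lower, upper) fence for one rule on a clean numeric sample.

    Quantiles use linear interpolation (type 7) so fences are
    reproducible across implementations.  'six-sigma' is mean +/- 3
    sample standard deviations (total width six sigma); the Hubert
    fences tilt Tukey's by exp(-4*MC)/exp(3*MC) for medcouple MC >= 0,
    with the exponents mirrored for MC < 0.
    """
    x = np.asarray(values, dtype=float)
    if rule == "tukey":
        q1, q3 = np.quantile(x, [0.25, 0.75])
        iqr = q3 - q1
        return q1 - 1.5 * iqr, q3 + 1.5 * iqr
    if rule == "six-sigma":
        m, s = x.mean(), x.std(ddof=1)
        return m - 3 * s, m + 3 * s
    if rule == "hubert":
        q1, q3 = np.quantile(x, [0.25, 0.75])
        iqr = q3 - q1
        mc = float(medcouple(x)) if iqr > 0 else 0.0
        if mc >= 0:
            return q1 - 1.5 * np.exp(-4 * mc) * iqr, q3 + 1.5 * np.exp(3 * mc) * iqr
        return q1 - 1.5 * np.exp(-3 * mc) * iqr, q3 + 1.5 * np.exp(4 * mc) * iqr
    if rule == "mad-rule":
        med = np.median(x)
        mad = np.median(np.abs(x - med))
        w = 3 * 1.4826 * mad
        return med - w, med + w
    raise ValueError(f"unknown outlier rule {rule!r}")


def univariate_outliers(
    column,
    rules: tuple = OUTLIER_RULES,
    threshold: int = 1,
    record_ids: pd.Series | None = None,
    variable: str = "study-level",
    min_n: int = 10,
) -> tuple[IndicatorResult, list[OutlierVerdict]]:
    """Univariate outliers by consensus of up to four rules.

    ``column`` must already be numeric with qualified codes and
    hard-limit violations removed.  A value is flagged when at least
    ``threshold`` rules fire; the direction (low/high) is reported per
    value.  Fewer than ``min_n`` non-missing values -> not-applicable.
    """
    vals = pd.Series(column).astype(float)
    if record_ids is None:
        record_ids = pd.Series(vals.index.astype(str), index=vals.index)
    nonmiss = vals.notna()
    x = vals[nonmiss].to_numpy()
    ids = record_ids[nonmiss.to_numpy()]
    if len(x) < min_n:
        return (
            IndicatorResult(
                indicator_id="DQI-4001", variable=variable,
                grading="not-applicable",
            ),
            [],
        )
    unknown = set(rules) - set(OUTLIER_RULES)
    if unknown:
        raise ValueError(f"unknown outlier rules: {sorted(unknown)}")

    fired = {r: np.zeros(len(x), dtype=bool) for r in rules}
    low = np.zeros(len(x), dtype=bool)
    for r in rules:
        lo, hi = outlier_fences(x, r)
        below, above = x < lo, x > hi
        fired[r] = below | above
        low |= below
    n_fired = np.sum(np.column_stack([fired[r] for r in rules]), axis=1)
    flag = n_fired >= threshold

    verdicts = [
        OutlierVerdict(
            record_id=ids.iloc[i],
            value=float(x[i]),
            rules_fired=tuple(r for r in rules if fired[r][i]),
            direction="low" if low[i] else "high",
        )
        for i in np.flatnonzero(flag)
    ]
    result = IndicatorResult(
        indicator_id="DQI-4001",
        variable=variable,
        n_flagged=int(flag.sum()),
        denominator=len(x),
        flagged_cells=[(v.record_id, variable) for v in verdicts],
        descriptor={
            "per_rule_counts": {r: int(fired[r].sum()) for r in rules},
            "n_low": int((flag & low).sum()),
            "n_high": int((flag & ~low).sum()),
        },
    )
    return result, verdicts


def multivariate_outliers(
    columns: pd.DataFrame,
    rules: tuple = OUTLIER_RULES,
    threshold: int = 1,
    record_ids: pd.Series | None = None,
) -> tuple[IndicatorResult, pd.Series]:
    """Mahalanobis-distance outliers over complete cases.

    The distance of each complete case from the sample mean (sample
    covariance, ddof=1) is screened with the univariate rules, high
    direction only.  Returns the indicator result and the distance
    vector (a descriptor in its own right).
    """
    num = columns.apply(pd.to_numeric, errors="coerce")
    if num.shape[1] < 2:
        raise ValueError("multivariate outliers need at least 2 variables")
    complete = num.dropna()
    if record_ids is None:
        record_ids = pd.Series(num.index.astype(str), index=num.index)
    ids = record_ids.loc[complete.index]
    X = complete.to_numpy(dtype=float)
    cov = np.cov(X, rowvar=False, ddof=1)
    try:
        cov_inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:
        corr = np.corrcoef(X, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise ValueError(
            "singular covariance matrix; most collinear pair: "
            f"{complete.columns[i]!r} and {complete.columns[j]!r}"
        ) from exc
    centered = X - X.mean(axis=0)
    d2 = np.einsum("ij,jk,ik->i", centered, cov_inv, centered)
    dist = pd.Series(np.sqrt(np.maximum(d2, 0.0)), index=complete.index)

    fired = {}
    for r in rules:
        _, hi = outlier_fences(dist.to_numpy(), r)
        fired[r] = dist.to_numpy() > hi
    n_fired = np.sum(np.column_stack([fired[r] for r in rules]), axis=1)
    flag = n_fired >= threshold
    var_label = "|".join(columns.columns)
    result = IndicatorResult(
        indicator_id="DQI-4002",
        variable=var_label,
        n_flagged=int(flag.sum()),
        denominator=len(dist),
        flagged_cells=[(ids.iloc[i], var_label) for i in np.flatnonzero(flag)],
        descriptor={"per_rule_counts": {r: int(fired[r].sum()) for r in rules}},
    )
    return result, dist


# ---------------------------------------------------------------------------
# Distribution descriptors and tests
# ---------------------------------------------------------------------------

def distribution_descriptor(
    column, group: pd.Series | None = None, bins: int = 20,
    categorical: bool = False,
) -> dict:
    """Pure descriptor: binned counts (numeric) or level counts
    (categorical), plus per-group ECDF point sets when a grouping
    variable is given.  Carries no machine-readable decision."""
    s = pd.Series(column)
    payload: dict = {"kind": "categorical" if categorical else "histogram"}
    if categorical:
        payload["level_counts"] = s.dropna().astype(str).value_counts().to_dict()
    else:
        x = pd.to_numeric(s, errors="coerce").dropna()
        counts, edges = np.histogram(x, bins=bins)
        payload["counts"] = counts.tolist()
        payload["edges"] = [float(e) for e in edges]
        payload["n"] = int(len(x))
    if group is not None and not categorical:
        x = pd.to_numeric(s, errors="coerce")
        ecdfs = {}
        for level, idx in pd.Series(group).groupby(pd.Series(group)).groups.items():
            vals = x.loc[idx].dropna().sort_values().to_numpy()
            if len(vals) == 0:
                continue
            ecdfs[str(level)] = {
                "x": vals.tolist(),
                "F": (np.arange(1, len(vals) + 1) / len(vals)).tolist(),
            }
        payload["ecdf_by_group"] = ecdfs
    return payload


_FAMILIES = ("normal", "gamma", "uniform")


def _fit_family(x: np.ndarray, family: str, params: dict | None):
    """Method-of-moments fit; returns (frozen scipy dist, n_estimated)."""
    if params:
        if family == "normal":
            return st.norm(params["mean"], params["sd"]), 0
        if family == "gamma":
            return st.gamma(params["shape"], scale=params["scale"]), 0
        if family == "uniform":
            return st.uniform(params["min"], params["max"] - params["min"]), 0
    m, v = x.mean(), x.var(ddof=1)
    if family == "normal":
        return st.norm(m, np.sqrt(v)), 2
    if family == "gamma":
        shape = m * m / v
        scale = v / m
        return st.gamma(shape, scale=scale), 2
    if family == "uniform":
        half = np.sqrt(3 * v)
        return st.uniform(m - half, 2 * half), 2
    raise ValueError(f"unsupported distribution family {family!r}")


def shape_or_scale(
    column,
    family: str,
    params: dict | None = None,
    bins: int = 10,
    variable: str = "study-level",
    min_n: int = 30,
    alpha: float = 0.05,
) -> IndicatorResult:
    """Test the observed distribution against a declared family.

    Parameters are estimated by the method of moments unless fixed.
    Observed counts are compared with expected counts on
    equal-probability bins of the fitted distribution; the statistic is
    Pearson chi-square with df = bins - 1 - #estimated parameters.  The
    descriptor carries hanging-rootogram residuals
    (sqrt(observed) - sqrt(expected) per bin).
    """
    if family not in _FAMILIES:
        raise ValueError(
            f"unsupported family {family!r}; choose from {_FAMILIES}"
        )
    x = pd.to_numeric(pd.Series(column), errors="coerce").dropna().to_numpy()
    if len(x) < min_n:
        return IndicatorResult(
            indicator_id="DQI-4004", variable=variable,
            grading="not-applicable",
        )
    dist, n_est = _fit_family(x, family, params)
    probs = np.linspace(0, 1, bins + 1)
    inner_edges = dist.ppf(probs[1:-1])
    edges = np.concatenate(([-np.inf], inner_edges, [np.inf]))
    observed, _ = np.histogram(x, bins=edges)
    expected = np.diff(dist.cdf(edges)) * len(x)
    df = bins - 1 - n_est
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = float(np.sum((observed - expected) ** 2 / expected))
    pvalue = float(st.chi2.sf(chi2, df)) if df > 0 else float("nan")
    reject = bool(pvalue < alpha) if df > 0 else False
    return IndicatorResult(
        indicator_id="DQI-4004",
        variable=variable,
        n_flagged=int(reject),
        denominator=1,
        descriptor={
            "family": family,
            "chi2": chi2,
            "df": df,
            "pvalue": pvalue,
            "observed": observed.tolist(),
            "expected": expected.tolist(),
            "rootogram_residuals": (
                np.sqrt(observed) - np.sqrt(expected)
            ).tolist(),
        },
        grading="issue" if reject else "ok",
    )


def end_digits(
    column,
    decimals: int = 0,
    variable: str = "study-level",
    min_n: int = 50,
    alpha: float = 0.05,
) -> IndicatorResult:
    """End-digit preference of manually collected measurements.

    The final integer digit (after rounding to the declared precision)
    is tabulated and tested against a uniform digit distribution with a
    chi-square goodness-of-fit test (df = 9).  The descriptor carries
    rootogram-style residuals per digit.
    """
    x = pd.to_numeric(pd.Series(column), errors="coerce").dropna()
    if len(x) < min_n:
        return IndicatorResult(
            indicator_id="DQI-4004", variable=variable,
            grading="not-applicable",
        )
    scaled = np.round(x.to_numpy() * 10.0 ** decimals).astype(np.int64)
    digits = np.abs(scaled) % 10
    counts = np.bincount(digits, minlength=10).astype(float)
    chi2, pvalue = st.chisquare(counts)
    expected = counts.sum() / 10.0
    reject = bool(pvalue < alpha)
    return IndicatorResult(
        indicator_id="DQI-4004",
        variable=variable,
        n_flagged=int(reject),
        denominator=1,
        descriptor={
            "digit_counts": counts.astype(int).tolist(),
            "chi2": float(chi2),
            "df": 9,
            "pvalue": float(pvalue),
            "rootogram_residuals": (
                np.sqrt(counts) - np.sqrt(expected)
            ).tolist(),
        },
        grading="issue" if reject else "ok",
    )


# ---------------------------------------------------------------------------
# Examiner effects: adjusted margins and variance components
# ---------------------------------------------------------------------------

@dataclass
class MarginsResult:
    """Covariate-adjusted marginal means per process-variable class."""

    response: str
    class_var: str
    family: str
    per_class: pd.DataFrame  # index: class level; columns: n, mean, ci_low, ci_high
    overall_mean: float
    flagged_classes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "class_var": self.class_var,
            "family": self.family,
            "overall_adjusted_mean": self.overall_mean,
            "per_class": self.per_class.reset_index()
            .rename(columns={"index": "class"})
            .to_dict(orient="list"),
            "flagged_classes": [str(c) for c in self.flagged_classes],
        }


def _choose_family(y: pd.Series) -> str:
    vals = y.dropna().unique()
    if set(np.unique(vals)).issubset({0, 1, 0.0, 1.0}):
        return "logistic"
    if np.allclose(vals, np.round(vals)) and (vals >= 0).all() and len(
        np.unique(vals)
    ) > 2 and vals.max() <= 50:
        return "poisson"
    return "linear"


def margins(
    study: pd.DataFrame,
    response: str,
    class_var: str,
    covariates: list[str] | None = None,
    family: str | None = None,
    min_class_size: int = 10,
    alpha: float = 0.05,
) -> tuple[MarginsResult | None, IndicatorResult]:
    """Compare covariate-adjusted marginal means across classes.

    Fits ``response ~ covariates + class`` (linear, logistic or Poisson
    by response type) and computes the adjusted marginal mean of each
    class at the covariate means.  A class is flagged when its 95% CI
    excludes the overall adjusted mean (the class-size-weighted average
    of the per-class adjusted means).
    """
    covariates = covariates or []
    cols = [response, class_var] + covariates
    data = study[cols].copy()
    data[response] = pd.to_numeric(data[response], errors="coerce")
    for c in covariates:
        data[c] = pd.to_numeric(data[c], errors="coerce")
    data = data.dropna()
    data[class_var] = data[class_var].astype(str)

    sizes = data[class_var].value_counts()
    levels = sorted(sizes[sizes >= min_class_size].index)
    data = data[data[class_var].isin(levels)]
    indicator = "DQI-4006" if family == "logistic" else "DQI-4003"
    if len(levels) < 2:
        return None, IndicatorResult(
            indicator_id=indicator, variable=response,
            grading="not-applicable",
            descriptor={"note": "fewer than 2 classes of sufficient size"},
        )
    if family is None:
        family = _choose_family(data[response])
        indicator = "DQI-4006" if family == "logistic" else "DQI-4003"

    y = data[response].to_numpy(dtype=float)
    class_dummies = pd.get_dummies(data[class_var], prefix="__cls", dtype=float)
    X = pd.concat(
        [class_dummies.iloc[:, 1:], data[covariates].astype(float)], axis=1
    )
    X = sm.add_constant(X, has_constant="add")

    try:
        if family == "linear":
            fit = sm.OLS(y, X).fit()
        elif family == "logistic":
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        elif family == "poisson":
            fit = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        else:
            raise ValueError(f"unknown model family {family!r}")
    except Exception as exc:  # non-convergence must not kill the run
        return None, IndicatorResult(
            indicator_id=indicator, variable=response,
            grading="not-applicable",
            descriptor={"note": f"model failed: {exc}"},
        )

    cov_means = data[covariates].astype(float).mean() if covariates else None
    rows = []
    z = st.norm.ppf(1 - alpha / 2)
    for level in levels:
        x0 = {c: 0.0 for c in X.columns}
        x0["const"] = 1.0
        dummy = f"__cls_{level}"
        if dummy in X.columns:
            x0[dummy] = 1.0
        if covariates:
            for c in covariates:
                x0[c] = float(cov_means[c])
        xv = pd.DataFrame([x0])[X.columns]
        pred = fit.get_prediction(xv)
        if family == "linear":
            sf = pred.summary_frame(alpha=alpha)
            mean = float(sf["mean"].iloc[0])
            lo, hi = float(sf["mean_ci_lower"].iloc[0]), float(
                sf["mean_ci_upper"].iloc[0]
            )
        else:
            mean = float(pred.predicted_mean[0])
            se = float(pred.se[0]) if hasattr(pred, "se") else float(
                pred.se_mean[0]
            )
            lo, hi = mean - z * se, mean + z * se
        rows.append(
            {"class": level, "n": int(sizes[level]), "mean": mean,
             "ci_low": lo, "ci_high": hi}
        )
    per_class = pd.DataFrame(rows).set_index("class")
    overall = float(
        np.average(per_class["mean"], weights=per_class["n"])
    )
    flagged = [
        level
        for level, row in per_class.iterrows()
        if not (row["ci_low"] <= overall <= row["ci_high"])
    ]
    mres = MarginsResult(
        response=response, class_var=class_var, family=family,
        per_class=per_class, overall_mean=overall, flagged_classes=flagged,
    )
    result = IndicatorResult(
        indicator_id=indicator,
        variable=response,
        n_flagged=len(flagged),
        denominator=len(levels),
        descriptor=mres.to_dict(),
        grading="issue" if flagged else "ok",
    )
    return mres, result


def varcomp(
    study: pd.DataFrame,
    response: str,
    class_var: str,
    covariates: list[str] | None = None,
    icc_threshold: float = 0.05,
) -> IndicatorResult:
    """Variance share of a process variable (random-intercept ICC).

    Decomposes the response variance into between-class and
    within-class components with a random-intercept model; ICC =
    sigma2_between / (sigma2_between + sigma2_within).  Flagged when
    the ICC exceeds ``icc_threshold`` (default 0.05).
    """
    covariates = covariates or []
    cols = [response, class_var] + covariates
    data = study[cols].copy()
    data[response] = pd.to_numeric(data[response], errors="coerce")
    for c in covariates:
        data[c] = pd.to_numeric(data[c], errors="coerce")
    data = data.dropna()
    if data[class_var].nunique() < 2:
        return IndicatorResult(
            indicator_id="DQI-4010", variable=response,
            grading="not-applicable",
            descriptor={"note": "single class"},
        )
    exog = sm.add_constant(
        data[covariates].astype(float), has_constant="add"
    ) if covariates else pd.DataFrame(
        {"const": np.ones(len(data))}, index=data.index
    )
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        model = sm.MixedLM(
            data[response].to_numpy(dtype=float), exog,
            groups=data[class_var].astype(str),
        )
        fit = model.fit(reml=True)
    sigma2_b = float(fit.cov_re.iloc[0, 0])
    sigma2_w = float(fit.scale)
    icc = sigma2_b / (sigma2_b + sigma2_w) if (sigma2_b + sigma2_w) > 0 else 0.0
    icc = min(max(icc, 0.0), 1.0)
    flagged = icc > icc_threshold
    return IndicatorResult(
        indicator_id="DQI-4010",
        variable=response,
        n_flagged=int(flagged),
        denominator=1,
        descriptor={
            "icc": icc,
            "sigma2_between": sigma2_b,
            "sigma2_within": sigma2_w,
            "n_classes": int(data[class_var].nunique()),
            "threshold": icc_threshold,
        },
        grading="issue" if flagged else "ok",
    )


def loess_trend(
    study: pd.DataFrame,
    response: str,
    time_var: str,
    class_var: str | None = None,
    covariates: list[str] | None = None,
    span: float = 0.75,
    grid_points: int = 100,
    min_points: int = 30,
) -> dict:
    """LOESS-smoothed residual trend over time, per class (descriptor).

    Raw measurements are adjusted for covariates by a linear fit; the
    residuals are smoothed over time with a locally linear LOESS
    (span 0.75) and evaluated on a common time grid.  No
    machine-readable flag is produced — the payload is interpreted by a
    human.
    """
    covariates = covariates or []
    cols = [response, time_var] + ([class_var] if class_var else []) + covariates
    data = study[cols].copy()
    data[response] = pd.to_numeric(data[response], errors="coerce")
    for c in covariates:
        data[c] = pd.to_numeric(data[c], errors="coerce")
    data[time_var] = pd.to_datetime(data[time_var], errors="coerce", format="ISO8601")
    data = data.dropna(subset=[response, time_var] + covariates)
    if data[time_var].nunique() < 2:
        return {"kind": "loess", "note": "degenerate time axis", "series": {}}

    t = data[time_var].astype("int64").to_numpy(dtype=float)  # ns since epoch
    y = data[response].to_numpy(dtype=float)
    if covariates:
        X = sm.add_constant(data[covariates].astype(float), has_constant="add")
        resid = y - np.asarray(sm.OLS(y, X).fit().predict(X))
    else:
        resid = y - y.mean()

    grid = np.linspace(t.min(), t.max(), grid_points)
    series = {}
    groups = (
        data.groupby(data[class_var].astype(str)).groups.items()
        if class_var
        else [("all", data.index)]
    )
    pos = pd.Series(np.arange(len(data)), index=data.index)
    for level, idx in groups:
        sel = pos.loc[idx].to_numpy()
        if len(sel) < min_points:
            continue
        tg, yg = t[sel], resid[sel]
        g_grid = grid[(grid >= tg.min()) & (grid <= tg.max())]
        smoothed = lowess(yg, tg, frac=span, xvals=g_grid)
        series[str(level)] = {
            "time": pd.to_datetime(g_grid.astype("int64"))
            .strftime("%Y-%m-%dT%H:%M:%S")
            .tolist(),
            "smoothed_residual": np.asarray(smoothed, dtype=float).tolist(),
        }
    return {"kind": "loess", "response": response, "series": series}
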