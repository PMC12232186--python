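"""Analytical- and clinical-validity statistics.

Analytical validity: interrater agreement of score matrices (cases x
raters) via the intraclass correlation coefficient (two-way random-effects
ANOVA; all six Shrout-Fleiss forms with F-based 95% CIs), Kendall's
coefficient of concordance W with mid-rank tie correction for ordinal
grades, and the per-case coefficient of variation.  Reliability bands:
moderate 0.40-0.60, good 0.61-0.80, excellent > 0.80 (below 0.40: poor).

Clinical validity: Kaplan-Meier curves with the two-group log-rank test,
Cox proportional-hazards regression (Efron tie handling, via lifelines)
univariable or adjusted for sex, age, and stage (I as reference), and the
Grambsch-Therneau scaled-Schoenfeld test of the proportional-hazards
assumption (per covariate and global).  All tests are two-sided.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats as sps

from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test, proportional_hazard_test

ICC_FORMS = ("ICC1", "ICC2", "ICC3", "ICC1k", "ICC2k", "ICC3k")
STAGE_DUMMIES = {2: "stage_ii", 3: "stage_iii", 4: "stage_iv"}


@dataclass
class ConcordanceResult:
    """One agreement statistic with its context."""

    statistic: str
    value: float
    ci: tuple[float, float] | None
    n_cases: int
    n_raters: int
    reliability: str
    n_dropped_cases: int = 0
    extra: dict = dc_field(default_factory=dict)


def classify_reliability(value: float) -> str:
    """Reliability band of an agreement coefficient (ICC or W)."""
    if value > 1.0 + 1e-9:
        raise ValueError("agreement coefficients cannot exceed 1")
    if value > 0.80:
        return "excellent"
    if value > 0.60:
        return "good"
    if value >= 0.40:
        return "moderate"
    return "poor"


def log_transform(matrix: pd.DataFrame, offset: float = 1.0) -> pd.DataFrame:
    """Natural log of (score + offset); missing entries stay missing.

    The default offset 1 keeps zero scores (0% TILs) defined.
    """
    values = matrix.to_numpy(float)
    if np.nanmin(values) < 0:
        raise ValueError("log transform requires non-negative scores")
    return pd.DataFrame(
        np.log(values + offset), index=matrix.index, columns=matrix.columns
    )


def _complete_cases(matrix: pd.DataFrame) -> tuple[np.ndarray, int]:
    df = pd.DataFrame(matrix).astype(float)
    complete = df.dropna(axis=0)
    return complete.to_numpy(), len(df) - len(complete)


def _anova_mean_squares(x: np.ndarray):
    """Two-way crossed ANOVA mean squares of an n x k matrix."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    sst = float(((x - grand) ** 2).sum())
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    msw = (sst - ssr) / (n * (k - 1))
    return msr, msc, mse, msw


def _spearman_brown(x: float, k: int) -> float:
    if not np.isfinite(x):
        return x
    denom = 1.0 + (k - 1) * x
    return k * x / denom if denom != 0 else np.nan


def icc_forms_table(matrix: pd.DataFrame, ci: float = 0.95) -> pd.DataFrame:
    """All six Shrout-Fleiss ICC forms with F-based confidence intervals.

    Rows: ICC1/2/3 (single rater) and ICC1k/2k/3k (mean of k raters);
    ICC2 is two-way random effects, absolute agreement.
    """
    x, _ = _complete_cases(matrix)
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("ICC needs >= 2 complete cases and >= 2 raters")
    msr, msc, mse, msw = _anova_mean_squares(x)
    alpha = 1.0 - ci
    fppf = sps.f.ppf

    with np.errstate(divide="ignore", invalid="ignore"):
        icc1 = (msr - msw) / (msr + (k - 1) * msw) if msr + (k - 1) * msw > 0 else np.nan
        icc3 = (msr - mse) / (msr + (k - 1) * mse) if msr + (k - 1) * mse > 0 else np.nan
        d2 = msr + (k - 1) * mse + k * (msc - mse) / n
        icc2 = (msr - mse) / d2 if d2 > 0 else np.nan

        # ICC1 / ICC3 CIs from the usual F pivots
        def _f_ci(F, df1, df2):
            fl = F / fppf(1 - alpha / 2, df1, df2)
            fu = F * fppf(1 - alpha / 2, df2, df1)
            return (fl - 1) / (fl + k - 1), (fu - 1) / (fu + k - 1)

        if msw > 0:
            l1, u1 = _f_ci(msr / msw, n - 1, n * (k - 1))
        else:
            l1 = u1 = np.nan
        if mse > 0:
            l3, u3 = _f_ci(msr / mse, n - 1, (n - 1) * (k - 1))
        else:
            l3 = u3 = np.nan

        # ICC2 CI via the Satterthwaite approximation
        if np.isfinite(icc2) and icc2 < 1.0 and mse > 0:
            a = k * icc2 / (n * (1.0 - icc2))
            b = 1.0 + k * icc2 * (n - 1) / (n * (1.0 - icc2))
            v = (a * msc + b * mse) ** 2 / (
                (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            )
            f2u = fppf(1 - alpha / 2, n - 1, v)
            f2l = fppf(1 - alpha / 2, v, n - 1)
            l2 = (
                n * (msr - f2u * mse)
                / (f2u * (k * msc + (k * n - k - n) * mse) + n * msr)
            )
            u2 = (
                n * (f2l * msr - mse)
                / (k * msc + (k * n - k - n) * mse + n * f2l * msr)
            )
        else:
            l2 = u2 = np.nan

    rows = {
        "ICC1": (icc1, l1, u1),
        "ICC2": (icc2, l2, u2),
        "ICC3": (icc3, l3, u3),
        "ICC1k": tuple(_spearman_brown(v, k) for v in (icc1, l1, u1)),
        "ICC2k": tuple(_spearman_brown(v, k) for v in (icc2, l2, u2)),
        "ICC3k": tuple(_spearman_brown(v, k) for v in (icc3, l3, u3)),
    }
    return pd.DataFrame(
        rows, index=["value", "ci_lower", "ci_upper"]
    ).T.assign(n_cases=n, n_raters=k)


def icc(matrix: pd.DataFrame, form: str = "ICC2", ci: float = 0.95) -> ConcordanceResult:
    """Intraclass correlation of a cases x raters matrix.

    Case-wise deletion of incomplete cases; default form ICC(2,1) (two-way
    random effects, absolute agreement, single rater).  All six forms are
    reported in ``extra['forms']``.
    """
    if form not in ICC_FORMS:
        raise ValueError(f"unknown ICC form {form!r}; choose from {ICC_FORMS}")
    x, n_dropped = _complete_cases(matrix)
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("ICC needs >= 2 complete cases and >= 2 raters")
    table = icc_forms_table(pd.DataFrame(x), ci=ci)
    row = table.loc[form]
    value = float(row["value"])
    bounds = (float(row["ci_lower"]), float(row["ci_upper"]))
    ci_pair = bounds if all(np.isfinite(bounds)) else None
    return ConcordanceResult(
        statistic=form,
        value=value,
        ci=ci_pair,
        n_cases=int(row["n_cases"]),
        n_raters=int(row["n_raters"]),
        reliability=classify_reliability(value),
        n_dropped_cases=n_dropped,
        extra={"forms": table},
    )


def kendall_w(matrix: pd.DataFrame) -> ConcordanceResult:
    """Kendall's coefficient of concordance with mid-rank tie correction.

    W = 12 S / (m^2 (n^3 - n) - m * sum_j T_j), where S is the sum of
    squared deviations of the case rank-sums from their mean and
    T_j = sum over tie groups of rater j of (t^3 - t).  A chi-square
    approximation (m (n-1) W, df = n-1) provides the p-value.
    """
    x, n_dropped = _complete_cases(matrix)
    n, m = x.shape
    if n < 2 or m < 2:
        raise ValueError("Kendall W needs >= 2 complete cases and >= 2 raters")
    ranks = np.column_stack([sps.rankdata(x[:, j]) for j in range(m)])
    rank_sums = ranks.sum(axis=1)
    s = float(((rank_sums - rank_sums.mean()) ** 2).sum())
    ties = 0.0
    for j in range(m):
        _, counts = np.unique(x[:, j], return_counts=True)
        ties += float((counts**3 - counts).sum())
    denom = m**2 * (n**3 - n) - m * ties
    if denom <= 0:
        raise ValueError(
            "Kendall W is undefined: every rater assigned a constant grade"
        )
    w = 12.0 * s / denom
    chi2 = m * (n - 1) * w
    p = float(sps.chi2.sf(chi2, n - 1))
    return ConcordanceResult(
        statistic="kendall_w",
        value=float(w),
        ci=None,
        n_cases=n,
        n_raters=m,
        reliability=classify_reliability(float(w)),
        n_dropped_cases=n_dropped,
        extra={"chi2": chi2, "p": p, "df": n - 1},
    )


def coefficient_of_variation(
    matrix: pd.DataFrame,
) -> tuple[pd.Series, float]:
    """Per-case CV (sample sd / mean across raters) and its median.

    Cases with mean 0 (or fewer than two ratings) get a missing CV.
    """
    df = pd.DataFrame(matrix).astype(float)
    cvs = {}
    for case, row in df.iterrows():
        vals = row.dropna().to_numpy()
        if len(vals) < 2 or vals.mean() == 0:
            cvs[case] = np.nan
        else:
            cvs[case] = float(vals.std(ddof=1) / vals.mean())
    series = pd.Series(cvs, name="cv")
    return series, float(series.median())


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------


@dataclass
class KMResult:
    curves: dict[str, pd.DataFrame]
    chi2: float
    p_value: float
    groups: tuple
    n_events: int


def km_logrank(
    records: pd.DataFrame,
    group_col: str = "group",
    time_col: str = "time_months",
    event_col: str = "event",
) -> KMResult:
    """Kaplan-Meier curves per group plus the two-group log-rank test."""
    df = records.dropna(subset=[group_col, time_col, event_col])
    groups = sorted(df[group_col].unique(), key=str)
    if len(groups) != 2:
        raise ValueError(f"log-rank comparison needs exactly 2 groups; got {groups}")
    masks = [df[group_col] == g for g in groups]
    if any(m.sum() == 0 for m in masks):
        raise ValueError("each group must contain at least one subject")
    n_events = int(df[event_col].sum())
    if n_events < 1:
        raise ValueError("need at least one observed event")
    curves = {}
    for g, m in zip(groups, masks):
        kmf = KaplanMeierFitter()
        kmf.fit(df.loc[m, time_col], df.loc[m, event_col], label=str(g))
        curves[str(g)] = kmf.survival_function_
    res = logrank_test(
        df.loc[masks[0], time_col],
        df.loc[masks[1], time_col],
        event_observed_A=df.loc[masks[0], event_col],
        event_observed_B=df.loc[masks[1], event_col],
    )
    return KMResult(
        curves=curves,
        chi2=float(res.test_statistic),
        p_value=float(res.p_value),
        groups=tuple(groups),
        n_events=n_events,
    )


@dataclass
class CoxResult:
    summary: pd.DataFrame  # index covariate; hr, ci_lower, ci_upper, p, coef, se
    fitter: CoxPHFitter
    data: pd.DataFrame
    duration_col: str
    event_col: str

    @property
    def n_events(self) -> int:
        return int(self.data[self.event_col].sum())


def _design_matrix(records: pd.DataFrame, covariates) -> pd.DataFrame:
    X = pd.DataFrame(index=records.index)
    for cov in covariates:
        if cov == "stage":
            for level, name in STAGE_DUMMIES.items():
                X[name] = (records["stage"] == level).astype(float)
        else:
            if cov not in records.columns:
                raise ValueError(f"covariate {cov!r} not in the table")
            col = records[cov]
            if col.dtype == object:
                uniq = sorted(col.dropna().unique(), key=str)
                if len(uniq) != 2:
                    raise ValueError(
                        f"categorical covariate {cov!r} must be binary; got {uniq}"
                    )
                X[cov] = (col == uniq[1]).astype(float)
            else:
                X[cov] = col.astype(float)
    return X


def cox_fit(
    records: pd.DataFrame,
    covariates=("group",),
    duration_col: str = "time_months",
    event_col: str = "event",
) -> CoxResult:
    """Cox proportional-hazards fit (Efron tie handling via lifelines).

    For multivariable models pass e.g. ``("group", "male", "age", "stage")``;
    stage enters as three dummies against stage I.  Raises ValueError on
    degenerate inputs (no events, constant covariates) or non-convergence
    (including monotone likelihood from perfect separation).
    """
    X = _design_matrix(records, covariates)
    data = X.copy()
    data[duration_col] = records[duration_col].astype(float)
    data[event_col] = records[event_col].astype(int)
    data = data.dropna()
    if data[event_col].sum() < 1:
        raise ValueError("Cox fit needs at least one observed event")
    for col in X.columns:
        if data[col].nunique() <= 1:
            raise ValueError(f"covariate {col!r} is constant")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            # tight Newton precision so score-equation identities (Schoenfeld
            # residual sums) hold to ~1e-10
            cph.fit(
                data,
                duration_col=duration_col,
                event_col=event_col,
                fit_options={"precision": 1e-10},
            )
    except (ConvergenceError, np.linalg.LinAlgError) as err:
        raise ValueError(f"Cox fit did not converge: {err}") from err
    s = cph.summary
    summary = pd.DataFrame(
        {
            "hr": np.exp(s["coef"]),
            "ci_lower": np.exp(s["coef lower 95%"]),
            "ci_upper": np.exp(s["coef upper 95%"]),
            "p": s["p"],
            "coef": s["coef"],
            "se": s["se(coef)"],
        }
    )
    return CoxResult(
        summary=summary,
        fitter=cph,
        data=data,
        duration_col=duration_col,
        event_col=event_col,
    )


@dataclass
class SchoenfeldResult:
    per_covariate: pd.DataFrame  # index covariate; columns test_statistic, p
    global_chi2: float
    global_p: float
    transform: str
    residuals: pd.DataFrame


def schoenfeld_test(result: CoxResult, time_transform: str = "km") -> SchoenfeldResult:
    """Proportional-hazards check from scaled Schoenfeld residuals.

    Per-covariate score tests come from lifelines' implementation of the
    Grambsch-Therneau test; the global statistic is the joint version
    chi2 = d * U' V U / sum((g - gbar)^2) with U the transformed-time-
    weighted sum of (unscaled) Schoenfeld residuals, V the coefficient
    covariance, and d the event count (df = number of covariates).
    """
    d = result.n_events
    if d < 3:
        raise ValueError("Schoenfeld test needs >= 3 events")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pht = proportional_hazard_test(
            result.fitter, result.data, time_transform=time_transform
        )
    summary = pht.summary.copy()
    if isinstance(summary.index, pd.MultiIndex):
        summary.index = summary.index.get_level_values(0)
    per_cov = summary[["test_statistic", "p"]]

    resid = result.fitter.compute_residuals(result.data, "schoenfeld")
    cov_cols = [c for c in resid.columns]
    event_times = (
        result.data.loc[resid.index, result.duration_col]
        if resid.index.isin(result.data.index).all()
        else result.data.loc[result.data[result.event_col] == 1, result.duration_col]
    )
    order = np.argsort(event_times.to_numpy(), kind="stable")
    times = event_times.to_numpy()[order]
    r = resid.to_numpy()[order]

    kmf = KaplanMeierFitter().fit(
        result.data[result.duration_col], result.data[result.event_col]
    )
    surv = kmf.survival_function_at_times(times).to_numpy()
    g = 1.0 - surv
    gc = g - g.mean()
    denom = float((gc**2).sum())
    U = gc @ r
    V = result.fitter.variance_matrix_.loc[cov_cols, cov_cols].to_numpy()
    chi2 = float(d * U @ V @ U / denom)
    p_global = float(sps.chi2.sf(chi2, len(cov_cols)))
    return SchoenfeldResult(
        per_covariate=per_cov,
        global_chi2=chi2,
        global_p=p_global,
        transform=time_transform,
        residuals=resid,
    )


def median_followup(records: pd.DataFrame, time_col: str = "time_months") -> dict:
    """Direct median (IQR) of the observed follow-up times, labelled as such."""
    t = records[time_col].dropna()
    q1, med, q3 = np.percentile(t, [25, 50, 75])
    return {"median": float(med), "iqr": (float(q1), float(q3)), "method": "direct"}
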