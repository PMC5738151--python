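"""Measurement-reliability statistics for repeated posture ratings.

The toolkit mirrors a standard method-comparison workflow:

* ICC from the two-way random-effects model with absolute agreement —
  ICC(2,1) for a single measurement (default) or ICC(2,k) for the mean
  of k — with the F-based 95% confidence interval, computed from the
  two-way ANOVA mean squares;
* Cronbach's alpha from the same decomposition (1 - MSE/MSR);
* SEM, the standard error of a single measurement, SD * sqrt(1 - ICC),
  with SD the pooled between-subject SD of all ratings;
* a five-level qualitative scale for ICC values (poor <= 0.20, fair to
  0.40, moderate to 0.60, good to 0.80, very good to 1);
* paired method agreement (instrument A vs. B): ICC on the n x 2 matrix
  plus the bias and 95% limits of agreement of the differences;
* session-variability screening: per-parameter repeated-measures ANOVA
  across sessions with Tukey HSD post hoc tests and normality /
  homogeneity diagnostics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .landmarks import MeasurementRecord

ICC_SCALE = (
    (0.20, "poor"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "good"),
    (1.00, "very good"),
)


@dataclass(frozen=True)
class ReliabilityResult:
    icc: float
    ci_low: float
    ci_high: float
    sem: float
    alpha: float  # Cronbach's alpha
    category: str
    p_value: float  # two-way ANOVA rater/column-effect p
    form: str  # "single" (2,1) or "average" (2,k)


@dataclass(frozen=True)
class AgreementResult:
    """Method-agreement summary: ICC plus Bland-Altman quantities."""

    reliability: ReliabilityResult
    bias: float  # mean(y - x)
    loa_low: float  # bias - 1.96 SD(diff)
    loa_high: float  # bias + 1.96 SD(diff)


def _as_matrix(m) -> np.ndarray:
    arr = np.asarray(m, dtype=float)
    if arr.ndim != 2:
        raise ValueError("ratings must form a 2-D subjects x raters matrix")
    n, k = arr.shape
    if n < 2 or k < 2:
        raise ValueError(f"need at least 2 subjects and 2 raters, got {n} x {k}")
    if not np.isfinite(arr).all():
        raise ValueError("ratings matrix contains missing or non-finite cells")
    return arr


def two_way_mean_squares(m) -> tuple[float, float, float, int, int]:
    """(MSR, MSC, MSE, n, k): two-way ANOVA mean squares of an n x k grid.

    MSR: between-subject (rows), MSC: between-rater (columns), MSE:
    residual (interaction + error, the two are confounded with one
    rating per cell).
    """
    arr = _as_matrix(m)
    n, k = arr.shape
    grand = arr.mean()
    row_means = arr.mean(axis=1)
    col_means = arr.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((arr - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(max(mse, 0.0)), n, k


def icc_two_way(m, form: str = "single", alpha_level: float = 0.05) -> ReliabilityResult:
    """ICC(2,1) (or ICC(2,k) with ``form='average'``) with 95% CI.

    Two-way random effects, absolute agreement. The confidence interval
    is the standard F-based interval with Satterthwaite degrees of
    freedom. The reported p-value tests the rater (column) effect.
    """
    if form not in ("single", "average"):
        raise ValueError("form must be 'single' or 'average'")
    msr, msc, mse, n, k = two_way_mean_squares(m)
    if msr <= 0 and msc <= 0 and mse <= 0:
        raise ValueError("zero total variance: ICC undefined for a constant matrix")
    denom_single = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom_single == 0:
        raise ValueError("degenerate variance decomposition: ICC undefined")
    icc1 = (msr - mse) / denom_single

    # F-based CI for ICC(2,1) (Satterthwaite df on the denominator)
    if mse > 0:
        fj = msc / mse
        num_v = (
            (k - 1) * (n - 1) * (k * icc1 * fj + n * (1 + (k - 1) * icc1) - k * icc1) ** 2
        )
        den_v = (
            (n - 1) * k**2 * icc1**2 * fj**2
            + (n * (1 + (k - 1) * icc1) - k * icc1) ** 2
        )
        v = num_v / den_v if den_v > 0 else (n - 1) * (k - 1)
        f_u = stats.f.ppf(1 - alpha_level / 2, n - 1, v)
        f_l = stats.f.ppf(1 - alpha_level / 2, v, n - 1)
        low = n * (msr - f_u * mse) / (
            f_u * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        high = n * (f_l * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_l * msr
        )
    else:  # perfect agreement
        low = high = icc1
    low, high = min(low, icc1), max(high, icc1)

    if form == "average":
        icc = k * icc1 / (1 + (k - 1) * icc1)
        low = k * low / (1 + (k - 1) * low)
        high = k * high / (1 + (k - 1) * high)
    else:
        icc = icc1

    cronbach = 1.0 - mse / msr if msr > 0 else float("nan")
    sem = sem_from(m, max(min(icc1, 1.0), 0.0))
    if mse > 0:
        p_rater = float(stats.f.sf(msc / mse, k - 1, (n - 1) * (k - 1)))
    else:
        p_rater = float("nan")
    return ReliabilityResult(
        icc=float(icc),
        ci_low=float(min(low, high)),
        ci_high=float(max(low, high)),
        sem=float(sem),
        alpha=float(cronbach),
        category=classify_icc(icc),
        p_value=p_rater,
        form=form,
    )


def sem_from(m, icc: float) -> float:
    """SEM = SD * sqrt(1 - ICC), SD = pooled SD of all ratings."""
    if not 0.0 <= icc <= 1.0:
        raise ValueError(f"icc must lie in [0, 1], got {icc}")
    arr = _as_matrix(m)
    sd = float(np.std(arr, ddof=1))
    return sd * math.sqrt(1.0 - icc)


def classify_icc(value: float) -> str:
    """Five-level qualitative label for an ICC value (upper bounds inclusive)."""
    if value > 1.0:
        raise ValueError(f"ICC cannot exceed 1, got {value}")
    for upper, label in ICC_SCALE:
        if value <= upper:
            return label
    return "very good"  # unreachable


def method_agreement(x, y, form: str = "single") -> AgreementResult:
    """Agreement between two instruments measured on the same subjects.

    ICC(2,1) treats the two methods as interchangeable raters on an
    n x 2 grid; bias and 95% limits of agreement summarize the paired
    differences (y - x).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired subjects")
    diffs = y - x
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    rel = icc_two_way(np.column_stack([x, y]), form=form)
    return AgreementResult(
        reliability=rel,
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
    )


@dataclass(frozen=True)
class SessionVariabilityResult:
    parameter: str
    f_statistic: float
    p_value: float
    session_means: dict = field(default_factory=dict)
    posthoc: pd.DataFrame | None = None  # Tukey HSD pairwise table
    shapiro_p: float = float("nan")  # normality of residuals
    levene_p: float = float("nan")  # homogeneity across sessions


def session_variability(
    records: list[MeasurementRecord], alpha_level: float = 0.05
) -> dict[str, SessionVariabilityResult]:
    """Per-parameter repeated-measures ANOVA across sessions.

    Replicate ratings (e.g. several raters or repeats) are averaged per
    subject x session first; every subject must then appear in every
    session. Post hoc: Tukey HSD on the session groups. Shapiro-Wilk
    (residual normality) and Levene (variance homogeneity) diagnostics
    accompany each test.
    """
    from statsmodels.stats.anova import AnovaRM
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    df = pd.DataFrame(
        [(r.subject_id, r.session_id, r.parameter, r.value) for r in records],
        columns=["subject", "session", "parameter", "value"],
    )
    if df.empty:
        raise ValueError("no measurement records supplied")
    out: dict[str, SessionVariabilityResult] = {}
    for param, grp in df.groupby("parameter"):
        cell = grp.groupby(["subject", "session"], as_index=False)["value"].mean()
        wide = cell.pivot(index="subject", columns="session", values="value")
        if wide.isna().any().any():
            missing = [
                f"({s}, {c})"
                for s, row in wide.iterrows()
                for c, v in row.items()
                if pd.isna(v)
            ]
            raise ValueError(
                f"parameter {param}: incomplete subject x session grid; "
                f"missing cells: {', '.join(missing)}"
            )
        if wide.shape[1] < 2:
            raise ValueError(f"parameter {param}: need at least 2 sessions")
        arr0 = wide.to_numpy()
        ss_session = arr0.shape[0] * float(
            np.sum((arr0.mean(axis=0) - arr0.mean()) ** 2)
        )
        ss_total = float(np.sum((arr0 - arr0.mean()) ** 2))
        if ss_session <= 1e-12 * max(ss_total, 1.0):
            # no session effect at all (e.g. replicated sessions): F degenerates
            f_stat, p = 0.0, 1.0
        else:
            res = AnovaRM(
                cell, depvar="value", subject="subject", within=["session"]
            ).fit()
            f_stat = float(res.anova_table["F Value"].iloc[0])
            p = float(res.anova_table["Pr > F"].iloc[0])

        sessions = list(wide.columns)
        groups = [wide[c].to_numpy() for c in sessions]
        # residuals after removing subject and session means (the RM-ANOVA error)
        arr = wide.to_numpy()
        resid = arr - arr.mean(axis=1, keepdims=True) - arr.mean(axis=0) + arr.mean()
        if resid.size >= 3 and float(np.std(resid)) > 0:
            shapiro_p = float(stats.shapiro(resid.ravel()).pvalue)
        else:
            shapiro_p = float("nan")
        levene_p = float(stats.levene(*groups).pvalue)
        tukey = pairwise_tukeyhsd(
            cell["value"].to_numpy(), cell["session"].to_numpy(), alpha=alpha_level
        )
        posthoc = pd.DataFrame(
            tukey.summary().data[1:], columns=tukey.summary().data[0]
        )
        out[param] = SessionVariabilityResult(
            parameter=param,
            f_statistic=f_stat,
            p_value=p,
            session_means={c: float(wide[c].mean()) for c in sessions},
            posthoc=posthoc,
            shapiro_p=shapiro_p,
            levene_p=levene_p,
        )
    return out
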