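"""Reliability and agreement between web- and lab-based thresholds.

Four complementary views of test-retest agreement between measurement
settings, plus a planning tool:

* ``icc_2_1`` — intraclass correlation for single-rater absolute agreement
  under a two-way random-effects model (Shrout-Fleiss ICC(2,1), McGraw-Wong
  case 2A), with the standard F-based 95% confidence interval.
* ``bland_altman_log`` — Bland-Altman analysis on log thresholds.  Threshold
  variability scales with threshold magnitude, so differences of logs (ratios
  after antilog) are the natural scale: the antilogged mean difference is the
  mean lab/web ratio (1 = no systematic bias) and the antilogged limits of
  agreement bound ~95% of individual ratios.
* ``median_absolute_ratio`` — antilog of |log difference|, a scale-free
  typical measurement error, always >= 1.
* ``learning_check`` — first-session over second-session mean ratio across
  participants, near 1 when practice does not shift thresholds.
* ``sample_size_icc`` — Walter-type F-based minimum number of subjects to
  distinguish an acceptable from an expected reliability.

Natural logs are used throughout; every reported quantity is a base-invariant
ratio.  The ratio convention is lab/web: values above 1 mean larger
thresholds in the lab session.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ICCResult",
    "BlandAltmanResult",
    "AgreementResult",
    "icc_2_1",
    "bland_altman_log",
    "median_absolute_ratio",
    "learning_check",
    "sample_size_icc",
    "agreement_analysis",
    "paired_thresholds",
]


@dataclass
class ICCResult:
    """ICC(2,1) point estimate, 95% CI and the underlying mean squares."""

    icc: float
    ci_low: float
    ci_high: float
    msr: float
    msc: float
    mse: float
    n: int
    k: int


def icc_2_1(matrix: np.ndarray, alpha: float = 0.05) -> ICCResult:
    """Single-measurement, absolute-agreement ICC under a two-way random model.

    ``matrix`` is (n subjects x k raters/sessions) with no missing cells.
    The estimate comes from the row (MSR), column (MSC) and error (MSE) mean
    squares; the CI is the standard F-based interval.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("matrix must be 2-D (subjects x sessions)")
    n, k = X.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 sessions")
    if not np.all(np.isfinite(X)):
        raise ValueError("missing or non-finite cells are not allowed")

    grand = X.mean()
    row_m = X.mean(axis=1)
    col_m = X.mean(axis=0)
    ssr = k * np.sum((row_m - grand) ** 2)
    ssc = n * np.sum((col_m - grand) ** 2)
    sse = np.sum((X - row_m[:, None] - col_m[None, :] + grand) ** 2)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

    # F-based CI (Shrout & Fleiss 1979; McGraw & Wong 1996, case 2A)
    a = k * icc / (n * (1.0 - icc)) if icc < 1 else math.inf
    b = 1.0 + k * icc * (n - 1.0) / (n * (1.0 - icc)) if icc < 1 else math.inf
    if math.isinf(a) or mse == 0:
        return ICCResult(float(icc), float(icc), float(icc), msr, msc, mse, n, k)
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1.0) + (b * mse) ** 2 / ((n - 1.0) * (k - 1.0))
    )
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lo = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    hi = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
    return ICCResult(float(icc), float(lo), float(hi), float(msr), float(msc), float(mse), n, k)


@dataclass
class BlandAltmanResult:
    """Log-scale Bland-Altman summary on the ratio scale (lab / web)."""

    mean_ratio: float
    loa_low: float
    loa_high: float
    mean_log_diff: float
    sd_log_diff: float
    shapiro_w: float
    shapiro_p: float
    n_pairs: int
    mean_log: np.ndarray = field(repr=False, default=None)  # per-pair plot x
    log_diff: np.ndarray = field(repr=False, default=None)  # per-pair plot y


def bland_altman_log(web, lab) -> BlandAltmanResult:
    """Bland-Altman agreement analysis on natural-log thresholds.

    ``d_i = log(lab_i) - log(web_i)``; the mean ratio is ``exp(mean d)`` and
    the limits of agreement are ``exp(mean d +/- 1.96 sd(d))``.  Ratios above
    1 indicate larger thresholds in the lab session.  Shapiro-Wilk checks the
    normality of the log differences; a violation warns but still reports.
    """
    web = np.asarray(web, dtype=float)
    lab = np.asarray(lab, dtype=float)
    if web.shape != lab.shape or web.ndim != 1:
        raise ValueError("web and lab must be equal-length 1-D arrays")
    if len(web) < 3:
        raise ValueError("need at least 3 pairs")
    bad = np.flatnonzero((web <= 0) | (lab <= 0))
    if bad.size:
        raise ValueError(f"non-positive threshold in pair(s) {bad.tolist()}")
    d = np.log(lab) - np.log(web)
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    w, p = stats.shapiro(d)
    if p < 0.05:
        warnings.warn(
            f"log differences deviate from normality (Shapiro-Wilk p={p:.3g}); "
            "limits of agreement may be unreliable",
            stacklevel=2,
        )
    return BlandAltmanResult(
        mean_ratio=math.exp(mean_d),
        loa_low=math.exp(mean_d - 1.96 * sd_d),
        loa_high=math.exp(mean_d + 1.96 * sd_d),
        mean_log_diff=mean_d,
        sd_log_diff=sd_d,
        shapiro_w=float(w),
        shapiro_p=float(p),
        n_pairs=len(d),
        mean_log=(np.log(lab) + np.log(web)) / 2.0,
        log_diff=d,
    )


def median_absolute_ratio(web, lab) -> tuple[float, float]:
    """Median and IQR of the antilogged absolute log differences.

    ``r_i = exp(|log lab_i - log web_i|) >= 1`` is a direction-free typical
    measurement error between the two settings.
    """
    web = np.asarray(web, dtype=float)
    lab = np.asarray(lab, dtype=float)
    if np.any(web <= 0) or np.any(lab <= 0):
        raise ValueError("thresholds must be strictly positive")
    r = np.exp(np.abs(np.log(lab) - np.log(web)))
    q25, q50, q75 = np.percentile(r, [25, 50, 75])
    return float(q50), float(q75 - q25)


def learning_check(table: pd.DataFrame, dv: str = "threshold") -> dict:
    """Mean first/second-session threshold ratio across participant-conditions.

    The antilog of the mean of ``log(threshold_first) - log(threshold_second)``
    over all paired conditions.  Values above 1 mean smaller (better)
    thresholds in the second session, consistent with learning; near 1 means
    no order effect.
    """
    for col in ("participant_id", "session_order", "task", "orientation", dv):
        if col not in table.columns:
            raise ValueError(f"table missing column {col!r}")
    if table["session_order"].isna().any():
        raise ValueError("missing session_order metadata")
    wide = table.pivot_table(
        index=["participant_id", "task", "orientation"],
        columns="session_order",
        values=dv,
    )
    if 1 not in wide.columns or 2 not in wide.columns or wide.isna().any().any():
        raise ValueError("every participant-condition needs both session orders")
    d = np.log(wide[1].to_numpy()) - np.log(wide[2].to_numpy())
    return {
        "ratio_first_over_second": float(np.exp(d.mean())),
        "n_pairs": int(len(d)),
        "convention": "ratio > 1: second-session thresholds smaller (improvement)",
    }


def sample_size_icc(
    icc_null: float,
    icc_alt: float,
    k_ratings: int,
    alpha: float = 0.05,
    power: float = 0.80,
    two_sided: bool = False,
) -> int:
    """Minimum subjects for a reliability study via the Walter F-based formula.

    Tests H0: ICC = ``icc_null`` against the expected ``icc_alt`` with ``k``
    ratings per subject.  The default one-sided alpha matches the published
    reliability sample-size tables this planner reproduces.
    """
    if not (0 <= icc_null < icc_alt < 1):
        raise ValueError("need 0 <= icc_null < icc_alt < 1")
    if k_ratings < 2:
        raise ValueError("k_ratings must be >= 2")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    z_a = stats.norm.ppf(1 - (alpha / 2 if two_sided else alpha))
    z_b = stats.norm.ppf(power)
    k = k_ratings
    C = (1 + k * icc_alt / (1 - icc_alt)) / (1 + k * icc_null / (1 - icc_null))
    n = 1 + 2 * (z_a + z_b) ** 2 * k / (math.log(C) ** 2 * (k - 1))
    return math.ceil(n)


@dataclass
class AgreementResult:
    """Bundle of all agreement metrics for one task (or pooled)."""

    label: str
    icc: ICCResult
    bland_altman: BlandAltmanResult
    median_abs_ratio: float
    iqr_abs_ratio: float
    n_pairs: int


def paired_thresholds(
    table: pd.DataFrame,
    task: str | None = None,
    sessions: tuple[str, str] = ("web", "lab"),
    dv: str = "threshold",
) -> tuple[np.ndarray, np.ndarray]:
    """Extract aligned (web, lab) threshold arrays, one pair per
    participant x orientation (x task when ``task`` is None)."""
    sub = table if task is None else table[table["task"] == task]
    if sub.empty:
        raise ValueError(f"no rows for task {task!r}")
    wide = sub.pivot_table(
        index=["participant_id", "task", "orientation"], columns="session", values=dv
    )
    for s in sessions:
        if s not in wide.columns:
            raise ValueError(f"missing session {s!r} in table")
    if wide[list(sessions)].isna().any().any():
        missing = wide[wide[list(sessions)].isna().any(axis=1)].index.tolist()
        raise ValueError(f"missing session cells for {missing[:10]}")
    return wide[sessions[0]].to_numpy(), wide[sessions[1]].to_numpy()


def agreement_analysis(
    table: pd.DataFrame,
    by_task: bool = True,
    sessions: tuple[str, str] = ("web", "lab"),
    log_icc: bool = False,
) -> dict[str, AgreementResult]:
    """Full web-vs-lab agreement analysis on a two-session threshold table.

    Pairs are pooled across the four orientation conditions within each task
    (or across everything with ``by_task=False``).  The ICC is computed on
    raw thresholds by default (``log_icc=True`` uses log thresholds); the
    Bland-Altman and ratio metrics are always log-scale.
    """
    tasks = sorted(table["task"].unique()) if by_task else [None]
    out: dict[str, AgreementResult] = {}
    for task in tasks:
        web, lab = paired_thresholds(table, task=task, sessions=sessions)
        mat = np.column_stack([web, lab])
        icc = icc_2_1(np.log(mat) if log_icc else mat)
        ba = bland_altman_log(web, lab)
        med, iqr = median_absolute_ratio(web, lab)
        label = task if task is not None else "all"
        out[label] = AgreementResult(
            label=label,
            icc=icc,
            bland_altman=ba,
            median_abs_ratio=med,
            iqr_abs_ratio=iqr,
            n_pairs=len(web),
        )
    return out
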