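"""Group-level inference on threshold tables.

Implements the classical two-way fully within-subjects (repeated-measures)
ANOVA for the 2 (task) x 4 (orientation) threshold design, with Mauchly's
sphericity test and Greenhouse-Geisser corrected degrees of freedom per
within-subject effect, partial eta squared effect sizes, and
Bonferroni-corrected paired comparisons with Cohen's d.

The decomposition is the textbook one for a balanced complete design: subject,
task, orientation and task x orientation strata, each within effect tested
against its own subject-interaction error term.  Sphericity statistics are
computed from the covariance matrix of orthonormally contrasted cell scores.
The reported p-value uses Greenhouse-Geisser corrected df when Mauchly's test
rejects at 0.05, and uncorrected df otherwise; both are always retained.

Two Cohen's d conventions are reported for paired contrasts: ``d_av`` (mean
difference over the average of the two condition SDs) and ``d_z`` (mean
difference over the SD of the paired differences).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "THRESHOLD_TABLE_COLUMNS",
    "validate_threshold_table",
    "EffectResult",
    "AnovaResult",
    "rm_anova",
    "rm_anova_cells",
    "mauchly_test",
    "greenhouse_geisser_epsilon",
    "pairwise_bonferroni",
]

THRESHOLD_TABLE_COLUMNS = [
    "participant_id",
    "session",
    "session_order",
    "task",
    "orientation",
    "threshold",
    "se_threshold",
]


def validate_threshold_table(table: pd.DataFrame, require_positive: bool = True) -> pd.DataFrame:
    """Check a long-format threshold table: required columns, unique keys."""
    missing = [c for c in THRESHOLD_TABLE_COLUMNS[:6] if c not in table.columns]
    if missing:
        raise ValueError(f"threshold table missing columns: {missing}")
    keys = table[["participant_id", "session", "task", "orientation"]]
    if keys.duplicated().any():
        dup = keys[keys.duplicated()].iloc[0].tolist()
        raise ValueError(f"duplicate threshold row for key {dup}")
    if require_positive and (table["threshold"] <= 0).any():
        raise ValueError("thresholds must be strictly positive")
    return table


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k matrix of orthonormal contrasts orthogonal to the mean."""
    helmert = np.zeros((k - 1, k))
    for i in range(k - 1):
        helmert[i, : i + 1] = 1.0
        helmert[i, i + 1] = -(i + 1.0)
        helmert[i] /= np.linalg.norm(helmert[i])
    return helmert


def greenhouse_geisser_epsilon(scores: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from an n x k matrix of within-subject scores.

    Computed from the covariance of orthonormally contrasted scores; bounded
    in [1/(k-1), 1].
    """
    scores = np.asarray(scores, dtype=float)
    n, k = scores.shape
    if k < 2:
        raise ValueError("need at least 2 within-subject levels")
    if k == 2:
        return 1.0
    C = _orthonormal_contrasts(k)
    T = C @ np.cov(scores, rowvar=False, ddof=1) @ C.T
    p = k - 1
    eps = np.trace(T) ** 2 / (p * np.trace(T @ T))
    return float(min(1.0, max(1.0 / p, eps)))


def mauchly_test(scores: np.ndarray) -> tuple[float, float, int, float]:
    """Mauchly's sphericity test on an n x k within-subject score matrix.

    Returns ``(W, chi2, df, p)``.  With k = 2 sphericity holds trivially
    (W = 1, p = 1).  A singular contrasted covariance (n <= k - 1) is flagged
    by NaN statistics; callers should then fall back to the epsilon lower
    bound 1/(k-1).
    """
    scores = np.asarray(scores, dtype=float)
    n, k = scores.shape
    if k < 2:
        raise ValueError("need at least 2 levels")
    if k == 2:
        return 1.0, 0.0, 0, 1.0
    p = k - 1
    df = p * (p + 1) // 2 - 1
    if n - 1 < p:
        return math.nan, math.nan, df, math.nan
    C = _orthonormal_contrasts(k)
    T = C @ np.cov(scores, rowvar=False, ddof=1) @ C.T
    det = np.linalg.det(T)
    mean_eig = np.trace(T) / p
    if det <= 0 or mean_eig <= 0:
        return math.nan, math.nan, df, math.nan
    W = float(det / mean_eig**p)
    f = 1.0 - (2.0 * p**2 + p + 2.0) / (6.0 * p * (n - 1.0))
    chi2 = -(n - 1.0) * f * math.log(W)
    pval = float(stats.chi2.sf(chi2, df))
    return W, float(chi2), df, pval


@dataclass
class EffectResult:
    """One within-subject effect of the repeated-measures ANOVA."""

    name: str
    ss: float
    df: int
    ss_error: float
    df_error: int
    F: float
    p_uncorrected: float
    gg_epsilon: float
    df_corrected: float
    df_error_corrected: float
    p_gg: float
    mauchly_w: float
    mauchly_chi2: float
    mauchly_df: int
    mauchly_p: float
    sphericity_assumed: bool
    partial_eta_sq: float

    @property
    def p(self) -> float:
        """Reported p: Greenhouse-Geisser corrected when sphericity is violated."""
        return self.p_uncorrected if self.sphericity_assumed else self.p_gg


@dataclass
class AnovaResult:
    """Full two-way repeated-measures ANOVA decomposition."""

    effects: dict[str, EffectResult]
    ss_subjects: float
    ss_total: float
    n_subjects: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.effects.values():
            rows.append(
                {
                    "effect": e.name,
                    "SS": e.ss,
                    "df": e.df,
                    "SS_error": e.ss_error,
                    "df_error": e.df_error,
                    "F": e.F,
                    "p_uncorrected": e.p_uncorrected,
                    "GG_epsilon": e.gg_epsilon,
                    "df_GG": e.df_corrected,
                    "df_error_GG": e.df_error_corrected,
                    "p_GG": e.p_gg,
                    "p": e.p,
                    "Mauchly_W": e.mauchly_w,
                    "Mauchly_chi2": e.mauchly_chi2,
                    "Mauchly_df": e.mauchly_df,
                    "Mauchly_p": e.mauchly_p,
                    "partial_eta_sq": e.partial_eta_sq,
                }
            )
        return pd.DataFrame(rows)


def rm_anova_cells(
    Y: np.ndarray,
    factor_names: tuple[str, str] = ("task", "orientation"),
    alpha_sphericity: float = 0.05,
) -> AnovaResult:
    """Two-way within-subjects ANOVA on an (n, A, B) cell array.

    ``Y[i, a, b]`` is subject i's score in level a of the first factor and
    level b of the second.  Exact balanced-design sums of squares; each within
    effect is tested against its subject-interaction error stratum.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 3:
        raise ValueError("Y must be (subjects, levels_A, levels_B)")
    n, A, B = Y.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    grand = Y.mean()
    m_i = Y.mean(axis=(1, 2))
    m_a = Y.mean(axis=(0, 2))
    m_b = Y.mean(axis=(0, 1))
    m_ia = Y.mean(axis=2)
    m_ib = Y.mean(axis=1)
    m_ab = Y.mean(axis=0)

    ss_subj = A * B * np.sum((m_i - grand) ** 2)
    ss_a = n * B * np.sum((m_a - grand) ** 2)
    ss_b = n * A * np.sum((m_b - grand) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_as = B * np.sum((m_ia - m_i[:, None] - m_a[None, :] + grand) ** 2)
    ss_bs = A * np.sum((m_ib - m_i[:, None] - m_b[None, :] + grand) ** 2)
    ss_total = np.sum((Y - grand) ** 2)
    ss_res = ss_total - (ss_subj + ss_a + ss_b + ss_ab + ss_as + ss_bs)

    specs = [
        (factor_names[0], ss_a, A - 1, ss_as, (A - 1) * (n - 1), Y.mean(axis=2)),
        (factor_names[1], ss_b, B - 1, ss_bs, (B - 1) * (n - 1), Y.mean(axis=1)),
    ]
    # interaction: sphericity assessed on the doubly contrasted cell scores
    CA = _orthonormal_contrasts(A) if A > 1 else None
    CB = _orthonormal_contrasts(B) if B > 1 else None
    inter_scores = (np.kron(CA, CB) @ Y.reshape(n, A * B).T).T if A > 1 and B > 1 else None
    specs.append(
        (
            f"{factor_names[0]} x {factor_names[1]}",
            ss_ab,
            (A - 1) * (B - 1),
            ss_res,
            (A - 1) * (B - 1) * (n - 1),
            None,
        )
    )

    effects: dict[str, EffectResult] = {}
    for name, ss, df, ss_err, df_err, scores in specs:
        F = (ss / df) / (ss_err / df_err)
        p_unc = float(stats.f.sf(F, df, df_err))
        if scores is not None:
            k = scores.shape[1]
            eps = greenhouse_geisser_epsilon(scores)
            W, chi2, mdf, mp = mauchly_test(scores)
        else:
            # interaction stratum: epsilon from contrasted covariance directly
            p_eff = df
            S = np.cov(inter_scores, rowvar=False, ddof=1)
            S = np.atleast_2d(S)
            eps = float(min(1.0, max(1.0 / p_eff, np.trace(S) ** 2 / (p_eff * np.trace(S @ S)))))
            mdf = p_eff * (p_eff + 1) // 2 - 1
            if n - 1 < p_eff:
                W = chi2 = mp = math.nan
            else:
                det = np.linalg.det(S)
                mean_eig = np.trace(S) / p_eff
                if det <= 0 or mean_eig <= 0 or p_eff == 1:
                    W, chi2, mp = (1.0, 0.0, 1.0) if p_eff == 1 else (math.nan,) * 3
                else:
                    W = float(det / mean_eig**p_eff)
                    fcorr = 1.0 - (2.0 * p_eff**2 + p_eff + 2.0) / (6.0 * p_eff * (n - 1.0))
                    chi2 = -(n - 1.0) * fcorr * math.log(W)
                    mp = float(stats.chi2.sf(chi2, mdf))
        df_c = eps * df
        df_err_c = eps * df_err
        p_gg = float(stats.f.sf(F, df_c, df_err_c))
        spherical = not (np.isfinite(mp) and mp < alpha_sphericity) if df > 1 else True
        effects[name] = EffectResult(
            name=name,
            ss=float(ss),
            df=df,
            ss_error=float(ss_err),
            df_error=df_err,
            F=float(F),
            p_uncorrected=p_unc,
            gg_epsilon=float(eps),
            df_corrected=float(df_c),
            df_error_corrected=float(df_err_c),
            p_gg=p_gg,
            mauchly_w=float(W),
            mauchly_chi2=float(chi2),
            mauchly_df=int(mdf),
            mauchly_p=float(mp),
            sphericity_assumed=spherical,
            partial_eta_sq=float(ss / (ss + ss_err)),
        )
    return AnovaResult(
        effects=effects,
        ss_subjects=float(ss_subj),
        ss_total=float(ss_total),
        n_subjects=n,
    )


def rm_anova(
    table: pd.DataFrame,
    session: str | None = None,
    dv: str = "threshold",
    alpha_sphericity: float = 0.05,
) -> AnovaResult:
    """Two-way (task x orientation) repeated-measures ANOVA on a threshold table.

    ``session`` filters to one session (e.g. ``"web"``); the design must be
    complete and balanced after filtering — every participant needs all
    task x orientation cells.
    """
    validate_threshold_table(table, require_positive=False)
    if session is not None:
        table = table[table["session"] == session]
    if table.empty:
        raise ValueError("no rows after session filter")
    wide = table.pivot_table(
        index="participant_id", columns=["task", "orientation"], values=dv
    )
    if wide.isna().any().any():
        missing = [
            (pid, col)
            for pid in wide.index
            for col in wide.columns[wide.loc[pid].isna()]
        ]
        raise ValueError(f"unbalanced design; missing cells: {missing[:10]}")
    tasks = sorted(wide.columns.get_level_values(0).unique())
    orients = sorted(wide.columns.get_level_values(1).unique())
    Y = np.empty((wide.shape[0], len(tasks), len(orients)))
    for a, t in enumerate(tasks):
        for b, o in enumerate(orients):
            Y[:, a, b] = wide[(t, o)].to_numpy()
    return rm_anova_cells(Y, alpha_sphericity=alpha_sphericity)


def _cell_values(table: pd.DataFrame, cell, dv: str) -> pd.Series:
    """Per-participant mean threshold for a cell selector.

    ``cell`` is ``(task, orientation)`` where orientation may be a number, the
    class label ``"cardinal"``/``"oblique"`` (averaged over its orientations),
    or None (all orientations of the task).
    """
    task, orient = cell
    sub = table[table["task"] == task]
    if orient is None:
        pass
    elif isinstance(orient, str):
        is_card = sub["orientation"].astype(float) % 90.0 == 0.0
        sub = sub[is_card if orient == "cardinal" else ~is_card]
    else:
        sub = sub[sub["orientation"].astype(float) == float(orient)]
    if sub.empty:
        raise ValueError(f"no rows match cell {cell!r}")
    return sub.groupby("participant_id")[dv].mean()


def pairwise_bonferroni(
    table: pd.DataFrame,
    comparisons: Sequence[tuple],
    session: str | None = None,
    dv: str = "threshold",
    n_comparisons: int | None = None,
) -> pd.DataFrame:
    """Bonferroni-corrected paired t tests between condition cells.

    Each comparison is a pair of cell selectors (see ``_cell_values``).  Raw p
    values are multiplied by the number of comparisons (capped at 1).  Both
    ``d_av`` and ``d_z`` Cohen's d conventions are reported; zero-variance
    differences leave them NaN with ``degenerate=True``.
    """
    validate_threshold_table(table, require_positive=False)
    if session is not None:
        table = table[table["session"] == session]
    m = n_comparisons if n_comparisons is not None else len(comparisons)
    rows = []
    for cell1, cell2 in comparisons:
        v1 = _cell_values(table, cell1, dv)
        v2 = _cell_values(table, cell2, dv)
        common = v1.index.intersection(v2.index)
        if len(common) < 2:
            raise ValueError(f"fewer than 2 paired observations for {cell1} vs {cell2}")
        x, y = v1[common].to_numpy(), v2[common].to_numpy()
        diff = x - y
        n = len(diff)
        sd_diff = diff.std(ddof=1)
        degenerate = sd_diff == 0
        if degenerate and diff.mean() == 0:
            t, p_raw = 0.0, 1.0
        else:
            t, p_raw = stats.ttest_rel(x, y)
        d_z = math.nan if degenerate else float(diff.mean() / sd_diff)
        sd_av = (x.std(ddof=1) + y.std(ddof=1)) / 2.0
        d_av = float(diff.mean() / sd_av) if sd_av > 0 else (0.0 if diff.mean() == 0 else math.nan)
        if degenerate and diff.mean() == 0:
            d_z = 0.0
        rows.append(
            {
                "cell_1": str(cell1),
                "cell_2": str(cell2),
                "mean_1": float(x.mean()),
                "mean_2": float(y.mean()),
                "t": float(t),
                "df": n - 1,
                "p_raw": float(p_raw),
                "p_adjusted": float(min(1.0, m * p_raw)),
                "d_av": d_av,
                "d_z": d_z,
                "n": n,
                "degenerate": bool(degenerate),
            }
        )
    return pd.DataFrame(rows)
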