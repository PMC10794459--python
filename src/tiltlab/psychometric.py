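"""Psychometric-function collation, logistic fitting and threshold extraction.

Proportion correct in a 2AFC task rises from 50% (chance) towards 100% with
the orientation offset between standard and comparison.  Per condition the
trial-level data are collated into counts per offset level and fitted with a
two-parameter logistic scaled to that range,

    y(x) = 50 + 50 / (1 + exp((x - a) / b)),

by unweighted least squares on percent correct.  ``a`` is the curve midpoint
and is taken as the threshold: the offset producing exactly 75% correct.  As
printed above the curve is increasing only for b < 0; the fitter works with a
positive slope scale ``beta`` in ``exp(-(x - a)/beta)`` internally and stores
``b = -beta`` so that reported values match the printed form while
``slope_magnitude`` gives |b|.

The exclusion rule mirrors standard practice for this design: a participant
is excluded when any of their conditions fails to reach 75% correct at the
largest offsets or yields no in-range converged threshold.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .task_engine import TrialRecord

__all__ = [
    "ConditionKey",
    "PsychometricData",
    "PsychometricFit",
    "logistic_percent",
    "collate",
    "fit_logistic",
    "apply_exclusion",
    "ExclusionReport",
    "thresholds_to_table",
]


class ConditionKey(NamedTuple):
    participant_id: str
    session: str
    task: str
    orientation: float


@dataclass
class PsychometricData:
    """Counts per offset level for one condition (runs and signs pooled)."""

    key: ConditionKey
    offsets: np.ndarray  # ascending offset magnitudes, degrees
    n_trials: np.ndarray
    n_correct: np.ndarray
    session_order: int = 1

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.n_trials = np.asarray(self.n_trials, dtype=int)
        self.n_correct = np.asarray(self.n_correct, dtype=int)
        if not (self.offsets.shape == self.n_trials.shape == self.n_correct.shape):
            raise ValueError("offsets, n_trials and n_correct must align")
        if np.any(np.diff(self.offsets) <= 0):
            raise ValueError("offsets must be strictly ascending")
        if np.any(self.n_correct > self.n_trials) or np.any(self.n_trials < 0):
            raise ValueError("need 0 <= n_correct <= n_trials")

    @property
    def percent_correct(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return 100.0 * self.n_correct / self.n_trials


@dataclass
class PsychometricFit:
    """Least-squares logistic fit: threshold ``a``, slope ``b``, diagnostics.

    ``b`` carries the fitted sign of the printed logistic form (negative for
    an increasing curve); ``slope_magnitude`` is |b|.  ``reached_threshold``
    is True when the condition peaked at >= 75% correct and ``a`` lies inside
    the tested offset range.
    """

    a: float
    b: float
    se_threshold: float
    rss: float
    converged: bool
    reached_threshold: bool
    key: ConditionKey | None = None
    session_order: int = 1

    @property
    def slope_magnitude(self) -> float:
        return abs(self.b)

    def predict(self, x) -> np.ndarray:
        return logistic_percent(np.asarray(x, dtype=float), self.a, abs(self.b))


def logistic_percent(x, a, beta):
    """Increasing 2AFC logistic in percent: 50 at -inf, 75 at ``a``, 100 at +inf."""
    z = np.clip((np.asarray(x, dtype=float) - a) / beta, -500.0, 500.0)
    return 50.0 + 50.0 / (1.0 + np.exp(-z))


def collate(trials: Iterable[TrialRecord]) -> dict[ConditionKey, PsychometricData]:
    """Aggregate completed trials into per-condition psychometric data.

    Runs and offset signs (clockwise/anticlockwise comparisons) are pooled;
    one row per distinct offset magnitude, in ascending order.
    """
    trials = list(trials)
    if not trials:
        raise ValueError("no trials to collate")
    counts: dict[ConditionKey, dict[float, list[int]]] = defaultdict(lambda: defaultdict(lambda: [0, 0]))
    orders: dict[ConditionKey, int] = {}
    for t in trials:
        if t.correct is None:
            raise ValueError(f"trial {t.trial_index} of run {t.run_index} has no response")
        key = ConditionKey(t.participant_id, t.session, t.task, t.standard_orientation_deg)
        cell = counts[key][float(t.offset_deg)]
        cell[0] += 1
        cell[1] += int(t.correct)
        orders[key] = t.session_order
    out: dict[ConditionKey, PsychometricData] = {}
    for key, by_offset in counts.items():
        offs = np.array(sorted(by_offset))
        n = np.array([by_offset[o][0] for o in offs])
        c = np.array([by_offset[o][1] for o in offs])
        out[key] = PsychometricData(key, offs, n, c, session_order=orders[key])
    return out


def _initial_guess(offsets: np.ndarray, percent: np.ndarray) -> tuple[float, float]:
    """Deterministic, scale-aware start: a0 near the 75%-point, beta0 = range/4."""
    i = int(np.argmin(np.abs(percent - 75.0)))
    a0 = offsets[i]
    # refine by linear interpolation if a neighbour brackets 75%
    for j in (i - 1, i + 1):
        if 0 <= j < len(offsets):
            p0, p1 = percent[min(i, j)], percent[max(i, j)]
            if (p0 - 75.0) * (p1 - 75.0) < 0 and p1 != p0:
                x0, x1 = offsets[min(i, j)], offsets[max(i, j)]
                a0 = x0 + (75.0 - p0) * (x1 - x0) / (p1 - p0)
                break
    beta0 = max((offsets[-1] - offsets[0]) / 4.0, 1e-3)
    return float(a0), float(beta0)


def fit_logistic(
    data: PsychometricData,
    se_method: str = "asymptotic",
    n_boot: int = 200,
    seed=None,
) -> PsychometricFit:
    """Fit the 2AFC logistic to percent correct by unweighted least squares.

    The threshold standard error comes from the asymptotic (Jacobian-based)
    covariance of the least-squares estimate, or from a parametric bootstrap
    resampling trials within each level when ``se_method="bootstrap"``.
    Optimiser failure is reported via ``converged=False``, never an exception.
    """
    if len(data.offsets) < 3:
        raise ValueError("need at least 3 offset levels to fit")
    percent = data.percent_correct
    if not np.all(np.isfinite(percent)):
        raise ValueError("non-finite proportions (empty level?)")

    a, beta, se, rss, ok = _fit_core(data.offsets, percent)
    if ok and se_method == "bootstrap":
        rng = np.random.default_rng(seed)
        boots = []
        for _ in range(n_boot):
            c = rng.binomial(data.n_trials, np.clip(data.n_correct / data.n_trials, 0, 1))
            pb = 100.0 * c / data.n_trials
            ab, _, _, _, okb = _fit_core(data.offsets, pb)
            if okb:
                boots.append(ab)
        se = float(np.std(boots, ddof=1)) if len(boots) > 1 else float("nan")

    reached = bool(
        percent.max() >= 75.0 and ok and data.offsets[0] <= a <= data.offsets[-1]
    )
    return PsychometricFit(
        a=float(a),
        b=-float(beta),
        se_threshold=float(se),
        rss=float(rss),
        converged=bool(ok),
        reached_threshold=reached,
        key=data.key,
        session_order=data.session_order,
    )


def _fit_core(offsets: np.ndarray, percent: np.ndarray):
    a0, beta0 = _initial_guess(offsets, percent)
    try:
        popt, pcov = curve_fit(
            logistic_percent,
            offsets,
            percent,
            p0=(a0, beta0),
            bounds=((-np.inf, 1e-9), (np.inf, np.inf)),
            maxfev=20000,
        )
    except (RuntimeError, ValueError):
        return math.nan, math.nan, math.nan, math.nan, False
    a, beta = popt
    resid = percent - logistic_percent(offsets, a, beta)
    rss = float(np.dot(resid, resid))
    with np.errstate(invalid="ignore"):
        se = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else math.nan
    return float(a), float(beta), se, rss, True


@dataclass
class ExclusionReport:
    """Per-participant inclusion decision with named failing conditions."""

    included: dict[str, bool] = field(default_factory=dict)
    failures: dict[str, list[str]] = field(default_factory=dict)

    @property
    def included_participants(self) -> list[str]:
        return sorted(p for p, ok in self.included.items() if ok)

    @property
    def excluded_participants(self) -> list[str]:
        return sorted(p for p, ok in self.included.items() if not ok)


def apply_exclusion(
    fits: Mapping[ConditionKey, PsychometricFit] | Sequence[PsychometricFit],
    data: Mapping[ConditionKey, PsychometricData] | None = None,
    required_tasks: Sequence[str] = ("temporal", "spatial"),
    required_orientations: Sequence[float] = (0.0, 90.0, -45.0, 45.0),
) -> ExclusionReport:
    """Exclude participants who fail to reach threshold in any condition.

    A condition passes when its maximum observed proportion correct is at
    least 75% and its fit converged with the threshold inside the tested
    offset range (both folded into ``fit.reached_threshold``).  Each session a
    participant took part in must contain all task x orientation conditions;
    missing conditions count as failures.
    """
    if not isinstance(fits, Mapping):
        fits = {f.key: f for f in fits}
    by_participant: dict[str, set[str]] = defaultdict(set)
    for key in fits:
        by_participant[key.participant_id].add(key.session)

    report = ExclusionReport()
    for pid, sessions in sorted(by_participant.items()):
        fails: list[str] = []
        for session in sorted(sessions):
            for task in required_tasks:
                for orient in required_orientations:
                    key = ConditionKey(pid, session, task, float(orient))
                    label = f"{session}/{task}/{orient:g}deg"
                    fit = fits.get(key)
                    if fit is None:
                        fails.append(label + " (missing)")
                    elif not fit.reached_threshold:
                        fails.append(label)
        report.included[pid] = not fails
        if fails:
            report.failures[pid] = fails
    return report


def thresholds_to_table(
    fits: Mapping[ConditionKey, PsychometricFit] | Sequence[PsychometricFit],
    include_only: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Build a long-format threshold table (one row per fitted condition)."""
    if isinstance(fits, Mapping):
        fits = list(fits.values())
    rows = []
    for f in fits:
        if f.key is None:
            raise ValueError("fit lacks a condition key")
        if include_only is not None and f.key.participant_id not in include_only:
            continue
        rows.append(
            {
                "participant_id": f.key.participant_id,
                "session": f.key.session,
                "session_order": f.session_order,
                "task": f.key.task,
                "orientation": f.key.orientation,
                "threshold": f.a,
                "se_threshold": f.se_threshold,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "session",
            "session_order",
            "task",
            "orientation",
            "threshold",
            "se_threshold",
        ],
    )
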