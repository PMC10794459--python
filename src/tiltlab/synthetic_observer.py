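"""Synthetic observers with a controllable web/lab agreement structure.

Generates trial-level data with the statistical structure the downstream
analyses assume.  Each participant owns one true logistic psychometric
function per (session, task, orientation) cell.  True thresholds are
log-normal:

    log a(i, s, task, orient) = mu(task, class) + S_i + E_{i,s} + eps

with independent zero-mean Gaussian components: ``S_i`` a subject effect
shared across sessions (SD ``sigma_subject``), ``E_{i,s}`` a session-specific
effect (SD ``sigma_session``) and ``eps`` condition-level residual noise (SD
``sigma_resid``).  The implied test-retest intraclass correlation of log
thresholds is

    ICC = sigma_subject^2 / (sigma_subject^2 + sigma_session^2 + sigma_resid^2),

so the agreement structure is a single dial.  Slopes scale with the threshold
(constant Weber-like log-slope); there is no lapse parameter — the logistic
runs from 50% to 100%, matching the two-parameter model used for fitting.

Default cell means give cardinal thresholds several-fold smaller than oblique
ones and a temporal-task advantage over the spatial task; web and lab are
exchangeable (no systematic bias) unless ``session_bias_factor`` or
``learning_factor`` says otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .task_engine import (
    DesignConfig,
    POSITIONS,
    TrialRecord,
    build_trial_schedule,
    orientation_class,
)

__all__ = [
    "ObserverPopulationConfig",
    "ObserverModel",
    "draw_population",
    "p_correct",
    "simulate_responses",
    "simulate_study",
    "sample_log_threshold_matrix",
]

#: default mean thresholds (degrees) per (task, orientation class)
DEFAULT_MEAN_THRESHOLDS = {
    ("temporal", "cardinal"): 1.4,
    ("temporal", "oblique"): 8.0,
    ("spatial", "cardinal"): 2.2,
    ("spatial", "oblique"): 12.0,
}


@dataclass(frozen=True)
class ObserverPopulationConfig:
    """Population parameters of the synthetic observer model.

    ``mean_threshold`` holds per-(task, class) mean thresholds in degrees
    (geometric means; the generative model is log-normal).  Variance
    components are SDs on the natural-log scale.  ``session_bias_factor``
    multiplies lab-session thresholds (1 = exchangeable sessions);
    ``learning_factor`` multiplies each participant's second-session
    thresholds (< 1 simulates improvement with practice).
    """

    mean_threshold: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_MEAN_THRESHOLDS)
    )
    slope_factor: float = 0.30  # b = slope_factor * a
    sigma_subject: float = 0.45
    sigma_session: float = 0.10
    sigma_resid: float = 0.12
    n_participants: int = 18
    session_bias_factor: float = 1.0
    learning_factor: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("sigma_subject", "sigma_session", "sigma_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.slope_factor <= 0:
            raise ValueError("slope_factor must be > 0")
        if self.session_bias_factor <= 0 or self.learning_factor <= 0:
            raise ValueError("multiplicative session factors must be > 0")

    @property
    def true_icc(self) -> float:
        """Implied intraclass correlation of log thresholds between sessions."""
        tot = self.sigma_subject**2 + self.sigma_session**2 + self.sigma_resid**2
        if tot == 0:
            return 1.0
        return self.sigma_subject**2 / tot

    @classmethod
    def with_true_icc(
        cls, icc: float, sigma_total: float = 0.48, **kwargs
    ) -> "ObserverPopulationConfig":
        """Config whose variance components yield a target true ICC.

        The total log-threshold SD is held at ``sigma_total``; the
        non-subject variance is split equally between the session effect and
        the residual.
        """
        if not (0 <= icc <= 1):
            raise ValueError("icc must lie in [0, 1]")
        s2 = sigma_total**2
        sig_s = math.sqrt(icc * s2)
        rest = (1 - icc) * s2 / 2
        return cls(
            sigma_subject=sig_s,
            sigma_session=math.sqrt(rest),
            sigma_resid=math.sqrt(rest),
            **kwargs,
        )


@dataclass
class ObserverModel:
    """One participant's true psychometric parameters per condition.

    ``cells`` maps (session, task, orientation) to the true (a, b) of the
    logistic, both in degrees, with a > 0 and b its positive slope scale.
    """

    participant_id: str
    session_order: Mapping[str, int]  # session -> 1 or 2
    cells: Mapping[tuple[str, str, float], tuple[float, float]]

    def params(self, session: str, task: str, orientation: float) -> tuple[float, float]:
        key = (session, task, float(orientation))
        if key not in self.cells:
            raise KeyError(f"observer {self.participant_id} has no condition {key}")
        return self.cells[key]


def draw_population(
    popcfg: ObserverPopulationConfig,
    sessions: Sequence[str] = ("web", "lab"),
    orientations: Sequence[float] = (0.0, 90.0, -45.0, 45.0),
    tasks: Sequence[str] = ("temporal", "spatial"),
    rng=None,
) -> list[ObserverModel]:
    """Draw a population of synthetic observers.

    Session order is counterbalanced: even-indexed participants do the first
    listed session first, odd-indexed the reverse.  With a single session the
    order is trivially 1.
    """
    rng = np.random.default_rng(popcfg.seed if rng is None else rng)
    observers = []
    for i in range(popcfg.n_participants):
        pid = f"p{i:03d}"
        subj = rng.normal(0.0, popcfg.sigma_subject)
        if len(sessions) >= 2 and i % 2 == 1:
            order = {s: len(sessions) - j for j, s in enumerate(sessions)}
        else:
            order = {s: j + 1 for j, s in enumerate(sessions)}
        cells = {}
        for s in sessions:
            sess_eff = rng.normal(0.0, popcfg.sigma_session)
            for task in tasks:
                for orient in orientations:
                    mu = math.log(popcfg.mean_threshold[(task, orientation_class(orient))])
                    log_a = mu + subj + sess_eff + rng.normal(0.0, popcfg.sigma_resid)
                    if s == "lab":
                        log_a += math.log(popcfg.session_bias_factor)
                    if order[s] == 2:
                        log_a += math.log(popcfg.learning_factor)
                    a = math.exp(log_a)
                    cells[(s, task, float(orient))] = (a, popcfg.slope_factor * a)
        observers.append(ObserverModel(pid, order, cells))
    return observers


def p_correct(
    model: ObserverModel,
    task: str,
    orientation: float,
    offset_deg,
    session: str = "web",
):
    """Probability of a correct 2AFC response at a given orientation offset.

    Follows the increasing two-parameter logistic from 0.5 to 1.0; equals
    exactly 0.75 at the true threshold.
    """
    offset = np.asarray(offset_deg, dtype=float)
    if np.any(offset < 0):
        raise ValueError("offset_deg must be >= 0")
    a, b = model.params(session, task, orientation)
    z = np.clip((offset - a) / b, -500.0, 500.0)
    return 0.5 + 0.5 / (1.0 + np.exp(-z))


def simulate_responses(
    models: Iterable[ObserverModel] | ObserverModel,
    schedule: Sequence[TrialRecord],
    seed=None,
) -> list[TrialRecord]:
    """Fill in responses on a trial schedule by Bernoulli draws from the model.

    The response is the standard's position when correct and the other
    alternative when wrong; reproducible under ``seed``.
    """
    if isinstance(models, ObserverModel):
        models = [models]
    by_id = {m.participant_id: m for m in models}
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    p = np.empty(len(schedule))
    for j, t in enumerate(schedule):
        m = by_id.get(t.participant_id)
        if m is None:
            raise KeyError(f"no observer model for participant {t.participant_id!r}")
        p[j] = p_correct(m, t.task, t.standard_orientation_deg, t.offset_deg, session=t.session)
    correct = rng.random(len(schedule)) < p

    out = []
    for t, c in zip(schedule, correct):
        alt = POSITIONS[t.task]
        resp = t.standard_position if c else alt[1 - alt.index(t.standard_position)]
        out.append(
            TrialRecord(
                **{
                    **t.__dict__,
                    "response": resp,
                    "correct": bool(c),
                }
            )
        )
    return out


def simulate_study(
    popcfg: ObserverPopulationConfig,
    design: DesignConfig | None = None,
    sessions: Sequence[str] = ("web", "lab"),
    seed=None,
) -> tuple[list[TrialRecord], list[ObserverModel]]:
    """Run the full synthetic experiment: schedule, respond, return trials.

    Every participant completes every session x task x orientation condition
    at the design's runs-per-condition (350 trials per condition under the
    defaults).
    """
    design = design or DesignConfig()
    rng = np.random.default_rng(seed if seed is not None else popcfg.seed)
    observers = draw_population(popcfg, sessions=sessions, rng=rng)
    trials: list[TrialRecord] = []
    for obs in observers:
        for session in sessions:
            for task in design.tasks:
                for orient in design.standard_orientations:
                    stubs = build_trial_schedule(
                        design,
                        task,
                        orient,
                        seed=rng,
                        participant_id=obs.participant_id,
                        session=session,
                        session_order=obs.session_order[session],
                    )
                    trials.extend(simulate_responses(obs, stubs, seed=rng))
    return trials, observers


def sample_log_threshold_matrix(
    popcfg: ObserverPopulationConfig,
    n_subjects: int,
    n_sessions: int = 2,
    rng=None,
) -> np.ndarray:
    """Vectorised draw of an (n_subjects, n_sessions) log-threshold matrix.

    Samples the variance-component model for a single condition cell (mean
    zero); useful for studying the agreement statistics at large n without
    simulating trials.
    """
    rng = np.random.default_rng(rng)
    subj = rng.normal(0.0, popcfg.sigma_subject, size=(n_subjects, 1))
    sess = rng.normal(0.0, popcfg.sigma_session, size=(n_subjects, n_sessions))
    resid = rng.normal(0.0, popcfg.sigma_resid, size=(n_subjects, n_sessions))
    return subj + sess + resid
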