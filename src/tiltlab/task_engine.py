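"""Experiment design, trial scheduling and stimulus geometry.

Encodes a two-alternative forced-choice (2AFC) orientation-identification
experiment run with the method of constant stimuli.  A *standard* grating at a
fixed orientation (0, 90, -45 or +45 degrees) is paired on every trial with a
*comparison* rotated away from it by one of seven fixed offsets; the observer
reports which interval (temporal task) or which location (spatial task) held
the standard.  Cardinal standards (0/90 deg) use a fine offset set, oblique
standards (+/-45 deg) a coarse one, reflecting the oblique effect.

Display standardisation converts between degrees of visual angle and pixels
using the exact geometry ``2 * d * tan(theta / 2)`` so that stimulus size and
spatial frequency are comparable across displays.  Stimuli are Gabor patterns:
sinusoidal luminance gratings in sine phase at the centre of a truncated
Gaussian envelope.  Timing fields (durations, inter-stimulus interval) are
carried as metadata only; no real-time presentation is simulated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict, replace
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "DesignConfig",
    "DisplayGeometry",
    "TrialRecord",
    "CARDINAL_ORIENTATIONS",
    "OBLIQUE_ORIENTATIONS",
    "TASKS",
    "POSITIONS",
    "orientation_class",
    "build_trial_schedule",
    "pixels_per_degree",
    "render_gabor",
]

TASKS = ("temporal", "spatial")
CARDINAL_ORIENTATIONS = (0.0, 90.0)
OBLIQUE_ORIENTATIONS = (-45.0, 45.0)

#: response alternatives per task: interval order vs. screen side
POSITIONS = {"temporal": ("first", "second"), "spatial": ("left", "right")}


def orientation_class(orientation_deg: float) -> str:
    """Classify a standard orientation as ``"cardinal"`` (0/90) or ``"oblique"``."""
    return "cardinal" if float(orientation_deg) % 90.0 == 0.0 else "oblique"


@dataclass(frozen=True)
class DesignConfig:
    """All design constants of the orientation-identification experiment.

    Defaults reproduce the reference design: seven fine offsets for cardinal
    standards, seven coarse offsets for obliques, ten repeats of each offset
    level per run, five runs per condition (350 trials), 1 cyc/deg Gabors in a
    Gaussian envelope (space constant 1.33 deg, truncated at 4 deg) at 40%
    contrast, 300 ms presentations, 500 ms ISI on the temporal task, 8 deg
    eccentricity on the spatial task, 60 cm viewing distance.

    Orientations are in degrees anticlockwise from horizontal = 0 deg; the
    +/-45 labels are symmetric under the alternative vertical-referenced
    convention, recorded in ``orientation_reference``.
    """

    tasks: tuple[str, ...] = TASKS
    standard_orientations: tuple[float, ...] = (0.0, 90.0, -45.0, 45.0)
    cardinal_offsets: tuple[float, ...] = (0.71, 1.43, 2.14, 2.86, 3.57, 4.29, 5.00)
    oblique_offsets: tuple[float, ...] = (3.57, 7.14, 10.70, 14.29, 17.80, 21.42, 25.00)
    repeats_per_level: int = 10
    runs_per_condition: int = 5
    grating_sf: float = 1.0  # cycles / degree
    envelope_space_constant: float = 1.33  # degrees (Gaussian sigma)
    envelope_truncation: float = 4.0  # degrees (hard radius)
    contrast_fraction: float = 0.40
    stimulus_duration_ms: float = 300.0
    isi_ms: float = 500.0  # temporal task inter-stimulus interval
    eccentricity_deg: float = 8.0  # spatial task centre offset
    viewing_distance_cm: float = 60.0
    response_keys: dict = field(
        default_factory=lambda: {"first": "f", "second": "j", "left": "f", "right": "j"}
    )
    orientation_reference: str = "anticlockwise-from-horizontal"

    def __post_init__(self) -> None:
        for name in ("cardinal_offsets", "oblique_offsets"):
            offs = tuple(float(v) for v in getattr(self, name))
            object.__setattr__(self, name, offs)
            if len(offs) != 7:
                raise ValueError(f"{name} must have exactly 7 levels, got {len(offs)}")
            if any(v <= 0 for v in offs):
                raise ValueError(f"{name} entries must be strictly positive")
            if any(b <= a for a, b in zip(offs, offs[1:])):
                raise ValueError(f"{name} must be strictly increasing")
        if self.repeats_per_level < 1 or self.runs_per_condition < 1:
            raise ValueError("repeats_per_level and runs_per_condition must be >= 1")
        if not (0 < self.contrast_fraction <= 1):
            raise ValueError("contrast_fraction must lie in (0, 1]")

    def offsets_for(self, orientation_deg: float) -> tuple[float, ...]:
        """Offset set used with a given standard orientation."""
        if orientation_class(orientation_deg) == "cardinal":
            return self.cardinal_offsets
        return self.oblique_offsets

    def trials_per_run(self) -> int:
        return self.repeats_per_level * 7

    # -- serialisation ----------------------------------------------------
    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "DesignConfig":
        """Load a config; an empty file reproduces the default design."""
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("tasks", "standard_orientations", "cardinal_offsets", "oblique_offsets"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass(frozen=True)
class DisplayGeometry:
    """Physical display parameters needed to convert visual angle to pixels."""

    screen_width_cm: float
    horizontal_resolution_px: float
    viewing_distance_cm: float = 60.0

    def __post_init__(self) -> None:
        for name in ("screen_width_cm", "horizontal_resolution_px", "viewing_distance_cm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class TrialRecord:
    """One 2AFC trial: condition identifiers, stimulus randomisation, response.

    ``offset_sign`` is +1 when the comparison is rotated clockwise from the
    standard and -1 anticlockwise; ``standard_position`` is the interval
    (temporal) or side (spatial) holding the standard.  ``response`` and
    ``correct`` are None on a schedule stub.
    """

    participant_id: str
    session: str  # "web" | "lab"
    session_order: int  # 1 = this session was done first
    task: str
    standard_orientation_deg: float
    offset_deg: float
    offset_sign: int
    standard_position: str
    run_index: int
    trial_index: int
    response: str | None = None
    correct: bool | None = None

    def condition_key(self) -> tuple[str, str, str, float]:
        return (self.participant_id, self.session, self.task, self.standard_orientation_deg)


def build_trial_schedule(
    config: DesignConfig,
    task: str,
    standard_orientation: float,
    n_runs: int | None = None,
    seed=None,
    *,
    participant_id: str = "p0",
    session: str = "web",
    session_order: int = 1,
) -> list[TrialRecord]:
    """Build a constant-stimuli trial schedule for one condition.

    Each run presents every offset level exactly ``repeats_per_level`` times
    in a seeded random order; the offset sign and the standard's position are
    drawn independently per trial.  Responses are left empty.

    Parameters
    ----------
    seed : int or numpy.random.Generator
        Source of randomness; the same seed yields an identical schedule.
    """
    if task not in config.tasks:
        raise ValueError(f"unknown task {task!r}; allowed: {config.tasks}")
    if standard_orientation not in config.standard_orientations:
        raise ValueError(
            f"unknown standard orientation {standard_orientation!r}; "
            f"allowed: {config.standard_orientations}"
        )
    n_runs = config.runs_per_condition if n_runs is None else int(n_runs)
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    offsets = np.asarray(config.offsets_for(standard_orientation))
    positions = POSITIONS[task]
    trials: list[TrialRecord] = []
    for run in range(n_runs):
        levels = np.repeat(offsets, config.repeats_per_level)
        order = rng.permutation(levels.size)
        signs = rng.choice((-1, 1), size=levels.size)
        pos_idx = rng.integers(0, 2, size=levels.size)
        for i, (lvl, sgn, pi) in enumerate(zip(levels[order], signs, pos_idx)):
            trials.append(
                TrialRecord(
                    participant_id=participant_id,
                    session=session,
                    session_order=session_order,
                    task=task,
                    standard_orientation_deg=float(standard_orientation),
                    offset_deg=float(lvl),
                    offset_sign=int(sgn),
                    standard_position=positions[pi],
                    run_index=run,
                    trial_index=i,
                )
            )
    return trials


def pixels_per_degree(geometry: DisplayGeometry) -> float:
    """Pixels subtended by one degree of visual angle at the screen centre.

    Uses the exact chord formula ``2 * d * tan(0.5 deg)`` for the physical
    extent of one degree rather than the small-angle approximation.
    """
    cm_per_degree = 2.0 * geometry.viewing_distance_cm * math.tan(math.radians(0.5))
    return geometry.horizontal_resolution_px / geometry.screen_width_cm * cm_per_degree


def render_gabor(
    geometry: DisplayGeometry,
    orientation_deg: float,
    polarity: int = 1,
    config: DesignConfig | None = None,
    phase_deg: float = 0.0,
) -> np.ndarray:
    """Render a Gabor patch as a luminance matrix with values in [0, 1].

    The grating is in sine phase at the centre of its Gaussian envelope (the
    centre pixel is exactly mid-grey, 0.5) and the envelope is hard-truncated
    to zero beyond the truncation radius.  ``polarity`` +/-1 selects positive
    or negative sine; flipping polarity is equivalent to a 180 deg phase shift.
    """
    config = config or DesignConfig()
    if polarity not in (-1, 1):
        raise ValueError("polarity must be +1 or -1")
    sigma = config.envelope_space_constant
    trunc = config.envelope_truncation
    if trunc < sigma:
        warnings.warn(
            f"truncation radius {trunc} deg is smaller than the envelope "
            f"space constant {sigma} deg; the Gaussian is clipped hard",
            stacklevel=2,
        )
    ppd = pixels_per_degree(geometry)
    half = int(round(trunc * ppd))
    # odd-sized grid so a pixel sits exactly at the envelope centre
    coords = np.arange(-half, half + 1) / ppd
    x, y = np.meshgrid(coords, coords)
    theta = math.radians(orientation_deg)
    # coordinate perpendicular to the grating stripes
    u = x * math.sin(theta) + y * math.cos(theta)
    carrier = np.sin(2.0 * math.pi * config.grating_sf * u + math.radians(phase_deg))
    envelope = np.exp(-(x**2 + y**2) / (2.0 * sigma**2))
    envelope[x**2 + y**2 > trunc**2] = 0.0
    return 0.5 * (1.0 + config.contrast_fraction * polarity * carrier * envelope)
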