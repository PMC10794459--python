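"""CSV interchange, report writing and run manifests.

Trials travel as plain UTF-8 CSV with a fixed header and '.' decimal
separator, one row per 2AFC trial, matching the long format experiment
software exports.  Unknown columns are preserved as opaque metadata on read.
Reports bundle a threshold table, a structured text summary of the group and
agreement analyses, and optional figures.  Every command-line invocation
writes a manifest capturing the configuration, seed and file lists so a rerun
reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .agreement import AgreementResult
from .group_inference import AnovaResult, THRESHOLD_TABLE_COLUMNS, validate_threshold_table
from .task_engine import TrialRecord

__all__ = [
    "TRIAL_COLUMNS",
    "write_trials",
    "read_trials",
    "trials_to_frame",
    "write_threshold_table",
    "read_threshold_table",
    "write_report",
    "RunManifest",
]

TRIAL_COLUMNS = [
    "participant_id",
    "session",
    "session_order",
    "task",
    "standard_orientation_deg",
    "offset_deg",
    "offset_sign",
    "standard_position",
    "run_index",
    "trial_index",
    "response",
    "correct",
]

_REQUIRED = TRIAL_COLUMNS[:10]


def trials_to_frame(trials: Iterable[TrialRecord]) -> pd.DataFrame:
    rows = [dataclasses.asdict(t) for t in trials]
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def write_trials(trials: Iterable[TrialRecord], path) -> None:
    """Write trials as UTF-8 CSV with the fixed schema header."""
    df = trials_to_frame(trials)
    df.to_csv(path, index=False, encoding="utf-8")


def read_trials(path) -> list[TrialRecord]:
    """Read and validate a trial CSV; errors name the column or row at fault."""
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"trial file {path} missing required column(s): {missing}")
    records: list[TrialRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        try:
            d = row._asdict()
            resp = d.get("response")
            corr = d.get("correct")
            records.append(
                TrialRecord(
                    participant_id=str(d["participant_id"]),
                    session=str(d["session"]),
                    session_order=int(d["session_order"]),
                    task=str(d["task"]),
                    standard_orientation_deg=float(d["standard_orientation_deg"]),
                    offset_deg=float(d["offset_deg"]),
                    offset_sign=int(d["offset_sign"]),
                    standard_position=str(d["standard_position"]),
                    run_index=int(d["run_index"]),
                    trial_index=int(d["trial_index"]),
                    response=None if pd.isna(resp) else str(resp),
                    correct=None if corr is None or (isinstance(corr, float) and np.isnan(corr)) else bool(corr),
                )
            )
        except (TypeError, ValueError, KeyError) as exc:
            raise ValueError(f"malformed trial row at line {i} of {path}: {exc}") from exc
        t = records[-1]
        if t.offset_deg <= 0:
            raise ValueError(f"non-positive offset_deg at line {i} of {path}")
        if t.offset_sign not in (-1, 1):
            raise ValueError(f"offset_sign must be +/-1 at line {i} of {path}")
    return records


def write_threshold_table(table: pd.DataFrame, path) -> None:
    validate_threshold_table(table, require_positive=False)
    table.to_csv(path, index=False, encoding="utf-8")


def read_threshold_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in THRESHOLD_TABLE_COLUMNS[:6] if c not in df.columns]
    if missing:
        raise ValueError(f"threshold table {path} missing column(s): {missing}")
    return df


def _fmt_agreement(label: str, res: AgreementResult) -> str:
    icc = res.icc
    ba = res.bland_altman
    return "\n".join(
        [
            f"[{label}]",
            f"  n_pairs             = {res.n_pairs}",
            f"  ICC(2,1)            = {icc.icc:.6g}  (95% CI {icc.ci_low:.6g}, {icc.ci_high:.6g})",
            f"  mean ratio lab/web  = {ba.mean_ratio:.6g}",
            f"  limits of agreement = {ba.loa_low:.6g} .. {ba.loa_high:.6g}",
            f"  median abs ratio    = {res.median_abs_ratio:.6g}  (IQR {res.iqr_abs_ratio:.6g})",
            f"  Shapiro-Wilk (log d)= W {ba.shapiro_w:.4f}, p {ba.shapiro_p:.4g}",
        ]
    )


def write_report(
    outdir,
    thresholds: pd.DataFrame | None = None,
    anova: AnovaResult | None = None,
    agreement: Mapping[str, AgreementResult] | None = None,
    learning: Mapping | None = None,
    plots: bool = False,
) -> list[Path]:
    """Write a deterministic report bundle into ``outdir``.

    Always writes ``thresholds.csv`` (headers only when empty) and
    ``summary.txt``; full-precision numbers go to ``summary.json``.  With
    ``plots=True`` adds boxplots of thresholds and a Bland-Altman figure.
    Returns the list of files written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    thr = thresholds if thresholds is not None else pd.DataFrame(columns=THRESHOLD_TABLE_COLUMNS)
    p = outdir / "thresholds.csv"
    thr.to_csv(p, index=False, encoding="utf-8")
    written.append(p)

    lines: list[str] = ["# Analysis summary", ""]
    blob: dict = {}
    if anova is not None:
        lines.append("## Repeated-measures ANOVA (task x orientation)")
        lines.append(anova.to_frame().round(4).to_string(index=False))
        lines.append("")
        blob["anova"] = json.loads(anova.to_frame().to_json(orient="records"))
    if agreement is not None:
        lines.append("## Web vs lab agreement (ratios are lab/web)")
        for label, res in agreement.items():
            lines.append(_fmt_agreement(label, res))
        lines.append("")
        blob["agreement"] = {
            label: {
                "icc": res.icc.icc,
                "icc_ci": [res.icc.ci_low, res.icc.ci_high],
                "mean_ratio": res.bland_altman.mean_ratio,
                "loa": [res.bland_altman.loa_low, res.bland_altman.loa_high],
                "median_absolute_ratio": res.median_abs_ratio,
                "iqr_absolute_ratio": res.iqr_abs_ratio,
                "shapiro_w": res.bland_altman.shapiro_w,
                "shapiro_p": res.bland_altman.shapiro_p,
                "n_pairs": res.n_pairs,
            }
            for label, res in agreement.items()
        }
    if learning is not None:
        lines.append("## Learning check (first/second session)")
        lines.append(f"  mean ratio = {learning['ratio_first_over_second']:.6g} "
                     f"(n = {learning['n_pairs']}; {learning['convention']})")
        lines.append("")
        blob["learning"] = dict(learning)

    p = outdir / "summary.txt"
    p.write_text("\n".join(lines), encoding="utf-8")
    written.append(p)
    p = outdir / "summary.json"
    p.write_text(json.dumps(blob, indent=2, sort_keys=True), encoding="utf-8")
    written.append(p)

    if plots and thresholds is not None and not thr.empty:
        written.extend(_write_plots(outdir, thr, agreement))
    return written


def _write_plots(outdir: Path, thr: pd.DataFrame, agreement) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    fig, axes = plt.subplots(1, thr["session"].nunique(), figsize=(10, 4), squeeze=False)
    for ax, (session, sub) in zip(axes.flat, thr.groupby("session")):
        labels, groups = [], []
        for (task, orient), g in sub.groupby(["task", "orientation"]):
            labels.append(f"{task[:4]}\n{orient:g}")
            groups.append(g["threshold"].to_numpy())
        ax.boxplot(groups, tick_labels=labels)
        ax.set_title(f"{session} thresholds")
        ax.set_ylabel("threshold (deg)")
    fig.tight_layout()
    p = outdir / "thresholds_boxplot.png"
    fig.savefig(p, dpi=100)
    plt.close(fig)
    written.append(p)

    if agreement:
        fig, axes = plt.subplots(1, len(agreement), figsize=(5 * len(agreement), 4), squeeze=False)
        for ax, (label, res) in zip(axes.flat, agreement.items()):
            ba = res.bland_altman
            ax.scatter(ba.mean_log, ba.log_diff, s=15)
            for y, style in ((ba.mean_log_diff, "r--"), (0.0, "k-")):
                ax.axhline(y, ls=style[1:], c=style[0], lw=1)
            for y in (ba.mean_log_diff - 1.96 * ba.sd_log_diff, ba.mean_log_diff + 1.96 * ba.sd_log_diff):
                ax.axhline(y, ls=":", c="b", lw=1)
            ax.set_title(f"Bland-Altman ({label})")
            ax.set_xlabel("mean log threshold")
            ax.set_ylabel("log(lab) - log(web)")
        fig.tight_layout()
        p = outdir / "bland_altman.png"
        fig.savefig(p, dpi=100)
        plt.close(fig)
        written.append(p)
    return written


@dataclass
class RunManifest:
    """Reproducibility record for one command-line invocation."""

    command: str
    seed: int | None
    config: dict = field(default_factory=dict)
    inputs: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    package_version: str = ""
    timestamp: str = field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat()
    )

    def write(self, path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True), encoding="utf-8"
        )

    @classmethod
    def read(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text(encoding="utf-8")))
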