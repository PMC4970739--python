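"""Curve-file readers/writers and report rendering.

Digitized curves travel as CSV with header
``time_months,survival,n_at_risk_total``; the trial sample size may be
repeated per row or supplied by the manifest. Reports are CSV plus a plain
text summary embedding the resolved configuration hash.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .config import RunConfig
from .survival_models import SurvivalCurve, TransitionSchedule

__all__ = [
    "read_curve_csv",
    "write_curve_csv",
    "load_branch_curves",
    "write_fit_report",
    "write_schedule_csv",
    "render_text_report",
]

CURVE_COLUMNS = ["time_months", "survival", "n_at_risk_total"]


def read_curve_csv(path: str | Path, label: str | None = None,
                   n: int | None = None) -> SurvivalCurve:
    """Read one digitized trial-arm curve."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in CURVE_COLUMNS[:2] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if n is None:
        if "n_at_risk_total" not in df.columns:
            raise ValueError(f"{path}: no n_at_risk_total column and no n supplied")
        n = int(df["n_at_risk_total"].iloc[0])
    return SurvivalCurve(
        label or path.stem,
        list(zip(df["time_months"].astype(float), df["survival"].astype(float))),
        n=n,
    )


def write_curve_csv(curve: SurvivalCurve, path: str | Path) -> None:
    df = pd.DataFrame({
        "time_months": curve.times,
        "survival": curve.survival,
        "n_at_risk_total": curve.n,
    })
    df.to_csv(path, index=False)


def load_branch_curves(config: RunConfig,
                       base_dir: str | Path) -> dict[str, list[SurvivalCurve]]:
    """Load every curve file referenced by the manifest, keyed by branch."""
    base = Path(base_dir) / config.curve_dir
    out: dict[str, list[SurvivalCurve]] = {}
    for branch, files in config.curve_branches.items():
        out[branch] = [read_curve_csv(base / f) for f in files]
    return out


def write_fit_report(rows: Iterable[Mapping], path: str | Path) -> None:
    """CSV report of fitted parameters: branch, method, shape, scale, sse."""
    pd.DataFrame(rows, columns=["branch", "method", "shape", "scale", "sse"]) \
        .to_csv(path, index=False)


def write_schedule_csv(schedule: TransitionSchedule, path: str | Path) -> None:
    pd.DataFrame({"cycle": range(len(schedule)), "p_event": schedule.probs}) \
        .to_csv(path, index=False)


def render_text_report(config: RunConfig, lines: Iterable[str]) -> str:
    header = [
        "cdxcea run report",
        f"config hash: {config.hash}",
        f"horizon: {config.cycle.horizon} cycles, "
        f"discount: {config.cycle.annual_discount_rate:.1%}/yr, "
        f"extrapolation: {config.extrapolation}",
        "-" * 60,
    ]
    return "\n".join(header + list(lines)) + "\n"
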