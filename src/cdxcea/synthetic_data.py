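"""Synthetic Kaplan-Meier data with known ground truth.

Event times are drawn from a Weibull distribution per arm, censored by an
independent exponential mechanism plus an administrative cutoff, and turned
into product-limit estimates (via lifelines). Curves are then emitted on a
monthly grid, mirroring what figure digitization of a published K-M plot
yields, so the fitting/pooling pipeline can be exercised end-to-end with a
recoverable truth.

:func:`build_reference_study` assembles a complete synthetic study — one
curve set per model branch with the per-branch trial counts of the study
design this package models (e.g. three pooled trials for first-line TKI
PFS in mutation-positive patients, twelve for second-line TKI in all
comers), plus a fully populated run configuration. All curve values are
synthetic; the parameter table (costs, utilities, test accuracy) holds the
published input values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from lifelines import KaplanMeierFitter

from .config import RunConfig
from .survival_models import SurvivalCurve

log = logging.getLogger(__name__)

__all__ = [
    "SimSpec",
    "simulate_km",
    "monthly_digitized",
    "default_config",
    "build_reference_study",
    "DEFAULT_SEED",
]

DEFAULT_SEED = 12345


@dataclass(frozen=True)
class SimSpec:
    """Ground truth for one simulated trial arm.

    ``censor_rate`` is the monthly rate of the independent exponential
    censoring process (0 disables it); ``cutoff`` is the administrative
    follow-up limit in months.
    """

    label: str
    shape: float
    scale: float
    n: int
    censor_rate: float = 0.0
    cutoff: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need n ≥ 2")
        if self.censor_rate < 0 or self.cutoff <= 0:
            raise ValueError("censor_rate ≥ 0 and cutoff > 0 required")
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("Weibull parameters must be positive")


def simulate_km(spec: SimSpec) -> tuple[SurvivalCurve, pd.DataFrame]:
    """Simulate one arm and return its product-limit estimate.

    Returns the K-M curve evaluated at the observed event times together
    with the individual-level event table (time, observed flag).
    """
    rng = np.random.default_rng(spec.seed)
    event_times = spec.scale * rng.weibull(spec.shape, spec.n)
    if spec.censor_rate > 0:
        censor = rng.exponential(1.0 / spec.censor_rate, spec.n)
    else:
        censor = np.full(spec.n, np.inf)
    censor = np.minimum(censor, spec.cutoff)
    time = np.minimum(event_times, censor)
    observed = event_times <= censor
    events = pd.DataFrame({"time": time, "observed": observed})

    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=observed, label=spec.label)
    if not observed.any():
        warnings.warn(f"{spec.label}: all observations censored; flat curve")
        return SurvivalCurve(spec.label, [(0.0, 1.0)], n=spec.n), events

    ts = np.sort(np.unique(time[observed]))
    ss = np.asarray(kmf.predict(ts), dtype=float)
    pts = [(float(t), float(s)) for t, s in zip(ts, ss) if s > 0]
    return SurvivalCurve(spec.label, pts, n=spec.n), events


def monthly_digitized(spec: SimSpec) -> SurvivalCurve:
    """Simulate an arm and read its K-M estimate off a monthly grid,
    emulating a digitized published curve.

    The grid stops at the last observed time: a plotted K-M curve does not
    extend past the end of follow-up, so no points exist to digitize there.
    """
    curve, events = simulate_km(spec)
    end = min(spec.cutoff, float(events["time"].max()))
    months = np.arange(1.0, np.floor(end) + 1.0)
    pts = [(float(t), curve.step_at(t)) for t in months if curve.step_at(t) > 0]
    return SurvivalCurve(spec.label, pts, n=curve.n)


# ---------------------------------------------------------------------------
# reference study fixture

# True Weibull (shape, scale[months], n_trials, cutoff[months]) per branch.
# Medians chosen to be realistic for the disease setting: first-line TKI
# PFS in mutation-positive patients (~13 mo median) clearly dominates
# first-line chemotherapy PFS (~5-6 mo); unselected second-line TKI PFS is
# short (~2 mo); OS medians ~8-12 mo; BSC ~3 mo. Trial counts per branch
# follow the pooled-evidence design (3/1/1/1/2/12 for PFS, 9/1/1/2/12/1
# for OS).
_BRANCH_TRUTH: dict[str, tuple[float, float, int, float]] = {
    "pfs_ert1_mpos":  (1.4, 16.8, 3, 24.0),
    "pfs_cpem2_mpos": (1.2, 5.4, 1, 24.0),
    "pfs_cpem1_mneg": (1.3, 7.3, 1, 24.0),
    "pfs_dox2_mneg":  (1.1, 4.2, 1, 24.0),
    "pfs_cpem1_all":  (1.3, 7.3, 2, 24.0),
    "pfs_ert2_all":   (1.0, 3.2, 12, 24.0),
    "pfs_cgem1_all":  (1.3, 6.6, 9, 24.0),
    "pfs_pem2_all":   (1.1, 4.2, 1, 24.0),
    "os_cgem1_all":   (1.3, 14.6, 9, 36.0),
    "os_cpem2_mpos":  (1.2, 13.6, 1, 36.0),
    "os_dox2_mneg":   (1.2, 10.9, 1, 36.0),
    "os_cpem1_all":   (1.3, 15.3, 2, 36.0),
    "os_ert2_all":    (1.1, 11.2, 12, 36.0),
    "os_pem2_all":    (1.2, 11.3, 1, 36.0),
    "os_bsc":         (1.0, 4.3, 1, 24.0),
}

_CENSOR_RATE = 0.02  # per month, independent loss to follow-up


def branch_truth() -> dict[str, tuple[float, float, int, float]]:
    """Ground-truth table used by :func:`build_reference_study`."""
    return dict(_BRANCH_TRUTH)


def default_config(branches: dict[str, list[str]] | None = None) -> dict[str, Any]:
    """Raw configuration dictionary with the published input-parameter
    table pre-filled (costs per cycle in 2014 USD, utilities, diagnostic
    accuracy) and the two comparator strategies bound to their branches."""
    if branches is None:
        branches = {b: [f"{b}_trial{i}.csv" for i in range(k)]
                    for b, (_, _, k, _) in _BRANCH_TRUTH.items()}
    return {
        "cycle": {"horizon": 60, "annual_discount_rate": 0.03,
                  "half_cycle_correction": False},
        "epidemiology": {"prevalence": 0.39, "sensitivity": 0.984,
                         "specificity": 0.892, "p_unknown": 0.11},
        "test_cost": 104.0,
        "extrapolation": "mean",
        "ae_whole_admin_period": False,
        "iv_disutility_scenario": False,
        "utilities": {"pre_progression": 0.6532, "progression": 0.4734,
                      "bsc": 0.4734, "oral_adjustment": 0.02,
                      "iv_disutility": 0.043},
        # ae_disutility totals are Σ(assumed incidence × published per-event
        # disutility); incidences are a synthetic fixture choice.
        "regimens": {
            "ERT":  {"cost_admin": 2113.0, "cost_nonadmin": 2113.0,
                     "admin_cycles": "all", "oral": True, "ae_disutility": 0.034},
            "CPEM": {"cost_admin": 4157.0, "cost_nonadmin": 503.0,
                     "admin_cycles": 4, "oral": False, "ae_disutility": 0.070},
            "CGEM": {"cost_admin": 3327.0, "cost_nonadmin": 454.0,
                     "admin_cycles": 4, "oral": False, "ae_disutility": 0.076},
            "DOX":  {"cost_admin": 3300.0, "cost_nonadmin": 616.0,
                     "admin_cycles": 4, "oral": False, "ae_disutility": 0.081},
            "PEM":  {"cost_admin": 4501.0, "cost_nonadmin": 594.0,
                     "admin_cycles": 4, "oral": False, "ae_disutility": 0.050},
            "BSC":  {"cost_admin": 1038.0, "cost_nonadmin": 1038.0,
                     "admin_cycles": "all", "oral": False, "ae_disutility": 0.0},
        },
        "cost_scale": {},
        "curves": {"dir": "curves", "branches": branches},
        "strategies": {
            "testing": {
                "test_cost_applies": True,
                "arms": [
                    {"name": "test_positive", "weight": "p_test_positive",
                     "lines": [
                         {"regimen": "ERT", "pfs": "pfs_ert1_mpos",
                          "os": "os_cgem1_all", "utility": "pre_progression"},
                         {"regimen": "CPEM", "pfs": "pfs_cpem2_mpos",
                          "os": "os_cpem2_mpos", "utility": "progression"},
                         {"regimen": "BSC", "os": "os_bsc", "utility": "bsc"},
                     ]},
                    {"name": "chemo_pathway", "weight": "p_chemo_pathway",
                     "lines": [
                         {"regimen": "CPEM", "pfs": "pfs_cpem1_mneg",
                          "os": "os_cpem1_all", "utility": "pre_progression"},
                         {"regimen": "DOX", "pfs": "pfs_dox2_mneg",
                          "os": "os_dox2_mneg", "utility": "progression"},
                         {"regimen": "BSC", "os": "os_bsc", "utility": "bsc"},
                     ]},
                ],
            },
            "no_testing": {
                "test_cost_applies": False,
                "arms": [
                    {"name": "all", "weight": "all",
                     "lines": [
                         {"regimen": "CPEM", "pfs": "pfs_cpem1_all",
                          "os": "os_cpem1_all", "utility": "pre_progression"},
                         {"regimen": "ERT", "pfs": "pfs_ert2_all",
                          "os": "os_ert2_all", "utility": "progression"},
                         {"regimen": "BSC", "os": "os_bsc", "utility": "bsc"},
                     ]},
                ],
            },
        },
    }


def build_reference_study(seed: int = DEFAULT_SEED,
                          outdir: str | Path | None = None,
                          ) -> tuple[RunConfig, dict[str, list[SurvivalCurve]]]:
    """Generate the full synthetic study: curves per branch + configuration.

    Deterministic given ``seed``. When ``outdir`` is given, the curve CSVs,
    the base configuration (``config.yaml``) and one override file per
    registered scenario are written there.
    """
    from .economics import SCENARIOS  # local import to avoid a cycle

    master = np.random.SeedSequence(seed)
    curves: dict[str, list[SurvivalCurve]] = {}
    branches: dict[str, list[str]] = {}
    for branch, (shape, scale, k_trials, cutoff) in _BRANCH_TRUTH.items():
        children = master.spawn(k_trials)
        rng = np.random.default_rng(master.spawn(1)[0])
        sizes = rng.integers(120, 420, size=k_trials)
        curves[branch] = []
        branches[branch] = []
        for i, (child, n) in enumerate(zip(children, sizes)):
            spec = SimSpec(label=f"{branch}_trial{i}", shape=shape, scale=scale,
                           n=int(n), censor_rate=_CENSOR_RATE, cutoff=cutoff,
                           seed=int(child.generate_state(1)[0] % (2**31)))
            curves[branch].append(monthly_digitized(spec))
            branches[branch].append(f"{branch}_trial{i}.csv")

    config = RunConfig(default_config(branches))

    if outdir is not None:
        from .io import write_curve_csv
        outdir = Path(outdir)
        (outdir / config.curve_dir).mkdir(parents=True, exist_ok=True)
        for branch, curve_list in curves.items():
            for curve, fname in zip(curve_list, branches[branch]):
                write_curve_csv(curve, outdir / config.curve_dir / fname)
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
        scen_dir = outdir / "scenarios"
        scen_dir.mkdir(exist_ok=True)
        for name, overrides in SCENARIOS.items():
            with open(scen_dir / f"{name}.yaml", "w") as fh:
                yaml.safe_dump(overrides, fh)
    return config, curves
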