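"""Experiment orchestration: lambda sweep, selector comparison, fixed lambda.

Three analyses over a dataset of beats with ground-truth recordings:

1. ``run_sweep`` — reconstruct every beat at each lambda of a fixed
   grid (default: 0.001–0.009 step 0.001, 0.01–0.09 step 0.01,
   0.1–1.0 step 0.1; 28 values spanning low / medium / high
   regularization) and summarize CC/RE distributions per lambda.
2. ``run_method_comparison`` — per beat and selector, estimate the
   per-beat median lambda, reconstruct at it, and score the result.
3. ``run_fixed_lambda`` — reconstruct all beats at one fixed lambda and
   pair the metrics against each reference selector, beat by beat.

One lambda per beat is used throughout (the per-instant median), never
per-instant reconstruction.  Summary statistics are medians with
interquartile ranges.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import EvaluationReport, evaluate_beat
from .selection import METHODS, predefined_interval, select_beat
from .synthetic import Dataset, Geometry
from .tikhonov import TransferModel, decompose, reconstruct

__all__ = [
    "SweepGrid", "ExperimentConfig", "default_sweep_grid",
    "run_sweep", "run_method_comparison", "run_fixed_lambda",
    "render_at_map", "write_manifest",
]

METRICS = ("cc_egm", "re_egm", "cc_at", "re_at", "cc_rt", "re_rt")


@dataclass(frozen=True)
class SweepGrid:
    """Sorted, deduplicated set of fixed lambdas for the sweep analysis."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.size == 0 or np.any(v <= 0):
            raise ValueError("sweep grid must contain positive lambdas")
        u = np.unique(v)
        if u.size != v.size:
            warnings.warn("duplicate lambda values in sweep grid; deduplicated")
        object.__setattr__(self, "values", u)

    def __len__(self) -> int:
        return self.values.size


def default_sweep_grid() -> SweepGrid:
    """Low/medium/high-regularization ranges: 28 distinct lambdas."""
    vals = np.concatenate([
        np.round(np.arange(1, 10) * 0.001, 3),
        np.round(np.arange(1, 10) * 0.01, 2),
        np.round(np.arange(1, 11) * 0.1, 1),
    ])
    return SweepGrid(values=vals)


@dataclass
class ExperimentConfig:
    """Settings for one experiment run."""

    dataset_path: str = ""
    methods: tuple[str, ...] = METHODS
    sweep: SweepGrid = field(default_factory=default_sweep_grid)
    fixed_lambda: float = 0.01
    max_lag: int = 10
    stride: int = 1
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self):
        if self.fixed_lambda <= 0:
            raise ValueError("fixed_lambda must be positive")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")


# ---------------------------------------------------------------------------

def _score_beat(
    dataset: Dataset, tm: TransferModel, k: int, lam: float,
    max_lag: int, method: str = "",
) -> EvaluationReport:
    rec, gt = dataset.beats[k]
    sol = reconstruct(tm, rec.B, lam)
    return evaluate_beat(
        dataset.recorded_electrograms(k), sol, dataset.geometry,
        qrs_window=gt.qrs_window, t_window=gt.t_window, fs=gt.fs,
        max_lag=max_lag, method=method,
    )


def _pool(reports: list[EvaluationReport]) -> dict[str, np.ndarray]:
    """Pooled metric samples: electrode-level for electrograms, beat-level
    for activation/recovery times."""
    return {
        "cc_egm": np.concatenate([r.cc_egm for r in reports]),
        "re_egm": np.concatenate([r.re_egm for r in reports]),
        "cc_at": np.array([r.cc_at for r in reports]),
        "re_at": np.array([r.re_at for r in reports]),
        "cc_rt": np.array([r.cc_rt for r in reports]),
        "re_rt": np.array([r.re_rt for r in reports]),
    }


def _summary_rows(pool: dict[str, np.ndarray], **tags) -> list[dict]:
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        for metric, samples in pool.items():
            rows.append({
                **tags, "metric": metric,
                "median": float(np.nanmedian(samples)),
                "q1": float(np.nanquantile(samples, 0.25)),
                "q3": float(np.nanquantile(samples, 0.75)),
                "n": int(np.isfinite(samples).sum()),
                "n_flagged": int(np.size(samples) - np.isfinite(samples).sum()),
            })
    return rows


def run_sweep(
    dataset: Dataset,
    grid: SweepGrid | None = None,
    max_lag: int = 10,
    tm: TransferModel | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Reconstruct every beat at each grid lambda and summarize accuracy.

    Returns ``(table, best_lambda)``: a tidy frame with one row per
    (lambda, metric) holding median and quartiles, and per metric the
    lambda maximizing median CC (or minimizing median RE).
    """
    if dataset.n_beats == 0:
        raise ValueError("empty dataset")
    grid = grid or default_sweep_grid()
    tm = tm or decompose(dataset.A)
    rows = []
    for lam in grid.values:
        reports = [
            _score_beat(dataset, tm, k, float(lam), max_lag, method="fixed")
            for k in range(dataset.n_beats)
        ]
        rows.extend(_summary_rows(_pool(reports), lam=float(lam)))
    table = pd.DataFrame(rows)
    best = {}
    for metric in METRICS:
        sub = table[table.metric == metric].reset_index(drop=True)
        if metric.startswith("cc"):
            best[metric] = float(sub.lam[sub["median"].idxmax()])
        else:
            best[metric] = float(sub.lam[sub["median"].idxmin()])
    return table, best


def run_method_comparison(
    dataset: Dataset,
    methods: tuple[str, ...] = METHODS,
    max_lag: int = 10,
    stride: int = 1,
    tm: TransferModel | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-beat selector comparison.

    Returns a dict with

    ``lambdas``
        one row per (beat, method): per-beat median lambda, its search
        interval, and the count of fallback-flagged instants;
    ``beat_metrics``
        one row per (beat, method) with the evaluation summary;
    ``summary``
        per-method pooled medians/quartiles of every metric.
    """
    if not methods:
        raise ValueError("at least one method required")
    tm = tm or decompose(dataset.A)
    lam_rows, metric_rows, summary_rows = [], [], []
    for method in methods:
        interval = predefined_interval(tm, method)
        reports = []
        for k in range(dataset.n_beats):
            rec, _ = dataset.beats[k]
            sel = select_beat(tm, rec, method, interval=interval, stride=stride)
            n_fb = sum(d != "converged" for d in sel.diagnostics)
            lam_rows.append({
                "beat": k, "method": method, "lam_beat": sel.lam_beat,
                "lam_min": interval.lam_min, "lam_max": interval.lam_max,
                "n_instants": sel.lam_per_instant.size,
                "n_fallback": n_fb,
                "all_fallback": sel.all_fallback,
            })
            rep = _score_beat(dataset, tm, k, sel.lam_beat, max_lag, method)
            reports.append(rep)
            metric_rows.append({"beat": k, "method": method, **rep.beat_summary()})
        summary_rows.extend(_summary_rows(_pool(reports), method=method))
    return {
        "lambdas": pd.DataFrame(lam_rows),
        "beat_metrics": pd.DataFrame(metric_rows),
        "summary": pd.DataFrame(summary_rows),
    }


def run_fixed_lambda(
    dataset: Dataset,
    lam_fixed: float,
    reference_methods: tuple[str, ...] = ("lcurve", "creso", "zero_crossing"),
    max_lag: int = 10,
    stride: int = 1,
    tm: TransferModel | None = None,
    comparison: dict[str, pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Pair fixed-lambda reconstruction metrics against reference selectors.

    One row per (beat, method) with the fixed-lambda and method metrics
    side by side plus their differences — the data behind an
    identity-line scatter.  Pass a precomputed ``comparison`` (from
    :func:`run_method_comparison` over the same methods) to avoid
    re-running the selectors.
    """
    if lam_fixed <= 0:
        raise ValueError("lam_fixed must be positive")
    tm = tm or decompose(dataset.A)
    fixed_reports = {
        k: _score_beat(dataset, tm, k, lam_fixed, max_lag, method="fixed")
        for k in range(dataset.n_beats)
    }
    if comparison is None:
        comparison = run_method_comparison(
            dataset, reference_methods, max_lag=max_lag, stride=stride, tm=tm
        )
    beat_metrics = comparison["beat_metrics"]
    rows = []
    for method in reference_methods:
        sub = beat_metrics[beat_metrics.method == method].set_index("beat")
        for k in range(dataset.n_beats):
            fx = fixed_reports[k].beat_summary()
            mrow = sub.loc[k]
            row = {"beat": k, "method": method, "lam_fixed": lam_fixed,
                   "lam_method": float(mrow["lam"])}
            for metric in ("cc_egm_median", "re_egm_median",
                           "cc_at", "re_at", "cc_rt", "re_rt"):
                row[f"{metric}_fixed"] = fx[metric]
                row[f"{metric}_method"] = float(mrow[metric])
                row[f"{metric}_diff"] = fx[metric] - float(mrow[metric])
            rows.append(row)
    return pd.DataFrame(rows)


def render_at_map(
    at_values: np.ndarray, geometry: Geometry, path: str | Path
) -> Path:
    """Diagnostic 3-D scatter of an activation-time map (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    at_values = np.asarray(at_values, dtype=float)
    if at_values.size == geometry.n_heart:
        pts = geometry.heart_nodes
    elif at_values.size == geometry.n_recording:
        pts = geometry.recording_electrodes
    else:
        raise ValueError(
            f"{at_values.size} values match neither {geometry.n_heart} nodes "
            f"nor {geometry.n_recording} electrodes"
        )
    fig = plt.figure(figsize=(6, 5))
    ax = fig.add_subplot(projection="3d")
    sc = ax.scatter(pts[:, 0], pts[:, 1], pts[:, 2], c=at_values, cmap="turbo")
    fig.colorbar(sc, ax=ax, label="activation time (ms)")
    ax.set_title("Activation map")
    path = Path(path)
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path


def write_manifest(output_dir: str | Path, config: dict) -> Path:
    """Record the run configuration, its hash, and package versions."""
    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "versions": {"ecgireg": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
    }
    path = Path(output_dir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
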