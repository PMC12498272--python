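"""Grid orchestration: every task x subset x feature method x model cell.

Runs the repeated-holdout evaluation over the full analysis grid, writes
a tidy results table (one row per grid cell), a best-per-task table, a
per-task cross-method consensus report, and box-plot-ready group-wise
intensity summaries for the consensus bins.  Completed cells are cached
on disk keyed by a content hash of the cell settings and the input data,
so an interrupted grid resumes where it stopped.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .cohort import DEFAULT_TASKS, LabeledDataset, build_dataset, get_task
from .evaluation import (
    DEFAULT_N_REPEATS,
    MODEL_NAMES,
    run_evaluation,
    run_feature_stability,
    summary_row,
)
from .features import (
    CONSENSUS_METHODS,
    DEFAULT_ALPHA,
    DEFAULT_CONSENSUS_FRACTION,
    DEFAULT_K,
    ConsensusReport,
    consensus_features,
)

logger = logging.getLogger(__name__)

FEATURE_METHODS = ("none", "pearson", "overlap", "chi2")
SUBSETS = ("all", "extreme20", "extreme30")


@dataclass
class GridConfig:
    """Full analysis grid over tasks, subsets, methods and models."""

    tasks: tuple[str, ...] = tuple(DEFAULT_TASKS)
    subsets: dict = field(default_factory=dict)  # task -> list of subsets
    feature_methods: tuple[str, ...] = FEATURE_METHODS
    models: tuple[str, ...] = MODEL_NAMES
    demographics: tuple[bool, ...] = (False, True)
    repeats: int = DEFAULT_N_REPEATS
    base_seed: int = 0
    k: int = DEFAULT_K
    alpha: float = DEFAULT_ALPHA
    consensus_fraction: float = DEFAULT_CONSENSUS_FRACTION
    outdir: str | None = None

    def subsets_for(self, task: str) -> tuple[str, ...]:
        spec = get_task(task)
        if task in self.subsets:
            return tuple(self.subsets[task])
        if spec.extreme_allowed:
            return SUBSETS
        return ("all",)

    def validate(self, clinical: pd.DataFrame) -> None:
        """Reject impossible cells before any work is done."""
        for task in self.tasks:
            spec = get_task(task)
            if spec.variable not in clinical.columns:
                raise ValueError(
                    f"task {task!r}: variable {spec.variable!r} not in the "
                    "clinical table"
                )
            for subset in self.subsets_for(task):
                if subset not in SUBSETS:
                    raise ValueError(f"unknown subset {subset!r}")
                if subset != "all" and not spec.extreme_allowed:
                    raise ValueError(
                        f"task {task!r} has no extreme-patient variant; "
                        f"requested {subset!r}"
                    )
        for m in self.feature_methods:
            if m not in FEATURE_METHODS:
                raise ValueError(f"unknown feature method {m!r}")
        for m in self.models:
            if m not in MODEL_NAMES:
                raise ValueError(f"unknown model {m!r}")


def _fingerprint(clinical: pd.DataFrame, spectra: pd.DataFrame) -> str:
    h = hashlib.sha256()
    h.update(clinical.to_csv(index=False).encode())
    h.update(np.ascontiguousarray(spectra.to_numpy(float)).tobytes())
    h.update(",".join(map(str, spectra.index)).encode())
    return h.hexdigest()[:16]


def _cell_key(cell: dict, fingerprint: str) -> str:
    payload = json.dumps({**cell, "data": fingerprint}, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:24]


@dataclass
class GridResult:
    results: pd.DataFrame
    best_per_task: pd.DataFrame
    consensus: dict
    failures: list


def run_grid(
    config: GridConfig,
    clinical: pd.DataFrame,
    spectra: pd.DataFrame,
    force: bool = False,
) -> GridResult:
    """Execute every valid grid cell and assemble the result tables.

    Cell failures are recorded and the grid continues.  When
    ``config.outdir`` is set, per-cell summaries are cached as JSON and
    re-running a completed grid recomputes nothing and changes no output
    bytes (unless ``force``).
    """
    config.validate(clinical)
    fingerprint = _fingerprint(clinical, spectra)
    cache_dir = None
    if config.outdir:
        cache_dir = Path(config.outdir) / "cells"
        cache_dir.mkdir(parents=True, exist_ok=True)

    rows: list[dict] = []
    failures: list[dict] = []
    consensus: dict[tuple, ConsensusReport] = {}

    for task in config.tasks:
        for subset in config.subsets_for(task):
            for demo in config.demographics:
                try:
                    dataset = build_dataset(
                        spectra, clinical, task, subset=subset,
                        demographics=demo, seed=config.base_seed,
                    )
                except Exception as exc:
                    failures.append(
                        {"task": task, "subset": subset, "demographics": demo,
                         "stage": "build", "error": str(exc)}
                    )
                    continue
                for method in config.feature_methods:
                    for model in config.models:
                        cell = {
                            "task": task, "subset": subset,
                            "demographics": demo, "feature_method": method,
                            "model": model, "repeats": config.repeats,
                            "base_seed": config.base_seed, "k": config.k,
                            "alpha": config.alpha,
                        }
                        key = _cell_key(cell, fingerprint)
                        cached = cache_dir / f"{key}.json" if cache_dir else None
                        if cached is not None and cached.exists() and not force:
                            rows.append(json.loads(cached.read_text()))
                            continue
                        try:
                            res = run_evaluation(
                                dataset, model=model, feature_method=method,
                                n_repeats=config.repeats,
                                base_seed=config.base_seed,
                                k=config.k, alpha=config.alpha,
                            )
                        except Exception as exc:
                            failures.append({**cell, "stage": "evaluate",
                                             "error": str(exc)})
                            continue
                        row = summary_row(res.summary)
                        rows.append(row)
                        if cached is not None:
                            cached.write_text(json.dumps(row, sort_keys=True))
            # consensus per (task, subset): three methods on shared splits,
            # no demographic columns involved
            try:
                base = build_dataset(
                    spectra, clinical, task, subset=subset,
                    demographics=False, seed=config.base_seed,
                )
                selections = run_feature_stability(
                    base, methods=CONSENSUS_METHODS,
                    n_repeats=config.repeats, base_seed=config.base_seed,
                    k=config.k, alpha=config.alpha,
                )
                consensus[(task, subset)] = consensus_features(
                    selections, fraction=config.consensus_fraction
                )
            except Exception as exc:
                failures.append({"task": task, "subset": subset,
                                 "stage": "consensus", "error": str(exc)})

    column_order = [
        "task", "subset", "demographics", "feature_method", "model",
        "mean_kappa", "sd_kappa", "mean_accuracy", "sd_accuracy",
        "n_valid_partitions", "n_failed_partitions",
        "significance_threshold", "significant", "agreement",
    ]
    results = pd.DataFrame(rows)
    if not results.empty:
        results = results[column_order]
        results = results.sort_values(
            ["task", "subset", "demographics", "feature_method", "model"]
        ).reset_index(drop=True)
        best = (
            results.loc[results.groupby("task")["mean_kappa"].idxmax()]
            .sort_values("task")
            .reset_index(drop=True)
        )
    else:
        best = results
    if config.outdir:
        out = Path(config.outdir)
        results.to_csv(out / "results.csv", index=False)
        best.to_csv(out / "best_per_task.csv", index=False)
    return GridResult(results=results, best_per_task=best,
                      consensus=consensus, failures=failures)


# ---------------------------------------------------------------------------
# group-wise intensity summaries (box-plot statistics + t-test)


def export_group_distributions(
    consensus: ConsensusReport | Sequence[int],
    dataset: LabeledDataset,
    path=None,
) -> pd.DataFrame:
    """Box-plot statistics per consensus bin and class, with a t-test.

    For each bin and class: median, Q1 and Q3 (linear-interpolation
    quartiles), whisker ends at the farthest point within 1.5 x IQR of the
    box, and the outliers beyond them; plus the independent two-sample
    t statistic and P-value between the classes.  When a class has fewer
    than two samples the t-test is omitted and the row flagged.
    """
    bins = (
        list(consensus.consensus)
        if isinstance(consensus, ConsensusReport)
        else list(consensus)
    )
    if not bins:
        raise ValueError("consensus set is empty; nothing to export")
    y = np.asarray(dataset.labels).astype(int)
    rows = []
    for b in bins:
        col = dataset.spectra[b].to_numpy(float)
        groups = {cls: col[y == cls] for cls in (0, 1)}
        can_test = all(len(v) >= 2 for v in groups.values())
        if can_test:
            t_stat, p_value = stats.ttest_ind(groups[0], groups[1])
        else:
            t_stat = p_value = np.nan
        for cls, values in groups.items():
            q1, med, q3 = np.percentile(values, [25, 50, 75])
            iqr = q3 - q1
            in_lo = values[values >= q1 - 1.5 * iqr]
            in_hi = values[values <= q3 + 1.5 * iqr]
            lo = float(in_lo.min()) if in_lo.size else float(q1)
            hi = float(in_hi.max()) if in_hi.size else float(q3)
            outliers = values[(values < lo) | (values > hi)]
            rows.append(
                {
                    "bin": b,
                    "class": cls,
                    "n": len(values),
                    "median": float(med),
                    "q1": float(q1),
                    "q3": float(q3),
                    "whisker_low": lo,
                    "whisker_high": hi,
                    "n_outliers": int(outliers.size),
                    "t_statistic": float(t_stat) if can_test else np.nan,
                    "p_value": float(p_value) if can_test else np.nan,
                    "t_test_skipped": not can_test,
                }
            )
    frame = pd.DataFrame(rows)
    if path is not None:
        frame.to_csv(path, index=False)
    return frame


# ---------------------------------------------------------------------------
# structured configuration


def default_config() -> dict:
    """Template for the YAML run configuration."""
    return {
        "simulate": {
            "n_patients": 283,
            "seed": 0,
            "target": "mvo",
            "effect_peaks": [114, 129, 156, 197, 387, 532],
            "effect_size": 3.0,
            "noise_cv": 0.3,
            "biological_cv": 0.2,
        },
        "preprocess": {
            "bin_range": [11, 1000],
            "rise_factor": 5.0,
            "min_window_scans": 5,
        },
        "tasks": {name: {"variable": t.variable, "kind": t.kind,
                         "threshold": t.threshold,
                         "extreme_allowed": t.extreme_allowed}
                  for name, t in DEFAULT_TASKS.items()},
        "grid": {
            "tasks": list(DEFAULT_TASKS),
            "feature_methods": list(FEATURE_METHODS),
            "models": list(MODEL_NAMES),
            "demographics": [False, True],
            "repeats": DEFAULT_N_REPEATS,
            "base_seed": 0,
            "consensus_fraction": DEFAULT_CONSENSUS_FRACTION,
        },
        "output": {"outdir": "results"},
    }


def load_config(path) -> dict:
    """Load a YAML run configuration, filling unset keys from the template."""
    loaded = yaml.safe_load(Path(path).read_text()) or {}
    config = default_config()
    for section, values in loaded.items():
        if isinstance(values, dict) and section in config:
            config[section].update(values)
        else:
            config[section] = values
    return config


def grid_config_from_dict(grid: dict, outdir: str | None = None) -> GridConfig:
    return GridConfig(
        tasks=tuple(grid.get("tasks", tuple(DEFAULT_TASKS))),
        subsets=dict(grid.get("subsets", {})),
        feature_methods=tuple(grid.get("feature_methods", FEATURE_METHODS)),
        models=tuple(grid.get("models", MODEL_NAMES)),
        demographics=tuple(grid.get("demographics", (False, True))),
        repeats=int(grid.get("repeats", DEFAULT_N_REPEATS)),
        base_seed=int(grid.get("base_seed", 0)),
        k=int(grid.get("k", DEFAULT_K)),
        alpha=float(grid.get("alpha", DEFAULT_ALPHA)),
        consensus_fraction=float(
            grid.get("consensus_fraction", DEFAULT_CONSENSUS_FRACTION)
        ),
        outdir=outdir,
    )
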