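"""Per-partition feature reduction and cross-method consensus.

Three complementary ways of ranking m/z bins by how well they separate
two patient groups, always computed on training rows only:

``pearson``
    Point-biserial Pearson correlation between bin intensity and the 0/1
    class label, keeping every bin with a two-sided P below ``alpha``
    (no multiple-testing correction by default, optionally
    Benjamini-Hochberg).
``overlap``
    Overlap integral between the two groups' intensity distributions -
    the shared area of the two normalised histograms.  Near 1 the groups
    are indistinguishable at that bin; the ``k`` bins with the smallest
    integrals are kept.
``chi2``
    The chi-squared classification feature-ranking statistic on the
    nonnegative intensities; the ``k`` highest-importance bins are kept.

A bin is a *consensus* feature when, for each method separately, it is
selected in strictly more than a given fraction (default 75%) of that
method's training partitions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.feature_selection import chi2 as sklearn_chi2

DEFAULT_K = 40
DEFAULT_ALPHA = 0.05
DEFAULT_CONSENSUS_FRACTION = 0.75
CONSENSUS_METHODS = ("pearson", "overlap", "chi2")


@dataclass
class FeatureSelection:
    """Result of one feature-reduction pass on one training partition."""

    method: str
    selected: np.ndarray  # selected bin labels, ascending
    scores: pd.Series  # per-bin score (P-value, overlap integral, chi2)
    partition_id: int | None = None
    normal_fraction: float | None = None  # Shapiro-Wilk diagnostic (pearson)

    def __post_init__(self):
        self.selected = np.asarray(self.selected)
        if not np.all(np.isfinite(self.scores.to_numpy(float))):
            raise ValueError("feature scores must be finite")


def _feature_columns(X: pd.DataFrame) -> list:
    """All columns; callers pass m/z-only frames (demographics are appended
    downstream of selection)."""
    return list(X.columns)


def _as_matrix(X: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(float), np.asarray(list(X.columns))
    X = np.asarray(X, dtype=float)
    return X, np.arange(X.shape[1])


def _check_labels(y) -> np.ndarray:
    y = np.asarray(y)
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    return y.astype(int)


# ---------------------------------------------------------------------------
# method 1: point-biserial Pearson correlation


def pearson_select(
    X: pd.DataFrame | np.ndarray,
    y: Sequence,
    alpha: float = DEFAULT_ALPHA,
    fdr: bool = False,
    normality_diagnostic: bool = False,
    partition_id: int | None = None,
) -> FeatureSelection:
    """Select bins whose intensity correlates with the class label.

    Computes, per bin, the Pearson correlation against the 0/1 label (the
    point-biserial coefficient) and its two-sided P-value from the exact
    t transform; bins with P < ``alpha`` are selected.  Constant bins have
    undefined correlation and are assigned P = 1, never selected.  With
    ``fdr=True`` the gate is applied to Benjamini-Hochberg-adjusted
    P-values instead.  ``normality_diagnostic`` additionally reports the
    fraction of bins passing a Shapiro-Wilk normality test at P < 0.05
    (a sanity check on using a parametric test; it does not gate
    anything).
    """
    values, names = _as_matrix(X)
    y = _check_labels(y)
    n = values.shape[0]
    if min((y == 0).sum(), (y == 1).sum()) < 3:
        raise ValueError("need at least 3 samples per class")

    xc = values - values.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    constant = sx == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc * yc[:, None]).sum(axis=0) / (sx * sy)
    r = np.clip(np.where(constant, 0.0, r), -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    pvals = np.where(
        np.isclose(np.abs(r), 1.0), 0.0, 2.0 * stats.t.sf(np.abs(t), df)
    )
    pvals = np.where(constant, 1.0, pvals)

    gate = pvals.copy()
    if fdr:
        gate = stats.false_discovery_control(pvals, method="bh")
    mask = gate < alpha

    normal_fraction = None
    if normality_diagnostic:
        ok = 0
        tested = 0
        for j in range(values.shape[1]):
            col = values[:, j]
            if np.ptp(col) == 0:
                continue
            tested += 1
            if stats.shapiro(col).pvalue >= 0.05:
                ok += 1
        normal_fraction = ok / tested if tested else float("nan")

    return FeatureSelection(
        method="pearson",
        selected=names[mask],
        scores=pd.Series(pvals, index=names),
        partition_id=partition_id,
        normal_fraction=normal_fraction,
    )


# ---------------------------------------------------------------------------
# method 2: overlap integrals


def overlap_edges(pooled: np.ndarray, min_cells: int = 5) -> np.ndarray | None:
    """Shared histogram edges for a pooled sample.

    Equal-width cells spanning the pooled min-max, with ceil(sqrt(n))
    cells (at least ``min_cells``).  Returns None for a degenerate pooled
    range (all values identical), where the two distributions coincide by
    construction.
    """
    pooled = np.asarray(pooled, dtype=float)
    lo, hi = pooled.min(), pooled.max()
    if hi <= lo:
        return None
    cells = max(min_cells, math.ceil(math.sqrt(pooled.size)))
    return np.linspace(lo, hi, cells + 1)


def overlap_integral(
    values_class0: np.ndarray,
    values_class1: np.ndarray,
    bin_edges: np.ndarray | None,
) -> float:
    """Shared area of the two groups' normalised intensity histograms.

    Each group is histogrammed on the shared edges and normalised to unit
    sum; the overlap integral is the sum over histogram cells of the
    pointwise minimum.  1 means the binned distributions coincide, 0 means
    disjoint support.  Symmetric in its group arguments.
    """
    a = np.asarray(values_class0, dtype=float)
    b = np.asarray(values_class1, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if bin_edges is None:
        return 1.0
    ha, _ = np.histogram(a, bins=bin_edges)
    hb, _ = np.histogram(b, bins=bin_edges)
    # values at the pooled max fall in the last (closed) cell per numpy;
    # values outside the edges are dropped group-wise before normalising
    sa, sb = ha.sum(), hb.sum()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.minimum(ha / sa, hb / sb).sum())


def overlap_select(
    X: pd.DataFrame | np.ndarray,
    y: Sequence,
    k: int = DEFAULT_K,
    partition_id: int | None = None,
) -> FeatureSelection:
    """Select the k bins with the smallest group-overlap integrals.

    Per bin, shared edges span the pooled min-max with ceil(sqrt(n))
    equal-width cells (minimum 5); ties at the k-th value are broken by
    ascending bin label.
    """
    values, names = _as_matrix(X)
    y = _check_labels(y)
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need at least 2 samples per class")
    mask0 = y == 0
    scores = np.empty(values.shape[1])
    for j in range(values.shape[1]):
        col = values[:, j]
        edges = overlap_edges(col)
        scores[j] = overlap_integral(col[mask0], col[~mask0], edges)
    n_keep = min(k, values.shape[1])
    if n_keep < k:
        warnings.warn(
            f"only {values.shape[1]} features available; selecting all",
            UserWarning,
            stacklevel=2,
        )
    order = np.lexsort((names, scores))
    selected = np.sort(names[order[:n_keep]])
    return FeatureSelection(
        method="overlap",
        selected=selected,
        scores=pd.Series(scores, index=names),
        partition_id=partition_id,
    )


# ---------------------------------------------------------------------------
# method 3: chi-squared feature ranking


def chi2_select(
    X: pd.DataFrame | np.ndarray,
    y: Sequence,
    k: int = DEFAULT_K,
    partition_id: int | None = None,
) -> FeatureSelection:
    """Select the k bins with the highest chi-squared importance.

    Uses the frequency-style chi-squared classification ranking statistic
    on the nonnegative intensities (per-class intensity sums against the
    marginal expectation).  Ties are broken by ascending bin label.
    """
    values, names = _as_matrix(X)
    y = _check_labels(y)
    if np.any(values < 0):
        raise ValueError(
            "chi-squared ranking requires nonnegative features; run the "
            "preprocessing background-subtraction clip first"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        statistic, _ = sklearn_chi2(values, y)
    statistic = np.nan_to_num(statistic, nan=0.0)
    n_keep = min(k, values.shape[1])
    if n_keep < k:
        warnings.warn(
            f"only {values.shape[1]} features available; selecting all",
            UserWarning,
            stacklevel=2,
        )
    order = np.lexsort((names, -statistic))
    selected = np.sort(names[order[:n_keep]])
    return FeatureSelection(
        method="chi2",
        selected=selected,
        scores=pd.Series(statistic, index=names),
        partition_id=partition_id,
    )


def select_features(
    method: str,
    X: pd.DataFrame | np.ndarray,
    y: Sequence,
    k: int = DEFAULT_K,
    alpha: float = DEFAULT_ALPHA,
    partition_id: int | None = None,
) -> FeatureSelection:
    """Dispatch to one of the three reduction methods (or ``none``)."""
    if method == "none":
        _, names = _as_matrix(X)
        return FeatureSelection(
            method="none",
            selected=np.asarray(names),
            scores=pd.Series(np.zeros(len(names)), index=names),
            partition_id=partition_id,
        )
    if method == "pearson":
        return pearson_select(X, y, alpha=alpha, partition_id=partition_id)
    if method == "overlap":
        return overlap_select(X, y, k=k, partition_id=partition_id)
    if method == "chi2":
        return chi2_select(X, y, k=k, partition_id=partition_id)
    raise ValueError(f"unknown feature-reduction method {method!r}")


# ---------------------------------------------------------------------------
# consensus across partitions and methods


@dataclass
class ConsensusReport:
    """Per-method selection fractions and the cross-method consensus set.

    A bin qualifies when, for every required method separately, it was
    selected in strictly more than ``fraction`` of that method's
    partitions.
    """

    fractions: pd.DataFrame  # bins x methods, selection fraction in [0, 1]
    consensus: np.ndarray  # qualifying bin labels, ascending
    fraction: float
    methods: tuple[str, ...]
    n_partitions: dict = field(default_factory=dict)


def consensus_features(
    selections: Iterable[FeatureSelection],
    fraction: float = DEFAULT_CONSENSUS_FRACTION,
    methods: Sequence[str] = CONSENSUS_METHODS,
) -> ConsensusReport:
    """Cross-method consensus over repeated training partitions.

    ``selections`` holds the per-partition selections of each method;
    every method in ``methods`` must contribute at least one partition.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must lie in [0, 1)")
    selections = list(selections)
    counts: dict[str, dict] = {m: {} for m in methods}
    n_partitions = {m: 0 for m in methods}
    all_bins: set = set()
    for sel in selections:
        if sel.method not in counts:
            continue
        n_partitions[sel.method] += 1
        all_bins.update(sel.scores.index)
        for b in sel.selected:
            counts[sel.method][b] = counts[sel.method].get(b, 0) + 1
    for m in methods:
        if n_partitions[m] == 0:
            raise ValueError(f"no partitions recorded for method {m!r}")
    bins = sorted(all_bins)
    fractions = pd.DataFrame(
        {
            m: [counts[m].get(b, 0) / n_partitions[m] for b in bins]
            for m in methods
        },
        index=bins,
    )
    qualifying = (fractions > fraction).all(axis=1)
    consensus = np.asarray(fractions.index[qualifying])
    return ConsensusReport(
        fractions=fractions,
        consensus=consensus,
        fraction=fraction,
        methods=tuple(methods),
        n_partitions=n_partitions,
    )


def write_selection_csv(selections: Iterable[FeatureSelection], path) -> None:
    rows = []
    for sel in selections:
        chosen = set(sel.selected.tolist())
        for b, score in sel.scores.items():
            rows.append(
                {
                    "bin": b,
                    "method": sel.method,
                    "partition": sel.partition_id,
                    "score": score,
                    "selected": b in chosen,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_consensus_csv(report: ConsensusReport, path) -> None:
    out = report.fractions.copy()
    out["consensus"] = out.index.isin(set(report.consensus.tolist()))
    out.to_csv(path, index_label="bin")
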