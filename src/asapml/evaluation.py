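"""Repeated-holdout classifier evaluation scored by accuracy and Cohen's kappa.

A balanced binary dataset is repeatedly partitioned into training and
test sets in a stratified 80:20 ratio.  Within every partition, feature
reduction (if any) is fitted on the training rows only, a classifier from
the registry (KNN, SVM, LDA, NBC or RFC) is trained on the selected
features, and the test-set confusion counts are scored by

    accuracy = 100 (TP + TN) / N

and the chance-corrected agreement

    kappa = (p_o - p_e) / (1 - p_e),

with observed agreement p_o = (TP + TN)/N and expected agreement
p_e = [(TP+FP)(TP+FN) + (FN+TN)(FP+TN)] / N^2 from the marginals.  Means
and standard deviations over the partitions are reported, together with
a small-sample significance gate on kappa and a qualitative agreement
band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .cohort import DEMOGRAPHIC_PREFIX, DemographicScaler, LabeledDataset
from .features import DEFAULT_ALPHA, DEFAULT_K, FeatureSelection, select_features

DEFAULT_N_REPEATS = 200
DEFAULT_TRAIN_RATIO = 0.8

#: kappa significance gates: totals at or below the first size use the
#: stricter threshold.  Small balanced cohorts (n = 20 per class and the
#: heart-failure-scale sets, total <= 50) require kappa >= 0.6; sets up to
#: 60 samples (n = 30 per class) require kappa >= 0.5.
KAPPA_SMALL_MAX, KAPPA_SMALL_THRESHOLD = 50, 0.6
KAPPA_MEDIUM_MAX, KAPPA_MEDIUM_THRESHOLD = 60, 0.5

#: Agreement bands for kappa; boundary values fall in the lower band.
KAPPA_BANDS = (
    (0.2, "None"),
    (0.4, "Weak"),
    (0.6, "Fair"),
    (0.8, "Moderate"),
    (0.9, "Strong"),
)


class DegenerateKappaError(ValueError):
    """kappa is undefined: both marginals are degenerate (p_e = 1)."""


@dataclass(frozen=True)
class ConfusionCounts:
    """True/false positive/negative tallies for one test set."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")
        if self.total == 0:
            raise ValueError("confusion counts must total at least 1")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        if y_true.shape != y_pred.shape:
            raise ValueError("truth and prediction vectors differ in length")
        return cls(
            tp=int(((y_true == 1) & (y_pred == 1)).sum()),
            tn=int(((y_true == 0) & (y_pred == 0)).sum()),
            fp=int(((y_true == 0) & (y_pred == 1)).sum()),
            fn=int(((y_true == 1) & (y_pred == 0)).sum()),
        )


def accuracy(conf: ConfusionCounts) -> float:
    """Percent of test samples classified correctly: 100 (TP + TN) / N."""
    return 100.0 * (conf.tp + conf.tn) / conf.total


def cohen_kappa(conf: ConfusionCounts) -> float:
    """Cohen's kappa from confusion counts; in [-1, 1].

    Raises :class:`DegenerateKappaError` when expected agreement is 1
    (both the truth and the prediction marginals are one-sided), where
    kappa is undefined.
    """
    n = conf.total
    p_o = (conf.tp + conf.tn) / n
    p_e = (
        (conf.tp + conf.fp) * (conf.tp + conf.fn)
        + (conf.fn + conf.tn) * (conf.fp + conf.tn)
    ) / n**2
    if p_e >= 1.0:
        raise DegenerateKappaError(
            "kappa undefined: expected agreement equals 1"
        )
    return (p_o - p_e) / (1.0 - p_e)


def kappa_significance_threshold(
    n_total: int,
    small_threshold: float = KAPPA_SMALL_THRESHOLD,
    medium_threshold: float = KAPPA_MEDIUM_THRESHOLD,
    default: float = 0.0,
) -> float:
    """Minimum kappa considered statistically significant at a dataset size.

    Chance agreement fluctuates more in small test sets, so small cohorts
    demand larger kappa: totals up to 50 require 0.6, up to 60 require
    0.5, larger datasets fall through to ``default`` (0 = always report).
    """
    if n_total < 4:
        raise ValueError("n_total must be at least 4")
    if n_total <= KAPPA_SMALL_MAX:
        return small_threshold
    if n_total <= KAPPA_MEDIUM_MAX:
        return medium_threshold
    return default


def interpret_kappa(kappa: float) -> str:
    """Qualitative level-of-agreement band for a kappa value.

    Bands: <0.2 None, 0.2-0.4 Weak, 0.4-0.6 Fair, 0.6-0.8 Moderate,
    0.8-0.9 Strong, >0.9 Very strong; boundary values go to the lower
    band.
    """
    if not -1.0 <= kappa <= 1.0:
        raise ValueError("kappa must lie in [-1, 1]")
    for upper, label in KAPPA_BANDS:
        if kappa <= upper:
            return label
    return "Very strong"


def stratified_partition(
    labels: Sequence,
    ratio: float = DEFAULT_TRAIN_RATIO,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Random stratified train/test split of a balanced binary label vector.

    Within each class, floor(ratio * n_class) samples go to training and
    the remainder to test; the partition is a pure function of the seed.
    """
    y = np.asarray(labels).astype(int)
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        if len(idx) == 0:
            raise ValueError(f"class {cls} is empty")
        n_train = int(np.floor(ratio * len(idx)))
        if n_train == 0 or n_train == len(idx):
            raise ValueError(
                f"class {cls} too small ({len(idx)}) to appear in both "
                "training and test sets"
            )
        perm = rng.permutation(idx)
        train_parts.append(perm[:n_train])
        test_parts.append(perm[n_train:])
    return (
        np.sort(np.concatenate(train_parts)),
        np.sort(np.concatenate(test_parts)),
    )


# ---------------------------------------------------------------------------
# model registry

DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "KNN": {"n_neighbors": 5, "metric": "euclidean"},
    "SVM": {"kernel": "rbf", "C": 1.0, "gamma": "scale"},
    "LDA": {},
    "NBC": {},
    "RFC": {"n_estimators": 100},
}


def make_model(name: str, seed: int = 0, hyperparameters: dict | None = None):
    """Instantiate a registry classifier with pinned, overridable settings."""
    params = dict(DEFAULT_HYPERPARAMETERS.get(name, {}))
    params.update(hyperparameters or {})
    if name == "KNN":
        return KNeighborsClassifier(**params)
    if name == "SVM":
        return SVC(random_state=seed, **params)
    if name == "LDA":
        return LinearDiscriminantAnalysis(**params)
    if name == "NBC":
        return GaussianNB(**params)
    if name == "RFC":
        return RandomForestClassifier(random_state=seed, **params)
    raise ValueError(
        f"unknown model {name!r}; registry: {sorted(DEFAULT_HYPERPARAMETERS)}"
    )


MODEL_NAMES = tuple(DEFAULT_HYPERPARAMETERS)


# ---------------------------------------------------------------------------
# repeated evaluation


@dataclass
class PartitionResult:
    """Outcome of one train/test partition."""

    partition_id: int
    seed: int
    model: str
    feature_method: str
    confusion: ConfusionCounts
    accuracy: float
    kappa: float
    selected: np.ndarray


@dataclass
class EvaluationSummary:
    """Mean +/- SD accuracy and kappa over the valid partitions."""

    mean_accuracy: float
    sd_accuracy: float
    mean_kappa: float
    sd_kappa: float
    n_partitions: int
    n_valid: int
    n_failed: int
    significance_threshold: float
    significant: bool
    agreement: str
    provenance: dict = field(default_factory=dict)


@dataclass
class EvaluationResult:
    summary: EvaluationSummary
    partitions: list[PartitionResult]


def _partition_seeds(base_seed: int, i: int) -> tuple[int, int]:
    """Per-partition (split, model) seeds derived from a base seed."""
    state = np.random.SeedSequence([int(base_seed), int(i)]).generate_state(2)
    return int(state[0] % 2**31), int(state[1] % 2**31)


def _mz_columns(X: pd.DataFrame) -> list:
    return [c for c in X.columns if not str(c).startswith(DEMOGRAPHIC_PREFIX)]


def run_evaluation(
    dataset: LabeledDataset,
    model: str = "LDA",
    feature_method: str = "none",
    n_repeats: int = DEFAULT_N_REPEATS,
    base_seed: int = 0,
    ratio: float = DEFAULT_TRAIN_RATIO,
    k: int = DEFAULT_K,
    alpha: float = DEFAULT_ALPHA,
    hyperparameters: dict | None = None,
) -> EvaluationResult:
    """Repeated stratified-holdout evaluation of one model on one dataset.

    Per repeat: draw a stratified 80:20 split, fit the feature selection
    on the training rows only, refit the demographic rescaling (when the
    dataset carries demographic parameters) on the training rows only,
    train the classifier on the selected features, and score the test
    confusion counts.  Partitions with undefined kappa or an empty
    feature selection are excluded from the means and counted in
    ``n_failed``.  The whole run is a pure function of
    ``(dataset, model, base_seed, settings)``.
    """
    y = np.asarray(dataset.labels).astype(int)
    X = dataset.spectra
    mz_cols = _mz_columns(X)

    results: list[PartitionResult] = []
    n_failed = 0
    for i in range(n_repeats):
        split_seed, model_seed = _partition_seeds(base_seed, i)
        train_idx, test_idx = stratified_partition(y, ratio=ratio, seed=split_seed)
        X_train, X_test = X.iloc[train_idx], X.iloc[test_idx]
        y_train, y_test = y[train_idx], y[test_idx]

        selection = select_features(
            feature_method, X_train[mz_cols], y_train, k=k, alpha=alpha,
            partition_id=i,
        )
        if len(selection.selected) == 0:
            n_failed += 1
            continue
        cols = list(selection.selected)
        F_train = X_train[cols]
        F_test = X_test[cols]

        if dataset.demographic_params:
            scaler = DemographicScaler(dataset.demographic_params)
            clin = dataset.clinical
            scaler.fit(F_train, clin.iloc[train_idx])
            F_train = scaler.transform(F_train, clin.iloc[train_idx])
            F_test = scaler.transform(F_test, clin.iloc[test_idx])

        clf = make_model(model, seed=model_seed, hyperparameters=hyperparameters)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(F_train.to_numpy(float), y_train)
            y_pred = clf.predict(F_test.to_numpy(float))
        conf = ConfusionCounts.from_predictions(y_test, y_pred)
        try:
            kappa = cohen_kappa(conf)
        except DegenerateKappaError:
            n_failed += 1
            continue
        results.append(
            PartitionResult(
                partition_id=i,
                seed=split_seed,
                model=model,
                feature_method=feature_method,
                confusion=conf,
                accuracy=accuracy(conf),
                kappa=kappa,
                selected=selection.selected,
            )
        )

    if not results:
        raise RuntimeError("no valid partitions; evaluation failed everywhere")
    accs = np.array([r.accuracy for r in results])
    kappas = np.array([r.kappa for r in results])
    threshold = kappa_significance_threshold(dataset.n)
    mean_kappa = float(kappas.mean())
    summary = EvaluationSummary(
        mean_accuracy=float(accs.mean()),
        sd_accuracy=float(accs.std(ddof=0)),
        mean_kappa=mean_kappa,
        sd_kappa=float(kappas.std(ddof=0)),
        n_partitions=n_repeats,
        n_valid=len(results),
        n_failed=n_failed,
        significance_threshold=threshold,
        significant=mean_kappa >= threshold,
        agreement=interpret_kappa(float(np.clip(mean_kappa, -1.0, 1.0))),
        provenance={
            **dataset.provenance,
            "model": model,
            "feature_method": feature_method,
            "base_seed": base_seed,
            "n_repeats": n_repeats,
            "ratio": ratio,
            "k": k,
            "alpha": alpha,
        },
    )
    if n_repeats == 1:
        summary.provenance["single_partition_sd_convention"] = True
    return EvaluationResult(summary=summary, partitions=results)


def run_feature_stability(
    dataset: LabeledDataset,
    methods: Sequence[str] = ("pearson", "overlap", "chi2"),
    n_repeats: int = DEFAULT_N_REPEATS,
    base_seed: int = 0,
    ratio: float = DEFAULT_TRAIN_RATIO,
    k: int = DEFAULT_K,
    alpha: float = DEFAULT_ALPHA,
) -> list[FeatureSelection]:
    """Per-partition selections of every method, on shared splits.

    Uses the same split-seed derivation as :func:`run_evaluation`, so the
    partitions match an evaluation run with the same base seed.  The
    output feeds :func:`asapml.features.consensus_features`.
    """
    y = np.asarray(dataset.labels).astype(int)
    X = dataset.spectra
    mz_cols = _mz_columns(X)
    selections: list[FeatureSelection] = []
    for i in range(n_repeats):
        split_seed, _ = _partition_seeds(base_seed, i)
        train_idx, _test = stratified_partition(y, ratio=ratio, seed=split_seed)
        X_train = X.iloc[train_idx][mz_cols]
        y_train = y[train_idx]
        for method in methods:
            selections.append(
                select_features(method, X_train, y_train, k=k, alpha=alpha,
                                partition_id=i)
            )
    return selections


def summary_row(summary: EvaluationSummary) -> dict:
    """Flatten an :class:`EvaluationSummary` for the tidy results table."""
    prov = summary.provenance
    return {
        "task": prov.get("task"),
        "subset": prov.get("subset"),
        "demographics": prov.get("demographics"),
        "feature_method": prov.get("feature_method"),
        "model": prov.get("model"),
        "mean_kappa": summary.mean_kappa,
        "sd_kappa": summary.sd_kappa,
        "mean_accuracy": summary.mean_accuracy,
        "sd_accuracy": summary.sd_accuracy,
        "n_valid_partitions": summary.n_valid,
        "n_failed_partitions": summary.n_failed,
        "significance_threshold": summary.significance_threshold,
        "significant": summary.significant,
        "agreement": summary.agreement,
    }
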