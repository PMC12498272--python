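"""Binary classification tasks and dataset construction from clinical variables.

Each clinical variable of interest is turned into a binary task by a
:class:`TaskSpec` rule: a yes/no categorical variable, a threshold on a
continuous variable, or a split of an ordinal score range.  Datasets are
then built either from *all* labelled patients with the majority class
undersampled to the minority count (so a classifier cannot win by always
guessing the majority), or from the *extreme* patients only - the n lowest
and n highest values of a continuous variable.

Clinically relevant demographic variables can be appended to a spectrum
matrix as additional feature columns after rescaling to the median
spectral intensity, so that their raw magnitudes (e.g. weight in kg) do
not dominate intensity features that sum to one per spectrum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

#: Prefix reserved for appended demographic feature columns; columns with
#: this prefix are excluded from m/z-peak selection and reporting.
DEMOGRAPHIC_PREFIX = "demo_"

#: Demographic variables appended by default: continuous anthropometrics
#: plus binary risk factors.  Patient sex is deliberately not included.
DEFAULT_DEMOGRAPHIC_PARAMS = (
    "age",
    "weight",
    "height",
    "bmi",
    "bsa",
    "smoker_or_ex",
    "hypertension",
    "diabetes",
    "previous_history",
)

BINARY_DEMOGRAPHICS = frozenset(
    {"smoker", "ex_smoker", "smoker_or_ex", "hypertension", "diabetes",
     "previous_history"}
)

_SEX_ALIASES = frozenset({"sex", "sex_male", "gender"})


@dataclass(frozen=True)
class TaskSpec:
    """Rule mapping one clinical variable to binary class labels 0/1.

    ``kind`` is one of ``binary`` (variable already 0/1), ``threshold``
    (class 0 strictly below / class 1 strictly above ``threshold``), or
    ``score_range`` (ordinal scores in ``low_scores`` -> 0, in
    ``high_scores`` -> 1, anything else unassigned).  For thresholds the
    exact-boundary value is assigned to ``boundary_class`` and counted.
    """

    name: str
    variable: str
    kind: str
    threshold: float | None = None
    low_scores: tuple[int, ...] = ()
    high_scores: tuple[int, ...] = ()
    boundary_class: int = 0
    extreme_allowed: bool = True
    labels: tuple[str, str] = ("Low", "High")

    def __post_init__(self):
        if self.kind not in {"binary", "threshold", "score_range"}:
            raise ValueError(f"unknown task kind: {self.kind!r}")
        if self.kind == "threshold" and self.threshold is None:
            raise ValueError("threshold task needs a threshold value")


#: Default binary tasks over the cohort's clinical variables.  Mortality
#: and heart-failure diagnosis are plain yes/no labels with no extreme
#: variant; the six continuous variables use literature thresholds
#: (IMR 40, ischemic time 6 h, peak troponin 50, creatinine 75, MVO 0)
#: or an ordinal split (thrombus score 1-3 vs 4-5, score 0 unassigned).
DEFAULT_TASKS: dict[str, TaskSpec] = {
    "died": TaskSpec("died", "died", "binary", extreme_allowed=False),
    "hfd": TaskSpec("hfd", "hfd", "binary", extreme_allowed=False),
    "mvo": TaskSpec("mvo", "mvo", "threshold", threshold=0.0),
    "imr": TaskSpec("imr", "imr", "threshold", threshold=40.0),
    "tscore": TaskSpec(
        "tscore", "tscore", "score_range",
        low_scores=(1, 2, 3), high_scores=(4, 5),
    ),
    "itime": TaskSpec("itime", "itime_h", "threshold", threshold=6.0),
    "troponin": TaskSpec("troponin", "troponin", "threshold", threshold=50.0),
    "creatinine": TaskSpec("creatinine", "creatinine", "threshold", threshold=75.0),
}


class BinarizationResult(NamedTuple):
    labels: np.ndarray  # float array, NaN = missing/unassigned
    boundary_count: int  # values exactly on a threshold boundary
    unassigned_count: int  # non-missing values outside any score range


def get_task(task: "TaskSpec | str") -> TaskSpec:
    if isinstance(task, TaskSpec):
        return task
    try:
        return DEFAULT_TASKS[task]
    except KeyError:
        raise KeyError(
            f"unknown task {task!r}; known tasks: {sorted(DEFAULT_TASKS)}"
        ) from None


def binarize_variable(values: Sequence, spec: TaskSpec) -> BinarizationResult:
    """Assign 0/1 class labels per the task rule; missing stays missing.

    Threshold tasks put values strictly below the threshold in class 0 and
    strictly above in class 1; values exactly at the threshold go to
    ``spec.boundary_class`` and are tallied in ``boundary_count``.  Score
    ranges leave out-of-range scores unassigned (NaN) and tally them.
    """
    v = pd.to_numeric(pd.Series(values), errors="coerce").to_numpy(float)
    labels = np.full(v.shape, np.nan)
    present = np.isfinite(v)
    boundary = 0
    unassigned = 0
    if spec.kind == "binary":
        bad = present & ~((v == 0) | (v == 1))
        if bad.any():
            raise ValueError(
                f"variable {spec.variable!r}: binary task but values outside "
                "{0, 1} present"
            )
        labels[present] = v[present]
    elif spec.kind == "threshold":
        t = spec.threshold
        labels[present & (v < t)] = 0.0
        labels[present & (v > t)] = 1.0
        on_boundary = present & (v == t)
        boundary = int(on_boundary.sum())
        labels[on_boundary] = float(spec.boundary_class)
    else:  # score_range
        labels[present & np.isin(v, spec.low_scores)] = 0.0
        labels[present & np.isin(v, spec.high_scores)] = 1.0
        unassigned = int((present & np.isnan(labels)).sum())
    return BinarizationResult(labels, boundary, unassigned)


def balanced_subset(labels: Sequence, seed: int = 0) -> np.ndarray:
    """Indices of a class-balanced subset.

    All minority-class samples are kept and the majority class is randomly
    undersampled without replacement to the same count.  Deterministic for
    a given seed; returned indices are sorted.
    """
    y = np.asarray(labels, dtype=float)
    if np.isnan(y).any():
        raise ValueError("labels contain missing values; drop them first")
    idx0 = np.flatnonzero(y == 0)
    idx1 = np.flatnonzero(y == 1)
    if len(idx0) == 0 or len(idx1) == 0:
        raise ValueError("both classes must be non-empty to balance")
    n = min(len(idx0), len(idx1))
    rng = np.random.default_rng(seed)
    keep0 = idx0 if len(idx0) == n else rng.choice(idx0, size=n, replace=False)
    keep1 = idx1 if len(idx1) == n else rng.choice(idx1, size=n, replace=False)
    return np.sort(np.concatenate([keep0, keep1]))


def extreme_subset(
    values: Sequence, n_per_tail: int
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the ``n`` smallest and ``n`` largest non-missing values.

    Ties are broken by the stable input (sample-ID) order, so the result
    is reproducible.  The two tails are disjoint by construction; fewer
    than ``2 * n_per_tail`` non-missing values is an error.
    """
    v = pd.to_numeric(pd.Series(values), errors="coerce").to_numpy(float)
    present = np.flatnonzero(np.isfinite(v))
    if len(present) < 2 * n_per_tail:
        raise ValueError(
            f"need at least {2 * n_per_tail} non-missing values for two "
            f"disjoint tails of {n_per_tail}; have {len(present)}"
        )
    order = present[np.argsort(v[present], kind="stable")]
    low = np.sort(order[:n_per_tail])
    high = np.sort(order[-n_per_tail:])
    return low, high


class DemographicScaler:
    """Rescale demographic variables onto the spectral intensity scale.

    ``fit`` learns, from a set of (training) rows, the global scale
    ``m`` - the median of all positive entries of the spectrum matrix -
    and per-variable observed ranges.  ``transform`` appends one column
    per variable: continuous variables are mapped linearly from
    [min, max] onto [0, m]; binary variables onto {0, m}.  Appended
    columns carry the reserved ``demo_`` prefix.

    Fitting on training rows only (and re-fitting per data partition)
    keeps test-set values out of the scaling.
    """

    def __init__(self, params: Sequence[str] = DEFAULT_DEMOGRAPHIC_PARAMS):
        params = list(params)
        kept = [p for p in params if p not in _SEX_ALIASES]
        if len(kept) != len(params):
            warnings.warn(
                "patient sex is excluded from demographic augmentation",
                UserWarning,
                stacklevel=2,
            )
        self.params = kept
        self.median_intensity_: float | None = None
        self.ranges_: dict[str, tuple[float, float]] = {}

    def fit(self, spectra: pd.DataFrame, clinical: pd.DataFrame) -> "DemographicScaler":
        values = spectra.to_numpy(float)
        positive = values[values > 0]
        if positive.size == 0:
            raise ValueError("spectrum matrix has no positive entries")
        self.median_intensity_ = float(np.median(positive))
        for p in self.params:
            if p not in clinical.columns:
                raise KeyError(f"demographic parameter {p!r} missing from table")
            col = pd.to_numeric(clinical[p], errors="coerce")
            if col.isna().any():
                raise ValueError(
                    f"demographic parameter {p!r} has missing values; drop "
                    "incomplete rows first"
                )
            if p not in BINARY_DEMOGRAPHICS:
                self.ranges_[p] = (float(col.min()), float(col.max()))
        return self

    def transform(
        self, spectra: pd.DataFrame, clinical: pd.DataFrame
    ) -> pd.DataFrame:
        if self.median_intensity_ is None:
            raise RuntimeError("scaler is not fitted")
        m = self.median_intensity_
        out = spectra.copy()
        for p in self.params:
            col = pd.to_numeric(clinical[p], errors="coerce").to_numpy(float)
            if p in BINARY_DEMOGRAPHICS:
                scaled = np.where(col > 0, m, 0.0)
            else:
                lo, hi = self.ranges_[p]
                if hi > lo:
                    scaled = np.clip((col - lo) / (hi - lo), 0.0, 1.0) * m
                else:
                    scaled = np.zeros_like(col)
            out[DEMOGRAPHIC_PREFIX + p] = scaled
        return out


def append_demographics(
    matrix: pd.DataFrame,
    clinical: pd.DataFrame,
    params: Sequence[str] = DEFAULT_DEMOGRAPHIC_PARAMS,
) -> pd.DataFrame:
    """One-shot demographic augmentation (fit and transform on all rows).

    For leakage-free evaluation use :class:`DemographicScaler` directly and
    fit it on training rows only.
    """
    if not params:
        return matrix.copy()
    clinical = clinical.set_index("patient_id").loc[matrix.index] \
        if "patient_id" in clinical.columns else clinical.loc[matrix.index]
    scaler = DemographicScaler(params).fit(matrix, clinical)
    return scaler.transform(matrix, clinical)


def complete_demographics_mask(
    clinical: pd.DataFrame, params: Sequence[str] = DEFAULT_DEMOGRAPHIC_PARAMS
) -> np.ndarray:
    """True where a patient has every listed demographic parameter present."""
    kept = [p for p in params if p not in _SEX_ALIASES]
    mask = np.ones(len(clinical), dtype=bool)
    for p in kept:
        mask &= pd.to_numeric(clinical[p], errors="coerce").notna().to_numpy()
    return mask


@dataclass
class LabeledDataset:
    """Aligned feature matrix, binary labels and provenance for one task."""

    spectra: pd.DataFrame
    labels: np.ndarray
    sample_ids: list[str]
    clinical: pd.DataFrame | None = None
    demographic_params: tuple[str, ...] | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.spectra) != len(self.labels):
            raise ValueError("feature matrix and labels are misaligned")

    @property
    def n(self) -> int:
        return len(self.labels)

    def class_counts(self) -> tuple[int, int]:
        return int((self.labels == 0).sum()), int((self.labels == 1).sum())


def subsample_balanced(
    dataset: "LabeledDataset", n_per_class: int, seed: int = 0
) -> "LabeledDataset":
    """Draw a smaller balanced dataset (n per class) from a balanced one.

    Used to pin a study design at an exact per-class size regardless of the
    stochastic class counts a generated cohort happens to produce.
    """
    y = dataset.labels
    rng = np.random.default_rng(seed)
    keep = []
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        if len(idx) < n_per_class:
            raise ValueError(
                f"class {cls} has {len(idx)} samples, fewer than {n_per_class}"
            )
        keep.append(rng.choice(idx, size=n_per_class, replace=False))
    idx = np.sort(np.concatenate(keep))
    return LabeledDataset(
        spectra=dataset.spectra.iloc[idx],
        labels=y[idx],
        sample_ids=[dataset.sample_ids[i] for i in idx],
        clinical=dataset.clinical.iloc[idx] if dataset.clinical is not None else None,
        demographic_params=dataset.demographic_params,
        provenance={**dataset.provenance, "n_per_class": n_per_class},
    )


def build_dataset(
    spectra: pd.DataFrame,
    clinical: pd.DataFrame,
    task: TaskSpec | str,
    subset: str = "all",
    demographics: bool | Sequence[str] = False,
    seed: int = 0,
) -> LabeledDataset:
    """Assemble a labelled, class-balanced dataset for one task.

    ``subset`` is ``"all"`` (every labelled patient, majority class
    undersampled to the minority count), ``"extreme20"`` or ``"extreme30"``
    (tails of the continuous variable; the low tail is class 0, the high
    tail class 1).  When ``demographics`` is truthy, patients missing any
    of the requested demographic parameters are dropped before subsetting
    and the parameter list is recorded so evaluation can refit the
    rescaling per partition.
    """
    spec = get_task(task)
    clin = clinical.set_index("patient_id", drop=False) \
        if "patient_id" in clinical.columns else clinical
    clin = clin.loc[spectra.index]

    demo_params: tuple[str, ...] | None = None
    n_dropped_demo = 0
    keep = np.ones(len(spectra), dtype=bool)
    if demographics:
        params = (
            DEFAULT_DEMOGRAPHIC_PARAMS
            if demographics is True
            else tuple(demographics)
        )
        demo_params = tuple(p for p in params if p not in _SEX_ALIASES)
        keep = complete_demographics_mask(clin, params)
        n_dropped_demo = int((~keep).sum())
    spectra = spectra.loc[keep]
    clin = clin.loc[keep]

    if subset == "all":
        labels, boundary, unassigned = binarize_variable(clin[spec.variable], spec)
        if np.isnan(labels).all():
            raise ValueError(f"target variable {spec.variable!r} entirely missing")
        # balance among the labelled rows only; no imputation is performed
        present = np.flatnonzero(~np.isnan(labels))
        idx = present[balanced_subset(labels[present], seed=seed)]
        y = labels[idx].astype(int)
    elif subset in {"extreme20", "extreme30"}:
        if not spec.extreme_allowed:
            raise ValueError(
                f"task {spec.name!r} has no extreme-patient variant"
            )
        n_tail = 20 if subset == "extreme20" else 30
        low, high = extreme_subset(clin[spec.variable], n_tail)
        idx = np.concatenate([low, high])
        y = np.concatenate([np.zeros(len(low), int), np.ones(len(high), int)])
        boundary = unassigned = 0
    else:
        raise ValueError(f"unknown subset {subset!r}")

    sub_spectra = spectra.iloc[idx]
    sub_clin = clin.iloc[idx]
    return LabeledDataset(
        spectra=sub_spectra,
        labels=y,
        sample_ids=[str(s) for s in sub_spectra.index],
        clinical=sub_clin,
        demographic_params=demo_params,
        provenance={
            "task": spec.name,
            "variable": spec.variable,
            "subset": subset,
            "demographics": bool(demographics),
            "n_dropped_incomplete_demographics": n_dropped_demo,
            "boundary_count": int(boundary),
            "unassigned_count": int(unassigned),
            "seed": seed,
        },
    )
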