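"""Synthetic cohorts with the statistical structure of ASAP-MS plasma studies.

The generators here stand in for a clinical cohort that cannot be
distributed: a demographic/clinical table with realistic skew and
missingness, per-patient plasma "molecular fingerprints" (unit-mass binned,
area-normalised spectra averaged over five replicate probe insertions)
with a class-dependent multiplicative effect planted on a small set of
m/z bins, and, optionally, the raw scan stream an ASAP-MS instrument
would emit for one sample.

Everything is a pure function of its inputs and a seed, so downstream
stages (segmentation, preprocessing, feature reduction, evaluation) can
be tested against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import binarize_variable, get_task
from .preprocessing import (
    DEFAULT_BIN_RANGE,
    RawAcquisition,
    Scan,
    WindowSegmentation,
    bin_labels,
)

# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class EffectSpec:
    """Planted class effect and noise model for synthetic spectra.

    ``effect_size`` multiplies the mean intensity of class-1 patients at
    each bin in ``effect_peaks`` (1.0 = no effect).  ``noise_cv`` is the
    inter-replicate coefficient of variation of the multiplicative
    log-normal measurement noise; the instrument protocol emulated here
    keeps it under 0.4.  ``biological_cv`` adds per-patient log-normal
    variation of the underlying metabolite levels; no replicate protocol
    can reduce it, and its default (0.2) is a package choice since only
    the replicate CV is constrained by the instrument characterisation.
    ``baseline_profile``, when given, overrides the default smooth mean
    spectrum over the configured bin range.
    """

    effect_peaks: tuple[int, ...] = (114, 129, 156, 197, 387, 532)
    effect_size: float = 3.0
    noise_cv: float = 0.3
    biological_cv: float = 0.2
    baseline_profile: np.ndarray | None = None

    def __post_init__(self):
        if self.effect_size <= 0:
            raise ValueError("effect_size must be > 0")
        if not 0 <= self.noise_cv < 1:
            raise ValueError("noise_cv must be in [0, 1)")
        if self.biological_cv < 0:
            raise ValueError("biological_cv must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level simulation settings.

    Defaults mirror the emulated study design: 283 patients, 990 unit-mass
    bins (m/z 11-1000), five replicate probe insertions per sample, one
    scan every 0.9 s, and 30 s background / sample windows.
    """

    n_patients: int = 283
    bin_range: tuple[int, int] = DEFAULT_BIN_RANGE
    replicates_per_sample: int = 5
    scan_period: float = 0.9
    background_duration: float = 30.0
    sample_duration: float = 30.0
    gap_duration: float = 10.0
    background_tic: float = 1.0e4
    sample_rise: float = 10.0  # sample-window TIC as a multiple of background
    scan_noise_cv: float = 0.05
    mz_jitter: float = 0.1
    missingness: dict = field(default_factory=dict)  # per-variable overrides
    prevalence: dict = field(default_factory=dict)  # per-variable overrides
    seed: int = 0

    def __post_init__(self):
        low, high = self.bin_range
        if high < low:
            raise ValueError("bin_range high must be >= low")
        if self.replicates_per_sample < 1:
            raise ValueError("replicates_per_sample must be >= 1")
        for name in ("scan_period", "background_duration", "sample_duration",
                     "gap_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for var, frac in self.missingness.items():
            if not 0.0 <= float(frac) <= 1.0:
                raise ValueError(
                    f"missing fraction for variable {var!r} must lie in "
                    f"[0, 1], got {frac}"
                )

    @property
    def n_bins(self) -> int:
        low, high = self.bin_range
        return high - low + 1

    @property
    def bins(self) -> np.ndarray:
        return bin_labels(self.bin_range)


# ---------------------------------------------------------------------------
# clinical table

# Per-variable generator settings.  Continuous variables are right-skewed
# (log-normal, parameterised by median and log-SD) so that extreme-subset
# logic is exercised; medians sit near the task thresholds so both classes
# are well populated.  Missing fractions echo the uneven availability of
# clinical follow-up data (microvascular measures are the least complete).
CONTINUOUS_VARIABLES: dict[str, dict] = {
    "imr": {"median": 32.0, "sigma": 0.70, "missing": 0.45},
    "itime_h": {"median": 5.0, "sigma": 0.60, "missing": 0.35},
    "troponin": {"median": 50.0, "sigma": 1.00, "missing": 0.15},
    "creatinine": {"median": 78.0, "sigma": 0.35, "missing": 0.12},
    "mvo": {"median": 3.0, "sigma": 0.90, "missing": 0.30, "zero_inflation": 0.55},
    "age": {"median": 62.0, "sigma": 0.18, "missing": 0.07},
    "weight": {"median": 82.0, "sigma": 0.20, "missing": 0.10},
    "height": {"median": 1.73, "sigma": 0.06, "missing": 0.10},
    "bmi": {"median": 27.0, "sigma": 0.18, "missing": 0.16},
    "bsa": {"median": 1.95, "sigma": 0.10, "missing": 0.10},
}

BINARY_VARIABLES: dict[str, dict] = {
    "died": {"prevalence": 0.087, "missing": 0.06},
    "hfd": {"prevalence": 0.11, "missing": 0.205},
    "sex_male": {"prevalence": 0.82, "missing": 0.064},
    "smoker": {"prevalence": 0.40, "missing": 0.060},
    "ex_smoker": {"prevalence": 0.475, "missing": 0.297},
    "smoker_or_ex": {"prevalence": 0.70, "missing": 0.074},
    "hypertension": {"prevalence": 0.42, "missing": 0.060},
    "diabetes": {"prevalence": 0.15, "missing": 0.060},
    "previous_history": {"prevalence": 0.33, "missing": 0.064},
}

#: Thrombus score 0-5 category probabilities (skewed towards mid scores).
TSCORE_PROBS = (0.04, 0.10, 0.16, 0.28, 0.26, 0.16)
TSCORE_MISSING = 0.25


def _missing_fraction(config: SimulationConfig, var: str, default: float) -> float:
    frac = float(config.missingness.get(var, default))
    if not 0.0 <= frac <= 1.0:
        raise ValueError(
            f"missing fraction for variable {var!r} must lie in [0, 1], got {frac}"
        )
    return frac


def generate_clinical_table(
    config: SimulationConfig, seed: int | None = None
) -> pd.DataFrame:
    """Generate a synthetic per-patient clinical/demographic table.

    Continuous variables are log-normal (MVO additionally zero-inflated:
    a majority of patients show no microvascular obstruction at all, and
    the positive values are highly right-skewed).  Binary variables are
    Bernoulli at configurable prevalence.  Each variable is independently
    masked missing at its configured fraction.  Pure function of
    ``(config, seed)``.
    """
    if config.n_patients < 2:
        raise ValueError("n_patients must be >= 2")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_patients
    table: dict[str, np.ndarray] = {
        "patient_id": np.array([f"P{i:04d}" for i in range(n)], dtype=object)
    }

    for var, spec in CONTINUOUS_VARIABLES.items():
        values = rng.lognormal(np.log(spec["median"]), spec["sigma"], size=n)
        zero_frac = spec.get("zero_inflation")
        if zero_frac is not None:
            values[rng.random(n) < zero_frac] = 0.0
        frac = _missing_fraction(config, var, spec["missing"])
        values[rng.random(n) < frac] = np.nan
        table[var] = values

    tscore = rng.choice(np.arange(6), size=n, p=TSCORE_PROBS).astype(float)
    frac = _missing_fraction(config, "tscore", TSCORE_MISSING)
    tscore[rng.random(n) < frac] = np.nan
    table["tscore"] = tscore

    for var, spec in BINARY_VARIABLES.items():
        prevalence = float(config.prevalence.get(var, spec["prevalence"]))
        values = (rng.random(n) < prevalence).astype(float)
        frac = _missing_fraction(config, var, spec["missing"])
        values[rng.random(n) < frac] = np.nan
        table[var] = values

    return pd.DataFrame(table)


# ---------------------------------------------------------------------------
# spectra


def default_baseline_profile(bins: np.ndarray) -> np.ndarray:
    """Smooth, strictly positive mean-intensity profile over the bin range.

    A decaying small-molecule envelope with two broad humps - enough
    structure that unit-area normalisation and median-intensity rescaling
    behave as they would on real fingerprints, with no pretence of real
    ion chemistry.
    """
    b = np.asarray(bins, dtype=float)
    lo = b.min()
    profile = (
        np.exp(-(b - lo) / 150.0)
        + 0.5 * np.exp(-((b - 120.0) ** 2) / (2 * 40.0**2))
        + 0.3 * np.exp(-((b - 300.0) ** 2) / (2 * 80.0**2))
        + 0.05
    )
    return profile


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative log-normal noise with mean 1 and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), size=size)


def _effect_multipliers(
    labels: np.ndarray, effect: EffectSpec, config: SimulationConfig
) -> np.ndarray:
    """Per-patient, per-bin mean multiplier implied by the planted effect.

    Patients with a missing class label receive the class-0 (baseline)
    profile.
    """
    low, high = config.bin_range
    peaks = np.asarray(effect.effect_peaks, dtype=int)
    if peaks.size and (peaks.min() < low or peaks.max() > high):
        raise ValueError("effect_peaks must lie within the configured bin range")
    mult = np.ones((len(labels), config.n_bins))
    class1 = np.flatnonzero(labels == 1)
    mult[np.ix_(class1, peaks - low)] = effect.effect_size
    return mult


def expected_patient_means(
    clinical: pd.DataFrame,
    effect: EffectSpec,
    target_variable: str,
    config: SimulationConfig,
) -> np.ndarray:
    """Noise-free pre-normalisation mean spectrum per patient.

    Useful as ground truth: at zero noise the class-1 mean at each effect
    peak is exactly ``effect_size`` times the class-0 mean.
    """
    spec = get_task(target_variable)
    labels = binarize_variable(clinical[spec.variable], spec).labels
    baseline = (
        np.asarray(effect.baseline_profile, dtype=float)
        if effect.baseline_profile is not None
        else default_baseline_profile(config.bins)
    )
    if baseline.shape != (config.n_bins,):
        raise ValueError("baseline_profile length must equal the bin count")
    if np.any(baseline < 0):
        raise ValueError("baseline_profile must be nonnegative")
    return baseline * _effect_multipliers(labels, effect, config)


def generate_spectrum_matrix(
    clinical: pd.DataFrame,
    effect: EffectSpec,
    target_variable: str,
    config: SimulationConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Generate processed spectra with a class effect planted on the target.

    Per patient, ``replicates_per_sample`` replicate spectra are drawn
    around the patient mean (baseline x planted effect x biological
    variation) with multiplicative log-normal noise of CV ``noise_cv``;
    each replicate is normalised to unit area and the replicates are
    averaged - exactly the processed-spectrum convention of the
    preprocessing pipeline.  Rows align with the clinical table.
    """
    spec = get_task(target_variable)
    labels = binarize_variable(clinical[spec.variable], spec).labels
    if np.isnan(labels).all():
        raise ValueError(f"target variable {spec.variable!r} entirely missing")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    means = expected_patient_means(clinical, effect, target_variable, config)
    n, nbins = means.shape
    reps = config.replicates_per_sample

    bio = _lognormal_factors(rng, effect.biological_cv, (n, nbins))
    patient_means = means * bio
    replicate = patient_means[:, None, :] * _lognormal_factors(
        rng, effect.noise_cv, (n, reps, nbins)
    )
    replicate /= replicate.sum(axis=2, keepdims=True)
    matrix = replicate.mean(axis=1)
    return pd.DataFrame(
        matrix, index=pd.Index(clinical["patient_id"], name="sample_id"),
        columns=config.bins,
    )


# ---------------------------------------------------------------------------
# raw acquisitions


@dataclass
class SimulatedAcquisition:
    """A simulated scan stream plus its ground-truth segmentation."""

    raw: RawAcquisition
    truth: WindowSegmentation


def default_background_profile(bins: np.ndarray) -> np.ndarray:
    """Background (probe absent) spectral shape: a low decaying envelope."""
    b = np.asarray(bins, dtype=float)
    return np.exp(-(b - b.min()) / 120.0) + 0.02


def simulate_raw_acquisition(
    sample_spectrum: np.ndarray,
    config: SimulationConfig,
    seed: int | None = None,
    n_sample_windows: int = 5,
) -> SimulatedAcquisition:
    """Emit the scan stream an ASAP-MS acquisition of one sample would give.

    The stream contains, at one scan per ``scan_period``: a leading
    background window of ``background_duration``, then ``n_sample_windows``
    sample windows of ``sample_duration`` each followed by a background
    gap of ``gap_duration``.  Sample scans superimpose the (area-scaled)
    sample spectrum on the background so that their TIC is
    ``sample_rise`` times the background TIC; per-scan multiplicative
    noise has CV ``scan_noise_cv`` and peak m/z positions jitter within
    ``mz_jitter`` of the bin centre.  The ground-truth window boundaries
    are returned alongside for testing.
    """
    sample_spectrum = np.asarray(sample_spectrum, dtype=float)
    if np.any(sample_spectrum < 0):
        raise ValueError("sample spectrum must be nonnegative")
    if sample_spectrum.shape != (config.n_bins,):
        raise ValueError("sample spectrum length must equal the bin count")
    if sample_spectrum.sum() <= 0:
        raise ValueError("sample spectrum must have positive total intensity")
    for name in ("background_duration", "sample_duration", "gap_duration"):
        if getattr(config, name) < config.scan_period:
            raise ValueError(f"{name} is shorter than one scan period")

    rng = np.random.default_rng(config.seed if seed is None else seed)
    bins = config.bins.astype(float)
    background = default_background_profile(config.bins)
    background = background * (config.background_tic / background.sum())
    sample = sample_spectrum / sample_spectrum.sum()
    # sample-window scans sit at sample_rise x background TIC
    amplitude = (config.sample_rise - 1.0) * config.background_tic

    def n_scans(duration: float) -> int:
        return int(np.floor(duration / config.scan_period))

    segments: list[tuple[bool, int]] = [(False, n_scans(config.background_duration))]
    for _ in range(n_sample_windows):
        segments.append((True, n_scans(config.sample_duration)))
        segments.append((False, n_scans(config.gap_duration)))

    scans: list[Scan] = []
    sample_windows: list[tuple[int, int]] = []
    cursor = 0
    for is_sample, count in segments:
        if is_sample:
            sample_windows.append((cursor, cursor + count))
        for _ in range(count):
            mean = background + amplitude * sample if is_sample else background
            intensity = mean * _lognormal_factors(
                rng, config.scan_noise_cv, mean.shape
            )
            mz = bins + rng.uniform(-config.mz_jitter, config.mz_jitter, bins.shape)
            scans.append(
                Scan(time=len(scans) * config.scan_period, mz=mz,
                     intensity=intensity)
            )
        cursor += count

    truth = WindowSegmentation(
        background_window=(0, segments[0][1]), sample_windows=sample_windows
    )
    return SimulatedAcquisition(
        raw=RawAcquisition(scans=scans, metadata={"simulated": True}),
        truth=truth,
    )


def make_cohort(
    config: SimulationConfig | None = None,
    effect: EffectSpec | None = None,
    target_variable: str = "mvo",
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convenience wrapper: clinical table plus planted spectrum matrix."""
    config = config or SimulationConfig()
    effect = effect or EffectSpec()
    if seed is not None:
        config = replace(config, seed=seed)
    clinical = generate_clinical_table(config)
    spectra = generate_spectrum_matrix(clinical, effect, target_variable, config)
    return clinical, spectra
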