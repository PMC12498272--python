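"""Raw ASAP-MS acquisition processing.

An atmospheric solids analysis probe (ASAP) acquisition is a single
time-ordered stream of mass scans recorded continuously while the probe
is repeatedly loaded with sample and inserted into the ion source.  The
stream therefore interleaves *background* scans (probe absent) with a
small number of *sample-insertion windows* during which the total ion
count (TIC) rises sharply.

This module turns one such stream into a single processed spectrum:

1. segment the stream into the leading background window and the
   sample-insertion windows, from the rise in TIC
   (:func:`segment_acquisition`);
2. bin every scan to unit mass and average scans within each window
   (:func:`summarize_window`);
3. subtract the background spectrum from each sample window, clipping
   negative differences to zero (:func:`subtract_background`);
4. normalise each background-corrected replicate to unit area
   (:func:`normalize_unit_area`);
5. average the replicates into one spectrum per sample
   (:func:`average_replicates`).

:func:`process_acquisition` composes the five steps in that order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Default inclusive integer m/z bin range: 990 unit-mass bins.
DEFAULT_BIN_RANGE: tuple[int, int] = (11, 1000)
DEFAULT_RISE_FACTOR: float = 5.0
DEFAULT_MIN_WINDOW_SCANS: int = 5


class PreprocessingError(ValueError):
    """Raised when a processing stage cannot be completed.

    ``stage`` names the pipeline stage that failed.
    """

    def __init__(self, message: str, stage: str | None = None):
        self.stage = stage
        super().__init__(f"{stage}: {message}" if stage else message)


@dataclass
class Scan:
    """One mass scan: acquisition time plus centroided (m/z, intensity) pairs."""

    time: float
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("m/z and intensity arrays must have equal length")
        if np.any(self.intensity < 0):
            raise ValueError("scan intensities must be nonnegative")

    @property
    def tic(self) -> float:
        """Total ion count: the sum of all peak intensities in the scan."""
        return float(self.intensity.sum())


@dataclass
class RawAcquisition:
    """Time-ordered scan stream for one sample, with acquisition metadata."""

    scans: list[Scan]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = [s.time for s in self.scans]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("scan times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.scans)

    def tics(self) -> np.ndarray:
        return np.array([s.tic for s in self.scans], dtype=float)


@dataclass
class WindowSegmentation:
    """Half-open scan-index intervals for background and sample windows."""

    background_window: tuple[int, int]
    sample_windows: list[tuple[int, int]]

    @property
    def n_sample_windows(self) -> int:
        return len(self.sample_windows)


@dataclass
class ProcessedSpectrum:
    """A single area-normalised spectrum per sample.

    ``intensities`` is the replicate mean over unit-area replicates (itself
    unit-area, not re-normalised); ``per_bin_sd`` is the replicate
    population standard deviation (N divisor).
    """

    sample_id: str
    bin_labels: np.ndarray
    intensities: np.ndarray
    per_bin_sd: np.ndarray
    n_replicates: int


class BinnedSpectrum(NamedTuple):
    intensities: np.ndarray
    dropped_mass: float


class CorrectedSpectrum(NamedTuple):
    intensities: np.ndarray
    clip_mass: float


def bin_labels(bin_range: tuple[int, int] = DEFAULT_BIN_RANGE) -> np.ndarray:
    """Integer m/z bin labels for an inclusive bin range."""
    low, high = bin_range
    if high < low:
        raise ValueError("bin_range high must be >= low")
    return np.arange(low, high + 1)


def bin_to_unit_mass(
    mz: np.ndarray,
    intensity: np.ndarray,
    bin_range: tuple[int, int] = DEFAULT_BIN_RANGE,
) -> BinnedSpectrum:
    """Sum peak intensities into integer unit-mass bins.

    Bin ``k`` covers the half-open interval [k - 0.5, k + 0.5), i.e. peaks
    are assigned by round-half-up.  Peaks outside ``bin_range`` are dropped
    and their total intensity reported in ``dropped_mass`` so total
    intensity is conserved up to the reported drop.
    """
    mz = np.asarray(mz, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if mz.shape != intensity.shape:
        raise ValueError("m/z and intensity arrays must have equal length")
    if not np.all(np.isfinite(mz)):
        raise ValueError("m/z values must be finite")
    if np.any(intensity < 0):
        raise ValueError("negative intensity encountered in binning")
    low, high = bin_range
    # round-half-up: bin k covers [k - 0.5, k + 0.5)
    bins = np.floor(mz + 0.5).astype(int)
    inside = (bins >= low) & (bins <= high)
    out = np.zeros(high - low + 1, dtype=float)
    np.add.at(out, bins[inside] - low, intensity[inside])
    dropped = float(intensity[~inside].sum())
    return BinnedSpectrum(out, dropped)


def segment_acquisition(
    raw: RawAcquisition,
    rise_factor: float = DEFAULT_RISE_FACTOR,
    min_window_scans: int = DEFAULT_MIN_WINDOW_SCANS,
) -> WindowSegmentation:
    """Locate the background window and the sample-insertion windows.

    The acquisition must open with the probe absent, so the leading scans
    define the background TIC level.  A scan is *high* when its TIC is at
    least ``rise_factor`` times the median TIC of the leading background
    region; every maximal run of at least ``min_window_scans`` consecutive
    high scans is a sample window, shorter runs are rejected as transients.
    The background window extends from the first scan to the first high
    scan.
    """
    if len(raw) == 0:
        raise PreprocessingError("acquisition contains zero scans", stage="segment")
    if rise_factor <= 1:
        raise PreprocessingError("rise_factor must exceed 1", stage="segment")
    if len(raw) < min_window_scans:
        raise PreprocessingError(
            f"acquisition has {len(raw)} scans, fewer than min_window_scans="
            f"{min_window_scans}",
            stage="segment",
        )
    tics = raw.tics()
    baseline = float(np.median(tics[:min_window_scans]))
    threshold = rise_factor * baseline
    high = tics >= threshold
    if high[0]:
        raise PreprocessingError(
            "no background region identifiable: acquisition starts above the "
            "TIC rise threshold",
            stage="segment",
        )
    if high.all():
        raise PreprocessingError(
            "no background region identifiable: all scans high", stage="segment"
        )
    # maximal runs of consecutive high scans
    padded = np.concatenate([[False], high, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts, ends = edges[0::2], edges[1::2]
    windows = [
        (int(s), int(e)) for s, e in zip(starts, ends) if e - s >= min_window_scans
    ]
    bg_end = windows[0][0] if windows else len(raw)
    return WindowSegmentation(background_window=(0, bg_end), sample_windows=windows)


def summarize_window(
    raw: RawAcquisition,
    window: tuple[int, int],
    bin_range: tuple[int, int] = DEFAULT_BIN_RANGE,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin mean and population SD of the scans in a window.

    Each scan is first binned to unit mass so that all scans share a common
    m/z axis.  The standard deviation uses the N divisor (population SD).
    """
    start, end = window
    if end <= start:
        raise PreprocessingError("empty window", stage="summarize")
    stack = np.stack(
        [bin_to_unit_mass(s.mz, s.intensity, bin_range).intensities
         for s in raw.scans[start:end]]
    )
    return stack.mean(axis=0), stack.std(axis=0, ddof=0)


def subtract_background(
    signal: np.ndarray, background: np.ndarray
) -> CorrectedSpectrum:
    """Elementwise ``signal - background`` with negatives clipped to zero.

    Clipping keeps downstream feature scoring (which requires nonnegative
    intensities) valid; the total intensity removed by clipping is
    reported as ``clip_mass``.
    """
    signal = np.asarray(signal, dtype=float)
    background = np.asarray(background, dtype=float)
    if signal.shape != background.shape:
        raise PreprocessingError(
            "signal and background vectors have different lengths",
            stage="subtract",
        )
    diff = signal - background
    clip_mass = float(-diff[diff < 0].sum())
    return CorrectedSpectrum(np.clip(diff, 0.0, None), clip_mass)


def normalize_unit_area(spectrum: np.ndarray) -> np.ndarray:
    """Scale a nonnegative spectrum to unit area (sum of intensities = 1)."""
    spectrum = np.asarray(spectrum, dtype=float)
    total = spectrum.sum()
    if total <= 0:
        raise PreprocessingError(
            "all-zero spectrum: empty measurement cannot be normalised",
            stage="normalize",
        )
    return spectrum / total


def average_replicates(
    spectra: Sequence[np.ndarray],
    sample_id: str = "",
    bin_range: tuple[int, int] = DEFAULT_BIN_RANGE,
) -> ProcessedSpectrum:
    """Average unit-area replicate spectra into one processed spectrum.

    The arithmetic mean of unit-area vectors already has unit area, so the
    result is deliberately not re-normalised.  Replicate spread is
    reported as the per-bin population SD.
    """
    if len(spectra) == 0:
        raise PreprocessingError("no replicates to average", stage="average")
    stack = np.stack([np.asarray(s, dtype=float) for s in spectra])
    return ProcessedSpectrum(
        sample_id=sample_id,
        bin_labels=bin_labels(bin_range),
        intensities=stack.mean(axis=0),
        per_bin_sd=stack.std(axis=0, ddof=0),
        n_replicates=len(spectra),
    )


@dataclass
class ProcessParams:
    """Tunable parameters for :func:`process_acquisition`."""

    bin_range: tuple[int, int] = DEFAULT_BIN_RANGE
    rise_factor: float = DEFAULT_RISE_FACTOR
    min_window_scans: int = DEFAULT_MIN_WINDOW_SCANS
    expected_windows: int = 5


def process_acquisition(
    raw: RawAcquisition, params: ProcessParams | None = None
) -> ProcessedSpectrum:
    """Full acquisition-to-spectrum pipeline.

    Segments the scan stream, builds the background spectrum from the
    leading background window, background-corrects and unit-area-normalises
    each sample window, and averages the resulting replicates.  A warning
    is logged when the number of detected sample windows differs from
    ``params.expected_windows`` (five insertions is the standard protocol).
    """
    params = params or ProcessParams()
    seg = segment_acquisition(raw, params.rise_factor, params.min_window_scans)
    if not seg.sample_windows:
        raise PreprocessingError("no sample windows detected", stage="segment")
    if seg.n_sample_windows != params.expected_windows:
        logger.warning(
            "expected %d sample windows, found %d",
            params.expected_windows,
            seg.n_sample_windows,
        )
    try:
        background, _ = summarize_window(raw, seg.background_window, params.bin_range)
    except PreprocessingError:
        raise
    except ValueError as exc:  # pragma: no cover - defensive
        raise PreprocessingError(str(exc), stage="background") from exc
    replicates = []
    for window in seg.sample_windows:
        mean_spec, _ = summarize_window(raw, window, params.bin_range)
        corrected, _ = subtract_background(mean_spec, background)
        replicates.append(normalize_unit_area(corrected))
    return average_replicates(
        replicates,
        sample_id=str(raw.metadata.get("sample_id", "")),
        bin_range=params.bin_range,
    )
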