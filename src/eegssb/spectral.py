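"""Sensor-space spectral analysis: windowing, Fourier coefficients,
cross-spectra, and band / region averaging of log power.

The analysis chain mirrors standard quantitative-EEG practice: the recording
is cut into short quasi-stationary windows (2.56 s at 100 Hz, i.e. 256
samples), each window is Fourier transformed after mean removal, and the
per-window coefficient vectors are averaged into a Hermitian cross-spectral
matrix per frequency bin.  Only the first 48 harmonics (0.39-18.75 Hz) are
retained; log power is then summarised into the seven IFCN broad bands and
averaged over anatomical regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BandDefinition",
    "IFCN_BANDS",
    "BAND_NAMES",
    "SegmentedEeg",
    "FourierSet",
    "CrossSpectrum",
    "SpectralFeatureSet",
    "segment_windows",
    "fourier_coefficients",
    "cross_spectrum",
    "band_bins",
    "band_average",
    "region_average",
    "InsufficientDataError",
    "ConfigurationError",
]

#: Number of retained harmonics (k = 1..48 of a 256-point DFT at 100 Hz).
N_BINS = 48
#: Samples per analysis window (2.56 s at 100 Hz).
WINDOW_SAMPLES = 256

#: Tolerance (Hz) when matching bin centres against printed band edges.
#: The published edges are rounded to 0.1 Hz while the bin grid has a
#: resolution of 100/256 = 0.390625 Hz (e.g. the delta edge "3.9" is the
#: bin centre 3.90625); 0.01 Hz absorbs exactly that rounding.
EDGE_TOL = 0.01


class InsufficientDataError(ValueError):
    """Recording too short for the requested segmentation."""


class ConfigurationError(ValueError):
    """Invalid band / region configuration."""


@dataclass(frozen=True)
class BandDefinition:
    """A broad frequency band given by its printed edges in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise ConfigurationError(f"invalid band edges {self.lo}-{self.hi}")


#: The seven IFCN broad bands used throughout the analysis.
IFCN_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.5, 3.9),
    BandDefinition("low_theta", 4.0, 5.4),
    BandDefinition("high_theta", 5.8, 7.4),
    BandDefinition("low_alpha", 7.5, 9.4),
    BandDefinition("high_alpha", 9.5, 12.5),
    BandDefinition("low_beta", 12.8, 14.9),
    BandDefinition("high_beta", 15.0, 19.14),
)

BAND_NAMES: tuple[str, ...] = tuple(b.name for b in IFCN_BANDS)


@dataclass
class SegmentedEeg:
    """Non-overlapping analysis windows of a multichannel recording."""

    windows: np.ndarray  # (n_windows, n_sensors, n_window_samples)
    fs: float
    window_length: float

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.windows.shape[1]


@dataclass
class FourierSet:
    """Per-window complex Fourier coefficient vectors V_k(w).

    ``coeffs[k, b]`` is the length-``n_sensors`` coefficient vector of window
    ``k`` at frequency bin ``b`` (bins 1..48 of the window DFT; DC removed).
    """

    coeffs: np.ndarray  # (n_windows, n_bins, n_sensors) complex
    bin_freqs: np.ndarray  # (n_bins,) Hz
    fs: float
    n_window_samples: int


@dataclass
class CrossSpectrum:
    """Hermitian cross-spectral matrices, one per retained frequency bin."""

    matrices: np.ndarray  # (n_bins, n, n) complex Hermitian PSD
    bin_freqs: np.ndarray
    n_windows: int

    @property
    def n_channels(self) -> int:
        return self.matrices.shape[1]

    def log_power(self) -> np.ndarray:
        """Per-channel log power spectrum, shape (n_channels, n_bins)."""
        diag = np.einsum("bii->bi", self.matrices).real.T
        return np.log(diag)


@dataclass
class SpectralFeatureSet:
    """Subjects x (region, band) table of log source power with covariates."""

    values: pd.DataFrame  # columns: MultiIndex (region, band)
    ages: pd.Series
    groups: pd.Series

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError("feature table contains non-finite values")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate feature labels")
        if not (len(self.values) == len(self.ages) == len(self.groups)):
            raise ValueError("row count mismatch between features and covariates")

    @property
    def feature_labels(self) -> list[tuple[str, str]]:
        return list(self.values.columns)

    def to_long(self) -> pd.DataFrame:
        long = self.values.stack([0, 1], future_stack=True).rename("log_power").reset_index()
        long.columns = ["subject_id", "region", "band", "log_power"]
        return long


def segment_windows(
    eeg: np.ndarray, fs: float, window_length: float = 2.56
) -> SegmentedEeg:
    """Cut a (sensors x samples) recording into consecutive windows.

    Trailing samples that do not fill a complete window are discarded
    (floor rule): 61.44 s at 100 Hz yields exactly 24 windows.
    """
    eeg = np.asarray(eeg, dtype=float)
    if eeg.ndim != 2:
        raise ValueError("eeg must be a 2-D (sensors x samples) array")
    n_win_samples = int(round(fs * window_length))
    n_samples = eeg.shape[1]
    if n_samples < n_win_samples:
        raise InsufficientDataError(
            f"recording has {n_samples} samples; a window needs {n_win_samples}"
        )
    n_windows = n_samples // n_win_samples
    trimmed = eeg[:, : n_windows * n_win_samples]
    windows = trimmed.reshape(eeg.shape[0], n_windows, n_win_samples)
    windows = np.moveaxis(windows, 0, 1)  # (window, sensor, sample)
    return SegmentedEeg(windows=np.ascontiguousarray(windows), fs=fs, window_length=window_length)


def fourier_coefficients(
    seg: SegmentedEeg, n_bins: int = N_BINS, taper: str = "boxcar"
) -> FourierSet:
    """Per-window DFT after mean removal, truncated to bins 1..n_bins.

    Coefficients are scaled by 1/sqrt(fs * n) so that the periodogram
    |V|^2 integrates (times the bin width fs/n) to the window variance
    (Parseval).  ``taper`` may be "boxcar" (default) or "hann"; the Hann
    taper is normalised to preserve white-noise power.
    """
    x = seg.windows - seg.windows.mean(axis=-1, keepdims=True)
    n = x.shape[-1]
    if taper == "hann":
        w = np.hanning(n)
        w = w / np.sqrt(np.mean(w**2))
        x = x * w
    elif taper != "boxcar":
        raise ConfigurationError(f"unknown taper {taper!r}")
    if n_bins > n // 2:
        raise ConfigurationError(f"n_bins={n_bins} exceeds Nyquist bin {n // 2}")
    V = np.fft.rfft(x, axis=-1)  # (window, sensor, bin 0..n/2)
    V = V[..., 1 : n_bins + 1] / np.sqrt(seg.fs * n)
    coeffs = np.moveaxis(V, 1, 2)  # (window, bin, sensor)
    bin_freqs = np.arange(1, n_bins + 1) * seg.fs / n
    return FourierSet(
        coeffs=np.ascontiguousarray(coeffs),
        bin_freqs=bin_freqs,
        fs=seg.fs,
        n_window_samples=n,
    )


def cross_spectrum(fs_set: FourierSet) -> CrossSpectrum:
    """Sample cross-spectrum S_v(w) = (1/T) sum_k V_k(w) V_k(w)^H.

    One-sided density scale: diagonals are periodogram averages whose
    integral over frequency recovers (half) the signal variance per the
    coefficient scaling in :func:`fourier_coefficients`.
    """
    T = fs_set.coeffs.shape[0]
    if T < 2:
        warnings.warn("cross-spectrum from a single window is rank 1", stacklevel=2)
    V = fs_set.coeffs  # (T, bins, sensors)
    S = np.einsum("kbi,kbj->bij", V, V.conj()) / T
    S = 0.5 * (S + np.conj(np.swapaxes(S, 1, 2)))  # enforce exact Hermitian
    return CrossSpectrum(matrices=S, bin_freqs=fs_set.bin_freqs, n_windows=T)


def band_bins(
    bin_freqs: np.ndarray, band: BandDefinition, edge_tol: float = EDGE_TOL
) -> np.ndarray:
    """Indices of bins whose centre lies in [lo, hi] (with rounding tolerance)."""
    f = np.asarray(bin_freqs)
    mask = (f >= band.lo - edge_tol) & (f <= band.hi + edge_tol)
    return np.flatnonzero(mask)


def band_average(
    log_power: np.ndarray,
    bin_freqs: np.ndarray,
    bands: tuple[BandDefinition, ...] = IFCN_BANDS,
) -> np.ndarray:
    """Mean log power per band over the bins inside each band's edges.

    ``log_power`` has bins on its last axis.  Bins falling in the gaps
    between printed bands belong to no band and are dropped.
    """
    log_power = np.asarray(log_power)
    out = []
    for band in bands:
        idx = band_bins(bin_freqs, band)
        if idx.size == 0:
            raise ConfigurationError(f"band {band.name} contains no frequency bins")
        out.append(log_power[..., idx].mean(axis=-1))
    return np.stack(out, axis=-1)


def region_average(
    source_values: np.ndarray, region_map: "pd.Series | np.ndarray"
) -> tuple[np.ndarray, list[str]]:
    """Average rows (sources) of ``source_values`` into atlas regions.

    ``region_map`` assigns each source a region label; region order follows
    first appearance in the map.  Returns (regions x trailing-axes array,
    region labels).
    """
    labels = pd.Series(np.asarray(region_map, dtype=object))
    if labels.isna().any():
        raise ConfigurationError("unmapped source in region map")
    values = np.asarray(source_values)
    if values.shape[0] != len(labels):
        raise ConfigurationError(
            f"{values.shape[0]} sources but {len(labels)} region assignments"
        )
    region_order = list(dict.fromkeys(labels))
    out = np.stack(
        [values[(labels == r).to_numpy()].mean(axis=0) for r in region_order], axis=0
    )
    return out, region_order


def features_from_log_band_power(
    per_subject: np.ndarray,
    region_labels: list[str],
    bands: tuple[BandDefinition, ...],
    subject_ids: list[str],
    ages: np.ndarray,
    groups: list[str],
) -> SpectralFeatureSet:
    """Assemble a (subjects x (region, band)) feature table."""
    n_subj, n_reg, n_band = per_subject.shape
    cols = pd.MultiIndex.from_product(
        [region_labels, [b.name for b in bands]], names=["region", "band"]
    )
    values = pd.DataFrame(
        per_subject.reshape(n_subj, n_reg * n_band), index=subject_ids, columns=cols
    )
    return SpectralFeatureSet(
        values=values,
        ages=pd.Series(ages, index=subject_ids, name="age"),
        groups=pd.Series(groups, index=subject_ids, name="group"),
    )
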