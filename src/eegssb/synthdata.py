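"""Synthetic cohort generator.

Emulates the study conditions of a two-group (PEM vs. Control) resting-state
EEG cohort of school-aged children: 19-channel 10/20 recordings at 100 Hz,
61.44 s of eyes-closed data per subject, with group differences concentrated
in the alpha-band log source power of designated regions and an
age-dependent component of those differences.

Generative model
----------------
Each source carries one damped-oscillator AR(2) process per broad band
(centre frequency = band midpoint, half-bandwidth a fixed fraction of the
band width), scaled so its stationary variance equals the target band power.
Group effects enter multiplicatively: a PEM subject's designated
(region, band) power is scaled by ``exp(shift + slope * (age - age_center))``,
so the group difference in *log* band power equals the specified shift
exactly in expectation, and the age slope creates the age-by-feature
interaction the classifier is built to capture.  Sensor EEG is the lead
field projection of the sources plus white sensor noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from .spectral import (
    BAND_NAMES,
    IFCN_BANDS,
    BandDefinition,
    ConfigurationError,
    SpectralFeatureSet,
    band_average,
    features_from_log_band_power,
    fourier_coefficients,
    region_average,
    segment_windows,
)

__all__ = [
    "CohortSpec",
    "SyntheticSubject",
    "default_cohort_spec",
    "make_lead_field",
    "make_region_map",
    "simulate_subject",
    "simulate_cohort",
    "iter_cohort",
    "cohort_features",
]

#: 10/20 montage channel labels, in acquisition order.
CHANNELS_1020 = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T3", "T4", "T5", "T6", "Fz", "Cz", "Pz",
)

#: Nominal source band powers (amplitude-squared units), a 1/f-like profile
#: with an alpha prominence typical of eyes-closed recordings in children.
BASE_BAND_POWER = {
    "delta": 20.0,
    "low_theta": 12.0,
    "high_theta": 10.0,
    "low_alpha": 15.0,
    "high_alpha": 12.0,
    "low_beta": 5.0,
    "high_beta": 3.0,
}

#: AR(2) half-bandwidth as a fraction of the band width; 0.1 keeps >90% of
#: an oscillator's power inside its own band.
BANDWIDTH_SCALE = 0.1

_BURN_IN = 1000


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic cohort.

    ``effect_regions`` lists (region, band, shift, age_slope) tuples: the PEM
    group's log band power in that (region, band) is shifted by
    ``shift + age_slope * (age - age_center)``.
    """

    n_pem: int = 46
    n_ctrl: int = 62
    age_range: tuple[float, float] = (5.0, 11.0)
    n_sensors: int = 19
    n_sources: int = 50
    n_regions: int = 50
    fs: float = 100.0
    duration: float = 61.44
    effect_regions: tuple[tuple[str, str, float, float], ...] = ()
    sensor_noise_sd: float = 1.0
    subject_power_sd: float = 0.4
    global_power_sd: float = 0.25
    age_center: float = 8.0
    bandwidth_scale: float = BANDWIDTH_SCALE
    bands: tuple[BandDefinition, ...] = IFCN_BANDS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pem < 1 or self.n_ctrl < 1:
            raise ValueError("each group needs at least one subject")
        if self.n_sensors < 2 or self.n_sources < 1 or self.n_regions < 1:
            raise ValueError("non-positive or degenerate dimensions")
        if self.n_regions > self.n_sources:
            raise ValueError("cannot have more regions than sources")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range must be an increasing (low, high) pair")
        n_samples = self.fs * self.duration
        if abs(n_samples - round(n_samples)) > 1e-9:
            raise ValueError("duration x fs must be an integer sample count")
        band_names = {b.name for b in self.bands}
        regions = set(make_region_map(self.n_sources, self.n_regions))
        for region, band, _, _ in self.effect_regions:
            if band not in band_names:
                raise ConfigurationError(f"unknown band {band!r} in effect_regions")
            if region not in regions:
                raise ConfigurationError(f"unknown region {region!r} in effect_regions")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))


@dataclass
class SyntheticSubject:
    """One simulated subject: sensor EEG plus ground truth."""

    subject_id: str
    eeg: np.ndarray  # (n_sensors, n_samples), µV
    age: float
    group: str  # "PEM" or "Control"
    true_source_power: pd.DataFrame  # sources x bands, log power
    source_ts: np.ndarray | None = None  # (n_sources, n_samples)


def default_cohort_spec(seed: int = 0, **overrides) -> CohortSpec:
    """The default effect cohort: an alpha deficit with an age slope in one
    region, standing in for the posterior-cortex alpha reduction the
    classifier is designed to detect."""
    spec = CohortSpec(
        effect_regions=(("R24", "low_alpha", -0.5, -0.1),),
        seed=seed,
    )
    return replace(spec, **overrides) if overrides else spec


def make_region_map(n_sources: int, n_regions: int) -> list[str]:
    """Assign sources to regions in contiguous, near-equal blocks."""
    width = len(str(max(n_regions - 1, 1)))
    edges = np.linspace(0, n_sources, n_regions + 1).round().astype(int)
    labels = []
    for r in range(n_regions):
        labels.extend([f"R{r:0{width}d}"] * (edges[r + 1] - edges[r]))
    return labels


def make_lead_field(
    n_sensors: int, n_sources: int, seed: int, identity: bool = False
) -> np.ndarray:
    """Seeded Gaussian lead field with unit-norm columns.

    A single shared matrix stands in for the study's average template lead
    field.  ``identity=True`` returns the identity (requires a square
    problem) for controlled tests.
    """
    if n_sensors < 2 or n_sources < 1:
        raise ValueError("lead field dimensions must be positive (>= 2 sensors)")
    if identity:
        if n_sensors != n_sources:
            raise ValueError("identity lead field needs n_sensors == n_sources")
        return np.eye(n_sensors)
    rng = np.random.default_rng(seed)
    L = rng.standard_normal((n_sensors, n_sources))
    L /= np.linalg.norm(L, axis=0, keepdims=True)
    if np.linalg.matrix_rank(L) < min(n_sensors, n_sources):  # pragma: no cover
        raise RuntimeError("degenerate lead field draw")
    return L


def _ar2_coeffs(f0: float, half_bw: float, fs: float) -> tuple[float, float]:
    rho = np.exp(-np.pi * half_bw / fs)
    theta = 2 * np.pi * f0 / fs
    return 2 * rho * np.cos(theta), -(rho**2)


def _ar2_unit_variance(phi1: float, phi2: float) -> float:
    """Stationary variance of AR(2) with unit innovation variance."""
    return (1 - phi2) / ((1 + phi2) * ((1 - phi2) ** 2 - phi1**2))


def _effect_shift(
    spec: CohortSpec, region_of_source: np.ndarray, age: float
) -> np.ndarray:
    """Log-power shift per (source, band) applied to PEM subjects."""
    shifts = np.zeros((spec.n_sources, len(spec.bands)))
    band_index = {b.name: i for i, b in enumerate(spec.bands)}
    for region, band, base, slope in spec.effect_regions:
        mask = region_of_source == region
        shifts[mask, band_index[band]] += base + slope * (age - spec.age_center)
    return shifts


def simulate_subject(
    spec: CohortSpec,
    group: str,
    age: float,
    seed: int,
    keep_sources: bool = True,
) -> SyntheticSubject:
    """Simulate one subject's source dynamics and sensor EEG.

    Sources are sums of per-band AR(2) oscillators with log band powers
    drawn around the nominal profile (between-subject variability), shifted
    for PEM subjects according to ``spec.effect_regions``.  The sensor EEG is
    exactly ``L @ sources`` plus white noise of SD ``sensor_noise_sd``.
    """
    if group not in ("PEM", "Control"):
        raise ValueError(f"unknown group {group!r}")
    rng = np.random.default_rng(seed)
    n_src, n_samp = spec.n_sources, spec.n_samples
    region_of_source = np.array(make_region_map(spec.n_sources, spec.n_regions))

    # between-subject log-power variability: one global scale plus one
    # deviate per (region, band), shared by the sources of a region
    z_global = rng.normal(0.0, spec.global_power_sd)
    z_region = rng.normal(0.0, spec.subject_power_sd, size=(spec.n_regions, len(spec.bands)))
    region_index = pd.factorize(region_of_source)[0]
    log_power = np.log(
        np.array([BASE_BAND_POWER.get(b.name, 10.0) for b in spec.bands])
    )[None, :] + z_global + z_region[region_index]
    if group == "PEM":
        log_power = log_power + _effect_shift(spec, region_of_source, age)

    sources = np.zeros((n_src, n_samp))
    for bi, band in enumerate(spec.bands):
        f0 = 0.5 * (band.lo + band.hi)
        half_bw = spec.bandwidth_scale * (band.hi - band.lo)
        phi1, phi2 = _ar2_coeffs(f0, half_bw, spec.fs)
        unit_var = _ar2_unit_variance(phi1, phi2)
        innov = rng.standard_normal((n_src, n_samp + _BURN_IN))
        osc = signal.lfilter([1.0], [1.0, -phi1, -phi2], innov, axis=-1)[:, _BURN_IN:]
        amp = np.sqrt(np.exp(log_power[:, bi]) / unit_var)
        sources += amp[:, None] * osc

    L = make_lead_field(spec.n_sensors, spec.n_sources, seed=spec.seed)
    eeg = L @ sources
    if spec.sensor_noise_sd > 0:
        eeg = eeg + rng.normal(0.0, spec.sensor_noise_sd, size=eeg.shape)

    true_power = pd.DataFrame(
        log_power, index=[f"S{j}" for j in range(n_src)],
        columns=[b.name for b in spec.bands],
    )
    return SyntheticSubject(
        subject_id="",
        eeg=eeg,
        age=age,
        group=group,
        true_source_power=true_power,
        source_ts=sources if keep_sources else None,
    )


def _covariate_frame(spec: CohortSpec) -> pd.DataFrame:
    """Deterministic covariate table (ids, groups, ages, sex, handedness)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_pem + spec.n_ctrl
    groups = ["PEM"] * spec.n_pem + ["Control"] * spec.n_ctrl
    ages = rng.uniform(*spec.age_range, size=n)
    # demographic proportions mirror the study sample; no EEG effect attached
    sex = np.where(rng.random(n) < 0.574, "M", "F")
    hand = np.where(rng.random(n) < 0.065, "L", "R")
    subject_seeds = rng.integers(0, 2**31 - 1, size=n)
    return pd.DataFrame(
        {
            "subject_id": [f"sub{i:03d}" for i in range(n)],
            "group": groups,
            "age": ages,
            "sex": sex,
            "handedness": hand,
            "_seed": subject_seeds,
        }
    )


def iter_cohort(spec: CohortSpec, keep_sources: bool = True):
    """Yield (covariate row, SyntheticSubject) pairs, one subject at a time."""
    cov = _covariate_frame(spec)
    for _, row in cov.iterrows():
        subj = simulate_subject(
            spec, row["group"], float(row["age"]), int(row["_seed"]),
            keep_sources=keep_sources,
        )
        subj.subject_id = row["subject_id"]
        yield row, subj


def simulate_cohort(spec: CohortSpec) -> tuple[list[SyntheticSubject], pd.DataFrame]:
    """Materialise the full cohort and its covariate table."""
    cov = _covariate_frame(spec)
    subjects = [subj for _, subj in iter_cohort(spec)]
    return subjects, cov.drop(columns="_seed")


def cohort_features(spec: CohortSpec) -> SpectralFeatureSet:
    """Empirical region x band log power computed from the simulated source
    time series (windowed periodogram, band average, region average).

    This is the feature table a perfect source-imaging stage would deliver;
    it is the input for classifier experiments that are not about the
    inverse problem.
    """
    region_map = make_region_map(spec.n_sources, spec.n_regions)
    per_subject, ids, ages, groups = [], [], [], []
    for row, subj in iter_cohort(spec):
        seg = segment_windows(subj.source_ts, spec.fs)
        fset = fourier_coefficients(seg)
        power = np.mean(np.abs(fset.coeffs) ** 2, axis=0).T  # (sources, bins)
        log_band = band_average(np.log(power), fset.bin_freqs, spec.bands)
        region_vals, region_labels = region_average(log_band, region_map)
        per_subject.append(region_vals)
        ids.append(row["subject_id"])
        ages.append(row["age"])
        groups.append(row["group"])
    return features_from_log_band_power(
        np.stack(per_subject), region_labels, spec.bands,
        ids, np.array(ages), groups,
    )
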