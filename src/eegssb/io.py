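"""Delimited-text readers and writers for the pipeline's interchange formats.

Everything round-trips through plain TSV: EEG matrices (sensors x samples,
one row per channel), the lead field, the source-to-region map, covariate
tables, long-format feature tables and the stability-selection report.
EDF recordings can be read if the optional ``mne`` backend is installed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .spectral import SpectralFeatureSet

__all__ = [
    "save_matrix",
    "load_matrix",
    "save_region_map",
    "load_region_map",
    "save_covariates",
    "load_covariates",
    "save_features",
    "load_features",
    "save_stability_table",
    "read_eeg",
]


def save_matrix(path, M: np.ndarray) -> None:
    np.savetxt(path, np.asarray(M), delimiter="\t", fmt="%.12g")


def load_matrix(path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter="\t"))


def save_region_map(path, region_labels: list[str]) -> None:
    pd.DataFrame(
        {"source": range(len(region_labels)), "region": region_labels}
    ).to_csv(path, sep="\t", index=False)


def load_region_map(path) -> list[str]:
    df = pd.read_csv(path, sep="\t")
    if df["region"].isna().any():
        raise ValueError(f"{path}: unmapped source in region map")
    return df.sort_values("source")["region"].astype(str).tolist()


def save_covariates(path, cov: pd.DataFrame) -> None:
    cov.to_csv(path, sep="\t", index=False)


def load_covariates(path) -> pd.DataFrame:
    cov = pd.read_csv(path, sep="\t")
    required = {"subject_id", "group", "age"}
    missing = required - set(cov.columns)
    if missing:
        raise ValueError(f"{path}: covariate table lacks columns {sorted(missing)}")
    return cov


def save_features(path, features: SpectralFeatureSet) -> None:
    """Long-format table: subject_id, region, band, log_power."""
    features.to_long().to_csv(path, sep="\t", index=False)


def load_features(path, covariates: pd.DataFrame) -> SpectralFeatureSet:
    long = pd.read_csv(path, sep="\t")
    wide = long.pivot_table(
        index="subject_id", columns=["region", "band"], values="log_power", sort=False
    )
    cov = covariates.set_index("subject_id").loc[wide.index]
    return SpectralFeatureSet(
        values=wide, ages=cov["age"].astype(float), groups=cov["group"].astype(str)
    )


def save_stability_table(path, result) -> None:
    """Selection report mirroring the classifier table: region, band,
    selection percentages and final coefficients per term."""
    rows = []
    for (region, band) in result.freq_phi.index:
        fphi = result.freq_phi[(region, band)]
        fpsi = result.freq_psi[(region, band)]
        if fphi == 0 and fpsi == 0:
            continue
        rows.append(
            {
                "region": region,
                "band": band,
                "pct_phi": 100 * fphi,
                "pct_psi": 100 * fpsi,
                "phi": result.model.phi.get((region, band), 0.0),
                "psi": result.model.psi.get((region, band), 0.0),
                "stable_phi": (region, band, "base") in result.stable_set,
                "stable_psi": (region, band, "age_interaction") in result.stable_set,
            }
        )
    pd.DataFrame(rows).sort_values(
        ["pct_phi", "pct_psi"], ascending=False
    ).to_csv(path, sep="\t", index=False)


def read_eeg(path, channels: list[str] | None = None) -> np.ndarray:
    """Read a recording as a (sensors x samples) array.

    ``.edf`` files are read through mne (optional dependency); anything else
    is treated as a delimited text matrix with one row per channel.
    Channel labels are matched case-insensitively when given.
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        try:
            import mne
        except ImportError as exc:  # pragma: no cover
            raise ImportError(
                "reading EDF requires the optional mne dependency"
            ) from exc
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data() * 1e6  # volts -> microvolts
        if channels is not None:
            lower = [ch.lower() for ch in raw.ch_names]
            idx = [lower.index(ch.lower()) for ch in channels]
            data = data[idx]
        return data
    return load_matrix(path)
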