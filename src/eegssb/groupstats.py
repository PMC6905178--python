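"""Group contrasts and demographic-table statistics.

``contrast_map`` produces the per-(region, band) two-sample t map
(PEM minus Control) with a family-wise threshold from the permutation
distribution of the maximum |t| across the map — negative flags mark
features where the PEM group shows lower activity.  ``welch_t_from_summary``
and ``chi2_2x2`` recompute the demographic-table statistics from printed
summary values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectral import SpectralFeatureSet

__all__ = [
    "ContrastMap",
    "contrast_map",
    "welch_t_from_summary",
    "chi2_2x2",
    "age_correlation_report",
]


@dataclass
class ContrastMap:
    t_values: pd.Series  # per (region, band), PEM - Control orientation
    threshold: float  # permutation critical value on |t|
    significant: pd.Series  # -1 (PEM lower), 0, +1 (PEM higher)
    n_perm: int
    alpha: float

    def flagged(self) -> pd.Series:
        return self.significant[self.significant != 0]


def _pooled_t(X: np.ndarray, mask_a: np.ndarray) -> np.ndarray:
    """Vectorised pooled-variance two-sample t (group a minus group b)."""
    a, b = X[mask_a], X[~mask_a]
    na, nb = len(a), len(b)
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(pooled * (1 / na + 1 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a.mean(axis=0) - b.mean(axis=0)) / denom
    return np.nan_to_num(t)


def contrast_map(
    features: SpectralFeatureSet,
    n_perm: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> ContrastMap:
    """PEM-vs-Control t map thresholded by the max-|t| permutation null.

    The family-wise critical value is the (1 - alpha) quantile of the
    maximum absolute t across all features under ``n_perm`` random label
    permutations (strong FWE control).
    """
    groups = features.groups.to_numpy()
    X = features.values.to_numpy(dtype=float)
    mask_pem = groups == "PEM"
    if mask_pem.sum() < 2 or (~mask_pem).sum() < 2:
        raise ValueError("both groups need at least 2 subjects")
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if n_perm < 1 / alpha:
        raise ValueError(f"n_perm={n_perm} cannot resolve alpha={alpha}")
    t_obs = _pooled_t(X, mask_pem)
    rng = np.random.default_rng(seed)
    max_t = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(mask_pem)
        max_t[i] = np.abs(_pooled_t(X, perm)).max()
    threshold = float(np.quantile(max_t, 1 - alpha))
    sig = np.sign(t_obs) * (np.abs(t_obs) >= threshold)
    idx = pd.MultiIndex.from_tuples(features.feature_labels, names=["region", "band"])
    return ContrastMap(
        t_values=pd.Series(t_obs, index=idx),
        threshold=threshold,
        significant=pd.Series(sig.astype(int), index=idx),
        n_perm=n_perm,
        alpha=alpha,
    )


def welch_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> float:
    """Welch two-sample t from summary statistics: (mean2 - mean1) /
    sqrt(sd1^2/n1 + sd2^2/n2)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    return float((mean2 - mean1) / np.sqrt(sd1**2 / n1 + sd2**2 / n2))


def pooled_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> float:
    """Pooled-variance alternative to :func:`welch_t_from_summary`."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
    return float((mean2 - mean1) / np.sqrt(sp2 * (1 / n1 + 1 / n2)))


def chi2_2x2(a: int, b: int, c: int, d: int) -> float:
    """Pearson chi-square for a 2x2 table [[a, b], [c, d]], no continuity
    correction: N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))."""
    counts = np.array([a, b, c, d], dtype=float)
    if np.any(counts < 0) or counts.sum() <= 0:
        raise ValueError("counts must be non-negative with a positive total")
    n = counts.sum()
    margins = np.array([a + b, c + d, a + c, b + d], dtype=float)
    if np.any(margins == 0):
        raise ValueError("a zero margin makes the chi-square undefined")
    return float(n * (a * d - b * c) ** 2 / margins.prod())


def age_correlation_report(features: SpectralFeatureSet) -> pd.DataFrame:
    """Pearson correlation of each feature with age, as a screening report
    for the age dependence the age-adjusted design absorbs."""
    X = features.values.to_numpy(dtype=float)
    ages = features.ages.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    ac = ages - ages.mean()
    denom = np.sqrt((Xc**2).sum(axis=0) * (ac**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.nan_to_num(Xc.T @ ac / denom)
    return pd.DataFrame(
        {"r_age": r},
        index=pd.MultiIndex.from_tuples(features.feature_labels, names=["region", "band"]),
    )
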