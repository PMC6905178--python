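"""Resampled ROC evaluation of the stable classifier (SSB Step 2).

With the stable set frozen, the sample is repeatedly split 70/30; the
classifier coefficients are refitted on each training split (restricted to
the stable terms) and the held-out 30% is scored.  Per resample the full
AUC and the partial AUCs below false-positive ratios 0.1 and 0.2 are
recorded; the resampled values are summarised by Gaussian kernel densities
and their medians.

The partial AUC at FPR cutoff c is standardised after McClish so that a
chance classifier maps to 0.5 and a perfect one to 1.0:

    spAUC = 1/2 * [1 + (pAUC - c^2/2) / (c - c^2/2)].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.metrics import roc_curve as _sk_roc_curve

from . import ssb as _ssb
from .spectral import SpectralFeatureSet
from .ssb import SsbConfig, classification_score, stratified_split

__all__ = [
    "RocCurve",
    "RocSummary",
    "roc_curve",
    "auc",
    "pauc",
    "spauc",
    "evaluate_stable_classifier",
    "PAUC_CUTOFFS",
]

#: Screening-oriented false-positive-rate cutoffs for the partial AUC.
PAUC_CUTOFFS = (0.1, 0.2)


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.fpr) < 0) or np.any(np.diff(self.tpr) < 0):
            raise ValueError("ROC curve must be non-decreasing")


@dataclass
class RocSummary:
    auc_samples: np.ndarray
    pauc01_samples: np.ndarray
    pauc02_samples: np.ndarray
    spauc01_samples: np.ndarray
    spauc02_samples: np.ndarray
    densities: dict[str, tuple[np.ndarray, np.ndarray]]  # name -> (grid, density)
    medians: dict[str, float]
    subject_scores: pd.DataFrame  # held-out scores at the median-AUC resample


def roc_curve(scores, labels, positive: str = "Control") -> RocCurve:
    """Empirical ROC by threshold sweep; ties advance both rates together."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    present = set(np.unique(labels))
    if len(present) < 2:
        raise ValueError("both classes must be present to form a ROC curve")
    y = (labels == positive).astype(int)
    fpr, tpr, thr = _sk_roc_curve(y, scores, drop_intermediate=False)
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr)


def auc(curve: RocCurve) -> float:
    """Trapezoidal area under the full curve."""
    return float(np.trapezoid(curve.tpr, curve.fpr))


def pauc(curve: RocCurve, c: float) -> float:
    """Partial area under the curve for fpr in [0, c], with linear
    interpolation of the curve at the cutoff."""
    if not 0 < c <= 1:
        raise ValueError("fpr cutoff must lie in (0, 1]")
    fpr, tpr = curve.fpr, curve.tpr
    if c >= fpr[-1]:
        return auc(curve)
    j = int(np.searchsorted(fpr, c, side="right"))
    tpr_c = np.interp(c, fpr, tpr)
    xs = np.r_[fpr[:j], c]
    ys = np.r_[tpr[:j], tpr_c]
    return float(np.trapezoid(ys, xs))


def spauc(pauc_value: float, c: float) -> float:
    """McClish-standardised partial AUC: chance -> 0.5, perfect -> 1.0.

    Values below the chance line are clipped to chance with a warning (the
    transform is undefined there); values above the maximum ``c`` are
    invalid.
    """
    if not 0 < c <= 1:
        raise ValueError("fpr cutoff must lie in (0, 1]")
    a_min, a_max = c**2 / 2.0, c
    if pauc_value > a_max + 1e-12:
        raise ValueError(f"pAUC {pauc_value} exceeds its maximum {a_max}")
    if pauc_value < a_min:
        warnings.warn(
            "pAUC below the chance line; clipped to chance before "
            "standardisation",
            stacklevel=2,
        )
        pauc_value = a_min
    return float(0.5 * (1.0 + (min(pauc_value, a_max) - a_min) / (a_max - a_min)))


def _reflected_kde(samples: np.ndarray, lo: float = 0.0, hi: float = 1.0, n_grid: int = 256):
    """Gaussian KDE (Silverman bandwidth) with boundary reflection on [lo, hi]."""
    grid = np.linspace(lo, hi, n_grid)
    if np.std(samples) < 1e-12:
        density = np.zeros(n_grid)
        density[np.argmin(np.abs(grid - np.mean(samples)))] = 1.0 / (grid[1] - grid[0])
        return grid, density
    kde = gaussian_kde(samples, bw_method="silverman")
    density = kde(grid) + kde(2 * lo - grid) + kde(2 * hi - grid)
    return grid, density


def evaluate_stable_classifier(
    features: SpectralFeatureSet,
    stable_set: list[tuple],
    cfg: SsbConfig,
    n_resamples: int | None = None,
) -> RocSummary:
    """SSB Step 2: resampled out-of-sample ROC evaluation.

    ``stable_set`` must be fixed beforehand (no re-selection happens here);
    per resample the coefficients are refitted on the 70% training split
    restricted to the stable terms, with (gamma, lambda) by internal
    cross-validation, and the held-out 30% is scored.
    """
    if not stable_set:
        raise ValueError(
            "the stable set is empty: there is no classifier to evaluate "
            "(stability selection retained no feature)"
        )
    n_eval = cfg.n_resamples if n_resamples is None else n_resamples
    groups = features.groups.to_numpy()
    coding = cfg.coding
    y_all = np.array([coding[g] for g in groups])
    root = np.random.SeedSequence((cfg.seed, 0x5EB))  # independent of Step 1 streams
    children = root.spawn(n_eval)

    rows = []
    held_out: list[pd.DataFrame] = []
    for r in range(n_eval):
        rng = np.random.default_rng(children[r])
        tr, te = stratified_split(groups, cfg.train_fraction, rng)
        sub_train = _subset(features, tr)
        model = _ssb._fit_final(sub_train, stable_set, y_all[tr], cfg, rng)
        sub_test = _subset(features, te)
        scores = classification_score(sub_test.values, sub_test.ages.to_numpy(), model)
        curve = roc_curve(scores, groups[te])
        a = auc(curve)
        p1, p2 = pauc(curve, 0.1), pauc(curve, 0.2)
        rows.append((a, p1, p2))
        held_out.append(
            pd.DataFrame(
                {
                    "subject_id": sub_test.values.index,
                    "group": groups[te],
                    "score": scores,
                    "resample": r,
                }
            )
        )
    arr = np.array(rows)
    auc_s, p1_s, p2_s = arr[:, 0], arr[:, 1], arr[:, 2]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sp1 = np.array([spauc(v, 0.1) for v in p1_s])
        sp2 = np.array([spauc(v, 0.2) for v in p2_s])
    densities = {
        "auc": _reflected_kde(auc_s),
        "spauc01": _reflected_kde(sp1),
        "spauc02": _reflected_kde(sp2),
    }
    medians = {
        "auc": float(np.median(auc_s)),
        "pauc01": float(np.median(p1_s)),
        "pauc02": float(np.median(p2_s)),
        "spauc01": float(np.median(sp1)),
        "spauc02": float(np.median(sp2)),
    }
    # subject scores at the resample whose AUC is closest to the median
    j = int(np.argmin(np.abs(auc_s - medians["auc"])))
    return RocSummary(
        auc_samples=auc_s,
        pauc01_samples=p1_s,
        pauc02_samples=p2_s,
        spauc01_samples=sp1,
        spauc02_samples=sp2,
        densities=densities,
        medians=medians,
        subject_scores=held_out[j].drop(columns="resample"),
    )


def _subset(features: SpectralFeatureSet, idx: np.ndarray) -> SpectralFeatureSet:
    return SpectralFeatureSet(
        values=features.values.iloc[idx],
        ages=features.ages.iloc[idx],
        groups=features.groups.iloc[idx],
    )
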