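"""Stable Sparse Biomarker (SSB) detection.

Step 1 of the procedure: the cohort is repeatedly (default 500 times) and
randomly split 70/30; within each training split a univariate screen
("indfeat") winnows the feature set, an elastic net with an age-adjusted
design is fitted with (gamma, lambda) chosen by cross-validation, and the
identity of the nonzero coefficients is recorded.  Features selected in at
least 50% of the resamples form the *stable set*, on which a final model is
refitted on the full sample.

The age-adjusted design contains, for every candidate feature x_j = log s_j,
both the feature itself and its product with age, so each feature's
discriminative weight varies linearly with age:

    t_i = phi0 + x_i' phi + age_i * (x_i' psi) + alpha * age_i,
    d_j(age) = phi_j + age * psi_j.

Labels are coded Control = +1, PEM = -1 and fitted by penalised *squared
error* (the printed objective), not logistic deviance; a positive d_j(age)
therefore means higher power drives the score toward the control group.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet, enet_path
from sklearn.model_selection import StratifiedKFold

from .spectral import SpectralFeatureSet

__all__ = [
    "SsbConfig",
    "AgeDesign",
    "DesignScaler",
    "FittedClassifier",
    "StabilityResult",
    "indfeat_screen",
    "build_age_design",
    "elastic_net_fit",
    "stability_select",
    "classification_score",
    "stratified_split",
]

logger = logging.getLogger(__name__)

LABEL_CODING = {"Control": 1.0, "PEM": -1.0}


@dataclass(frozen=True)
class SsbConfig:
    """Resampling and regularisation settings for SSB Step 1."""

    n_resamples: int = 500
    train_fraction: float = 0.7
    stability_threshold: float = 0.5
    gamma_grid: tuple[float, ...] = (0.1, 0.5, 0.9)
    n_lambda: int = 20
    lambda_min_ratio: float = 0.01
    cv_folds: int = 10
    indfeat_percentile: float = 90.0
    indfeat_min: int = 10
    selection: str = "permutation"  # per-resample penalty rule: "permutation" | "cv"
    selection_gamma: float = 1.0
    n_perm_lambda: int = 100
    perm_quantile: float = 0.9
    seed: int = 0
    label_coding: tuple[tuple[str, float], ...] = (("Control", 1.0), ("PEM", -1.0))

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if not 0 <= self.stability_threshold <= 1:
            raise ValueError("stability_threshold must be in [0, 1]")
        if self.n_resamples < 1 or self.cv_folds < 2:
            raise ValueError("n_resamples >= 1 and cv_folds >= 2 required")
        if any(not 0 <= g <= 1 for g in self.gamma_grid):
            raise ValueError("gamma_grid values must lie in [0, 1]")
        if self.selection not in ("permutation", "cv"):
            raise ValueError("selection must be 'permutation' or 'cv'")
        if not 0 < self.perm_quantile < 1:
            raise ValueError("perm_quantile must lie in (0, 1)")

    @property
    def coding(self) -> dict[str, float]:
        return dict(self.label_coding)


def stratified_split(groups: np.ndarray, train_fraction: float, rng: np.random.Generator):
    """Random split preserving the class ratio; returns (train_idx, test_idx)."""
    groups = np.asarray(groups)
    train, test = [], []
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        idx = rng.permutation(idx)
        n_tr = int(round(train_fraction * idx.size))
        n_tr = min(max(n_tr, 1), idx.size - 1)
        train.extend(idx[:n_tr])
        test.extend(idx[n_tr:])
    return np.sort(np.array(train)), np.sort(np.array(test))


def indfeat_screen(
    X: np.ndarray,
    y: np.ndarray,
    percentile: float = 90.0,
    min_keep: int = 10,
) -> np.ndarray:
    """Univariate winnowing of candidate features.

    Scores each feature by the absolute two-sample t statistic between the
    classes and retains those above the given percentile of the |t|
    distribution, but always at least ``min_keep`` features (all of them if
    p < min_keep).  Constant features score 0.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("indfeat_screen needs exactly two classes")
    a, b = X[y == classes[0]], X[y == classes[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 subjects per class")
    na, nb = len(a), len(b)
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(pooled * (1 / na + 1 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (a.mean(axis=0) - b.mean(axis=0)) / denom, 0.0)
    t = np.abs(np.nan_to_num(t))
    cutoff = np.percentile(t, percentile)
    keep = np.flatnonzero(t >= cutoff)
    floor = min(min_keep, X.shape[1])
    if keep.size < floor:
        keep = np.argsort(t)[::-1][:floor]
    return np.sort(keep)


@dataclass
class DesignScaler:
    """Training-split standardisation statistics for base and interaction columns."""

    base_mean: np.ndarray
    base_sd: np.ndarray
    inter_mean: np.ndarray
    inter_sd: np.ndarray
    has_interaction: bool


@dataclass
class AgeDesign:
    """Standardised [base | age-interaction | age] design matrix."""

    Z: np.ndarray  # (n, n_cols)
    column_labels: list[tuple]  # (region, band, term); term of the age column is ("", "", "age_main")
    penalized: np.ndarray  # bool mask; the age main effect is unpenalized
    scaler: DesignScaler
    kept_base: np.ndarray  # indices of surviving base columns into the input X
    kept_inter: np.ndarray

    @property
    def n_base(self) -> int:
        return self.kept_base.size

    @property
    def n_inter(self) -> int:
        return self.kept_inter.size


def build_age_design(
    X: pd.DataFrame | np.ndarray,
    ages: np.ndarray,
    scaler: DesignScaler | None = None,
) -> AgeDesign:
    """Assemble the age-adjusted design [X | age*X | age].

    Interaction columns are the exact elementwise product of age and the raw
    feature columns.  Base and interaction columns are standardised (mean 0,
    SD 1) with statistics from the training split (pass the training
    ``scaler`` when transforming held-out rows); the age main effect is
    appended raw and left unpenalised.  Zero-variance columns are dropped
    with a log entry; if all ages are equal the interaction block is
    perfectly collinear with the base block and is dropped with a warning.
    """
    if isinstance(X, pd.DataFrame):
        labels = list(X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        labels = [(f"f{j}", "") for j in range(Xv.shape[1])]
    ages = np.asarray(ages, dtype=float)
    if not np.all(np.isfinite(ages)) or not np.all(np.isfinite(Xv)):
        raise ValueError("non-finite values in features or ages")
    inter = ages[:, None] * Xv

    if scaler is None:
        base_sd = Xv.std(axis=0, ddof=0)
        inter_sd = inter.std(axis=0, ddof=0)
        has_interaction = ages.std() > 0
        if not has_interaction:
            warnings.warn(
                "all ages equal: interaction block is collinear with the base "
                "block and was dropped",
                stacklevel=2,
            )
        scaler = DesignScaler(
            base_mean=Xv.mean(axis=0),
            base_sd=base_sd,
            inter_mean=inter.mean(axis=0),
            inter_sd=inter_sd,
            has_interaction=has_interaction,
        )
        dropped = np.flatnonzero(base_sd == 0)
        if dropped.size:
            logger.info("dropping %d zero-variance base column(s)", dropped.size)

    kept_base = np.flatnonzero(scaler.base_sd > 0)
    kept_inter = (
        np.flatnonzero(scaler.inter_sd > 0)
        if scaler.has_interaction
        else np.array([], dtype=int)
    )
    Zb = (Xv[:, kept_base] - scaler.base_mean[kept_base]) / scaler.base_sd[kept_base]
    cols = [Zb]
    col_labels = [(r, b, "base") for (r, b) in (labels[j] for j in kept_base)]
    if kept_inter.size:
        Zi = (inter[:, kept_inter] - scaler.inter_mean[kept_inter]) / scaler.inter_sd[
            kept_inter
        ]
        cols.append(Zi)
        col_labels += [(r, b, "age_interaction") for (r, b) in (labels[j] for j in kept_inter)]
    cols.append(ages[:, None])
    col_labels.append(("", "", "age_main"))
    Z = np.hstack(cols)
    penalized = np.array([lab[2] != "age_main" for lab in col_labels])
    return AgeDesign(
        Z=Z, column_labels=col_labels, penalized=penalized, scaler=scaler,
        kept_base=kept_base, kept_inter=kept_inter,
    )


def _partial_out(Z, y, penalized):
    """Project out the intercept and unpenalized columns (exact for squared loss)."""
    n = Z.shape[0]
    U = np.hstack([np.ones((n, 1)), Z[:, ~penalized]])
    Q, _ = np.linalg.qr(U)
    Zp = Z[:, penalized]
    Zt = Zp - Q @ (Q.T @ Zp)
    yt = y - Q @ (Q.T @ y)
    return Zt, yt, U


def _recover_unpenalized(U, y, Zp, beta):
    """Least-squares coefficients of the unpenalized block given beta."""
    resid = y - Zp @ beta
    coef, *_ = np.linalg.lstsq(U, resid, rcond=None)
    return coef  # [intercept, unpenalized...]


def kkt_residual(Zt, yt, beta, gamma, lam):
    """Max violation of the elastic-net stationarity conditions."""
    n = Zt.shape[0]
    g = Zt.T @ (Zt @ beta - yt) / n + lam * (1 - gamma) * beta
    thr = lam * gamma
    active = beta != 0
    res = np.where(
        active,
        np.abs(g + thr * np.sign(beta)),
        np.maximum(np.abs(g) - thr, 0.0),
    )
    return float(res.max()) if res.size else 0.0


def _cd_polish(Zt, yt, beta, gamma, lam, kkt_tol=1e-8, max_sweeps=2000):
    """Cyclic coordinate descent sweeps until the KKT residual is tiny."""
    n, p = Zt.shape
    col_ss = (Zt**2).sum(axis=0) / n + lam * (1 - gamma)
    thr = lam * gamma
    r = yt - Zt @ beta
    for _ in range(max_sweeps):
        if kkt_residual(Zt, yt, beta, gamma, lam) <= kkt_tol:
            break
        for j in range(p):
            if col_ss[j] == 0:
                continue
            rho = Zt[:, j] @ r / n + col_ss[j] * beta[j]
            new = np.sign(rho) * max(abs(rho) - thr, 0.0) / col_ss[j]
            if new != beta[j]:
                r += Zt[:, j] * (beta[j] - new)
                beta[j] = new
    return beta


def elastic_net_fit(
    design: AgeDesign | np.ndarray,
    y: np.ndarray,
    gamma: float,
    lam: float,
    penalized: np.ndarray | None = None,
    kkt_tol: float = 1e-8,
):
    """Minimise (1/2N) sum (y_i - phi0 - z_i'b)^2 + lam * P_gamma(b).

    The intercept and any unpenalized columns (the age main effect) are
    handled exactly by projection.  gamma = 0 is solved in closed form
    (ridge); gamma > 0 by coordinate descent, polished until the KKT
    residual is below ``kkt_tol``.  Returns (beta, intercept, unpen_coefs)
    where ``beta`` covers the penalized columns in design order.
    """
    if isinstance(design, AgeDesign):
        Z, penalized = design.Z, design.penalized
    else:
        Z = np.asarray(design, dtype=float)
        if penalized is None:
            penalized = np.ones(Z.shape[1], dtype=bool)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(Z)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite design or response")
    if not 0 <= gamma <= 1 or lam < 0:
        raise ValueError("gamma must be in [0, 1] and lam >= 0")
    n = Z.shape[0]
    Zt, yt, U = _partial_out(Z, y, penalized)
    p = Zt.shape[1]
    if lam == 0:
        beta, *_ = np.linalg.lstsq(Zt, yt, rcond=None)
    elif gamma == 0:
        beta = np.linalg.solve(Zt.T @ Zt / n + lam * np.eye(p), Zt.T @ yt / n)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = ElasticNet(
                alpha=lam, l1_ratio=gamma, fit_intercept=False,
                max_iter=10000, tol=1e-10,
            ).fit(Zt, yt)
        beta = _cd_polish(Zt, yt, est.coef_.copy(), gamma, lam, kkt_tol=kkt_tol)
    unpen = _recover_unpenalized(U, y, Z[:, penalized], beta)
    return beta, float(unpen[0]), np.asarray(unpen[1:], dtype=float)


def _lambda_path(Zt, yt, gamma, cfg: SsbConfig) -> np.ndarray:
    g = max(gamma, 0.01)
    lam_max = np.abs(Zt.T @ yt).max() / (Zt.shape[0] * g)
    lam_max = max(lam_max, 1e-10)
    return np.geomspace(lam_max, lam_max * cfg.lambda_min_ratio, cfg.n_lambda)


def permutation_lambda(
    Zt: np.ndarray,
    yt: np.ndarray,
    rng: np.random.Generator,
    n_perm: int = 100,
    quantile: float = 0.9,
) -> float:
    """Permutation-calibrated selection penalty.

    Returns the given quantile of the permutation null distribution of
    ``max_j |z_j' y_perm| / n`` — the smallest penalty at which no feature
    would enter the lasso path for a label-permuted response.  Holding the
    penalty at this level across resamples keeps the selection event
    comparable between resamples and controls family-wise false entry, which
    is what makes selection *frequencies* interpretable; a penalty tuned for
    prediction in each resample does not have this property.
    """
    n = Zt.shape[0]
    Y = np.empty((n, n_perm))
    for b in range(n_perm):
        Y[:, b] = rng.permutation(yt)
    max_cor = np.abs(Zt.T @ Y).max(axis=0) / n
    return float(np.quantile(max_cor, quantile))


def _cv_select(design: AgeDesign, y: np.ndarray, groups: np.ndarray, cfg: SsbConfig,
               rng: np.random.Generator) -> tuple[float, float]:
    """Choose (gamma, lambda) by CV-minimum squared error within the training split."""
    Z, penalized = design.Z, design.penalized
    Zt_full, yt_full, _ = _partial_out(Z, y, penalized)
    n_folds = min(cfg.cv_folds, np.bincount(pd.factorize(groups)[0]).min())
    n_folds = max(n_folds, 2)
    skf = StratifiedKFold(
        n_splits=n_folds, shuffle=True, random_state=int(rng.integers(2**31 - 1))
    )
    best = (np.inf, cfg.gamma_grid[0], 0.0)
    for gamma in cfg.gamma_grid:
        alphas = _lambda_path(Zt_full, yt_full, gamma, cfg)
        errs = np.zeros(len(alphas))
        for tr, va in skf.split(Z, groups):
            Zt, yt, U = _partial_out(Z[tr], y[tr], penalized)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, coefs, _ = enet_path(
                    Zt, yt, l1_ratio=max(gamma, 1e-6), alphas=alphas
                )
            # per-alpha unpenalized coefficients on the original scale
            Zp_tr = Z[tr][:, penalized]
            resid = y[tr][:, None] - Zp_tr @ coefs
            unpen, *_ = np.linalg.lstsq(U, resid, rcond=None)
            U_va = np.hstack([np.ones((len(va), 1)), Z[va][:, ~penalized]])
            pred = Z[va][:, penalized] @ coefs + U_va @ unpen
            errs += ((y[va][:, None] - pred) ** 2).sum(axis=0)
        j = int(np.argmin(errs))
        if errs[j] < best[0]:
            best = (errs[j], gamma, float(alphas[j]))
    return best[1], best[2]


@dataclass
class FittedClassifier:
    """Final classification equation on the raw log-power scale.

    ``phi`` and ``psi`` are indexed by (region, band); the score of subject i
    is ``phi0 + x_i' phi + age_i * (x_i' psi) + age_coef * age_i``.
    """

    feature_labels: list[tuple]
    phi0: float
    phi: pd.Series
    psi: pd.Series
    age_coef: float
    gamma: float
    lam: float

    def d(self, age: float) -> pd.Series:
        """Age-dependent coefficient d_j(age) = phi_j + age * psi_j per feature."""
        idx = self.phi.index.union(self.psi.index)
        return self.phi.reindex(idx, fill_value=0.0) + age * self.psi.reindex(
            idx, fill_value=0.0
        )


@dataclass
class StabilityResult:
    freq_phi: pd.Series  # per-feature selection frequency of the base term
    freq_psi: pd.Series  # per-feature selection frequency of the interaction term
    stable_set: list[tuple]  # (region, band, term) with frequency >= threshold
    model: FittedClassifier
    config: SsbConfig

    def stable_features(self) -> list[tuple]:
        """Unique (region, band) pairs appearing in the stable set."""
        return list(dict.fromkeys((r, b) for (r, b, _) in self.stable_set))

    def stable_at(self, threshold: float) -> list[tuple]:
        """Stable set at an alternative threshold (monotone in threshold)."""
        out = [(r, b, "base") for (r, b), f in self.freq_phi.items() if f >= threshold]
        out += [
            (r, b, "age_interaction")
            for (r, b), f in self.freq_psi.items()
            if f >= threshold
        ]
        return out


def _fit_final(
    features: SpectralFeatureSet,
    stable_set: list[tuple],
    y: np.ndarray,
    cfg: SsbConfig,
    rng: np.random.Generator,
) -> FittedClassifier:
    """Refit on the full sample restricted to the stable terms."""
    labels = features.feature_labels
    base_feats = [(r, b) for (r, b, t) in stable_set if t == "base"]
    inter_feats = [(r, b) for (r, b, t) in stable_set if t == "age_interaction"]
    used = list(dict.fromkeys(base_feats + inter_feats))
    ages = features.ages.to_numpy(dtype=float)
    n = len(ages)
    if not used:
        phi0 = float(np.mean(y))
        return FittedClassifier(
            feature_labels=labels, phi0=phi0,
            phi=pd.Series(dtype=float), psi=pd.Series(dtype=float),
            age_coef=0.0, gamma=cfg.gamma_grid[0], lam=0.0,
        )
    X = features.values[used]
    design = build_age_design(X, ages)
    # restrict to the stable terms only (plus the unpenalized age column)
    keep = [
        i
        for i, (r, b, t) in enumerate(design.column_labels)
        if t == "age_main"
        or (t == "base" and (r, b) in base_feats)
        or (t == "age_interaction" and (r, b) in inter_feats)
    ]
    design = replace(
        design,
        Z=design.Z[:, keep],
        column_labels=[design.column_labels[i] for i in keep],
        penalized=design.penalized[keep],
    )
    groups = features.groups.to_numpy()
    gamma, lam = _cv_select(design, y, groups, cfg, rng)
    beta, phi0, unpen = elastic_net_fit(design, y, gamma, lam)
    return _to_raw_classifier(design, X, beta, phi0, unpen, labels, gamma, lam)


def _to_raw_classifier(
    design: AgeDesign, X: pd.DataFrame, beta, phi0, unpen, labels, gamma, lam
) -> FittedClassifier:
    """Map standardised-scale coefficients back to the raw log-power scale."""
    pen_labels = [lab for lab, p in zip(design.column_labels, design.penalized) if p]
    sc = design.scaler
    phi, psi = {}, {}
    intercept = phi0
    cols = list(X.columns)
    for (r, b, t), coef in zip(pen_labels, beta):
        if coef == 0:
            continue
        j = cols.index((r, b))
        if t == "base":
            phi[(r, b)] = phi.get((r, b), 0.0) + coef / sc.base_sd[j]
            intercept -= coef * sc.base_mean[j] / sc.base_sd[j]
        else:
            psi[(r, b)] = psi.get((r, b), 0.0) + coef / sc.inter_sd[j]
            intercept -= coef * sc.inter_mean[j] / sc.inter_sd[j]
    age_coef = float(unpen[0]) if unpen.size else 0.0
    return FittedClassifier(
        feature_labels=labels, phi0=float(intercept),
        phi=pd.Series(phi, dtype=float), psi=pd.Series(psi, dtype=float),
        age_coef=age_coef, gamma=gamma, lam=lam,
    )


def stability_select(features: SpectralFeatureSet, cfg: SsbConfig) -> StabilityResult:
    """SSB Step 1: resampled selection frequencies and the stable-set refit."""
    groups = features.groups.to_numpy()
    coding = cfg.coding
    unknown = set(np.unique(groups)) - set(coding)
    if unknown:
        raise ValueError(f"groups {unknown} missing from label coding")
    if len(set(groups)) < 2:
        raise ValueError("both classes must be present")
    y_all = np.array([coding[g] for g in groups])
    Xall = features.values
    labels = features.feature_labels
    ages = features.ages.to_numpy(dtype=float)

    count_phi = pd.Series(0.0, index=pd.MultiIndex.from_tuples(labels))
    count_psi = pd.Series(0.0, index=pd.MultiIndex.from_tuples(labels))
    root = np.random.SeedSequence(cfg.seed)
    resample_seeds, final_seed = root.spawn(2)
    children = resample_seeds.spawn(cfg.n_resamples)

    for r in range(cfg.n_resamples):
        rng = np.random.default_rng(children[r])
        for attempt in range(20):
            tr, te = stratified_split(groups, cfg.train_fraction, rng)
            if len(set(groups[tr])) == 2 and len(set(groups[te])) == 2:
                break
            logger.info("resample %d redrawn: a class was absent from a split", r)
        X_tr = Xall.iloc[tr]
        y_tr, g_tr = y_all[tr], groups[tr]
        keep = indfeat_screen(
            X_tr.to_numpy(), g_tr, cfg.indfeat_percentile, cfg.indfeat_min
        )
        X_scr = X_tr.iloc[:, keep]
        design = build_age_design(X_scr, ages[tr])
        if cfg.selection == "permutation":
            gamma = cfg.selection_gamma
            Zt, yt, _ = _partial_out(design.Z, y_tr, design.penalized)
            lam = permutation_lambda(
                Zt, yt, rng, n_perm=cfg.n_perm_lambda, quantile=cfg.perm_quantile
            ) / max(gamma, 1e-6)
        else:
            gamma, lam = _cv_select(design, y_tr, g_tr, cfg, rng)
        beta, _, _ = elastic_net_fit(design, y_tr, gamma, lam)
        pen_labels = [
            lab for lab, p in zip(design.column_labels, design.penalized) if p
        ]
        for (reg, band, t), coef in zip(pen_labels, beta):
            if coef != 0.0:
                if t == "base":
                    count_phi[(reg, band)] += 1
                else:
                    count_psi[(reg, band)] += 1

    freq_phi = count_phi / cfg.n_resamples
    freq_psi = count_psi / cfg.n_resamples
    stable = [
        (r, b, "base") for (r, b), f in freq_phi.items() if f >= cfg.stability_threshold
    ] + [
        (r, b, "age_interaction")
        for (r, b), f in freq_psi.items()
        if f >= cfg.stability_threshold
    ]
    model = _fit_final(features, stable, y_all, cfg, np.random.default_rng(final_seed))
    return StabilityResult(
        freq_phi=freq_phi, freq_psi=freq_psi, stable_set=stable,
        model=model, config=cfg,
    )


def classification_score(
    x: pd.Series | pd.DataFrame, age, model: FittedClassifier
) -> np.ndarray | float:
    """Score t_i = phi0 + x'phi + age * x'psi + age_coef * age.

    ``x`` holds raw log band power indexed by (region, band).  Exponentiating
    (net of the intercept and age main effect) gives the product form
    prod_j s_j^{d_j(age)} — a data-driven generalisation of classical band
    power ratios.
    """
    single = isinstance(x, pd.Series)
    X = x.to_frame().T if single else x
    need = list(model.phi.index.union(model.psi.index))
    missing = [f for f in need if f not in X.columns]
    if missing:
        raise ValueError(f"feature(s) missing from input row: {missing}")
    ages = np.atleast_1d(np.asarray(age, dtype=float))
    base = X[list(model.phi.index)].to_numpy() @ model.phi.to_numpy() if len(model.phi) else 0.0
    inter = X[list(model.psi.index)].to_numpy() @ model.psi.to_numpy() if len(model.psi) else 0.0
    t = model.phi0 + base + ages * inter + model.age_coef * ages
    return float(t[0]) if single else np.asarray(t)
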