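"""End-to-end orchestration: synth -> spectra -> sourceimg -> features ->
ssb -> roceval -> groupstats, driven by one YAML configuration with a
reproducibility manifest.

Every stage writes its outputs under ``<out>/<stage>/``; a rerun with the
same configuration reproduces byte-identical feature tables and selection
frequencies.  Stages can be resumed individually from the previous stage's
files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as eio
from .groupstats import chi2_2x2, contrast_map, welch_t_from_summary
from .roceval import evaluate_stable_classifier
from .sourceimg import SourceModel, em_source_estimation, screen_sources, source_log_power
from .spectral import (
    IFCN_BANDS,
    cross_spectrum,
    features_from_log_band_power,
    fourier_coefficients,
    segment_windows,
)
from .ssb import SsbConfig, stability_select
from .synthdata import CohortSpec, iter_cohort, make_lead_field, make_region_map
from . import __version__

__all__ = ["run_pipeline", "load_config", "validate_config", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ("synth", "spectra", "sourceimg", "ssb", "roceval", "groupstats")

_COHORT_KEYS = {f.name for f in fields(CohortSpec)}
_SSB_KEYS = {f.name for f in fields(SsbConfig)}
_SOURCEIMG_KEYS = {"keep_fraction", "glasso_penalty", "max_iter", "tol", "mode"}
_ROCEVAL_KEYS = {"n_resamples"}
_GROUPSTATS_KEYS = {"n_perm", "alpha"}


class ConfigError(ValueError):
    """Configuration does not validate against the documented schema."""


def default_config(seed: int = 0) -> dict:
    return {
        "seed": seed,
        "synth": {
            "n_pem": 20,
            "n_ctrl": 20,
            "n_sources": 50,
            "n_regions": 10,
            "effect_regions": [["R2", "low_alpha", -0.5, -0.1]],
        },
        "sourceimg": {"keep_fraction": 0.1, "glasso_penalty": 0.1, "mode": "bcvareta"},
        "ssb": {"n_resamples": 100},
        "roceval": {"n_resamples": 100},
        "groupstats": {"n_perm": 1000, "alpha": 0.05},
    }


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    """Schema check; raises ConfigError listing every offending key."""
    problems = []
    if not isinstance(cfg, dict):
        raise ConfigError("configuration must be a mapping")
    known_top = set(STAGES) | {"seed"} - {"spectra"}
    for key in cfg:
        if key not in known_top:
            problems.append(f"unknown top-level key {key!r}")
    for section, allowed in [
        ("synth", _COHORT_KEYS),
        ("sourceimg", _SOURCEIMG_KEYS),
        ("ssb", _SSB_KEYS),
        ("roceval", _ROCEVAL_KEYS),
        ("groupstats", _GROUPSTATS_KEYS),
    ]:
        sub = cfg.get(section, {})
        if not isinstance(sub, dict):
            problems.append(f"section {section!r} must be a mapping")
            continue
        for key in sub:
            if key not in allowed:
                problems.append(f"unknown key {section}.{key}")
    ssb_cfg = cfg.get("ssb", {})
    thr = ssb_cfg.get("stability_threshold", 0.5)
    if not 0 <= thr <= 1:
        problems.append("ssb.stability_threshold must lie in [0, 1]")
    tf = ssb_cfg.get("train_fraction", 0.7)
    if not 0 < tf < 1:
        problems.append("ssb.train_fraction must lie in (0, 1)")
    mode = cfg.get("sourceimg", {}).get("mode", "bcvareta")
    if mode not in ("bcvareta", "oracle"):
        problems.append("sourceimg.mode must be 'bcvareta' or 'oracle'")
    if problems:
        raise ConfigError("invalid configuration: " + "; ".join(problems))


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _digest_dir(d: Path) -> dict[str, str]:
    return {p.name: _digest(p) for p in sorted(d.glob("*")) if p.is_file()}


def _cohort_spec(cfg: dict) -> CohortSpec:
    synth = dict(cfg.get("synth", {}))
    if "effect_regions" in synth:
        synth["effect_regions"] = tuple(tuple(e) for e in synth["effect_regions"])
    synth.setdefault("seed", cfg.get("seed", 0))
    return CohortSpec(**synth)


def run_pipeline(
    config: dict | str | Path,
    out_dir,
    from_stage: str = "synth",
) -> dict:
    """Run (or resume) the full experiment; returns the manifest dict."""
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if from_stage not in STAGES:
        raise ConfigError(f"unknown stage {from_stage!r}")
    start = STAGES.index(from_stage)
    manifest: dict = {
        "version": __version__,
        "config": config,
        "stages": {},
    }
    timings: dict[str, float] = {}
    spec = _cohort_spec(config)
    for stage in STAGES[start:]:
        t0 = time.time()
        logger.info("stage %s started", stage)
        _run_stage(stage, config, spec, out)
        timings[stage] = round(time.time() - t0, 3)
        manifest["stages"][stage] = {
            "outputs": _digest_dir(out / stage),
            "seconds": timings[stage],
        }
        logger.info("stage %s done in %.1fs", stage, timings[stage])
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _run_stage(stage: str, cfg: dict, spec: CohortSpec, out: Path) -> None:
    d = out / stage
    d.mkdir(parents=True, exist_ok=True)
    if stage == "synth":
        _stage_synth(spec, d)
    elif stage == "spectra":
        _stage_spectra(spec, out, d)
    elif stage == "sourceimg":
        _stage_sourceimg(cfg, spec, out, d)
    elif stage == "ssb":
        _stage_ssb(cfg, out, d)
    elif stage == "roceval":
        _stage_roceval(cfg, out, d)
    elif stage == "groupstats":
        _stage_groupstats(cfg, out, d)


def _stage_synth(spec: CohortSpec, d: Path) -> None:
    L = make_lead_field(spec.n_sensors, spec.n_sources, seed=spec.seed)
    eio.save_matrix(d / "leadfield.tsv", L)
    eio.save_region_map(d / "regions.tsv", make_region_map(spec.n_sources, spec.n_regions))
    rows = []
    for row, subj in iter_cohort(spec, keep_sources=False):
        eio.save_matrix(d / f"{row['subject_id']}_eeg.tsv", subj.eeg)
        rows.append(row.drop("_seed"))
    eio.save_covariates(d / "covariates.tsv", pd.DataFrame(rows))


def _stage_spectra(spec: CohortSpec, out: Path, d: Path) -> None:
    synth = out / "synth"
    if not (synth / "covariates.tsv").exists():
        raise FileNotFoundError("spectra stage needs the synth stage outputs")
    cov = eio.load_covariates(synth / "covariates.tsv")
    for sid in cov["subject_id"]:
        eeg = eio.read_eeg(synth / f"{sid}_eeg.tsv")
        seg = segment_windows(eeg, spec.fs)
        cs = cross_spectrum(fourier_coefficients(seg))
        np.savez(
            d / f"{sid}_xspec.npz",
            matrices=cs.matrices,
            bin_freqs=cs.bin_freqs,
            n_windows=cs.n_windows,
        )


def _stage_sourceimg(cfg: dict, spec: CohortSpec, out: Path, d: Path) -> None:
    from .spectral import CrossSpectrum

    sicfg = cfg.get("sourceimg", {})
    synth = out / "synth"
    spectra = out / "spectra"
    cov = eio.load_covariates(synth / "covariates.tsv")
    L = eio.load_matrix(synth / "leadfield.tsv")
    region_map = eio.load_region_map(synth / "regions.tsv")
    per_subject = []
    for sid in cov["subject_id"]:
        z = np.load(spectra / f"{sid}_xspec.npz")
        cs = CrossSpectrum(
            matrices=z["matrices"], bin_freqs=z["bin_freqs"], n_windows=int(z["n_windows"])
        )
        scr = screen_sources(cs, L, keep_fraction=sicfg.get("keep_fraction", 0.1))
        model = SourceModel(
            L=L, active_set=scr.active_set,
            glasso_penalty=sicfg.get("glasso_penalty", 0.1),
        )
        fitted = em_source_estimation(
            cs, model,
            max_iter=sicfg.get("max_iter", 50), tol=sicfg.get("tol", 1e-6),
        )
        vals, region_labels = source_log_power(fitted, cs.bin_freqs, IFCN_BANDS, region_map)
        per_subject.append(vals)
    features = features_from_log_band_power(
        np.stack(per_subject), region_labels, IFCN_BANDS,
        cov["subject_id"].tolist(), cov["age"].to_numpy(), cov["group"].tolist(),
    )
    eio.save_features(d / "features.tsv", features)


def _load_stage_features(out: Path):
    cov = eio.load_covariates(out / "synth" / "covariates.tsv")
    return eio.load_features(out / "sourceimg" / "features.tsv", cov)


def _ssb_config(cfg: dict) -> SsbConfig:
    ssb_cfg = dict(cfg.get("ssb", {}))
    if "gamma_grid" in ssb_cfg:
        ssb_cfg["gamma_grid"] = tuple(ssb_cfg["gamma_grid"])
    ssb_cfg.setdefault("seed", cfg.get("seed", 0))
    return SsbConfig(**ssb_cfg)


def _stage_ssb(cfg: dict, out: Path, d: Path) -> None:
    features = _load_stage_features(out)
    result = stability_select(features, _ssb_config(cfg))
    eio.save_stability_table(d / "stability.tsv", result)
    with open(d / "stable_set.json", "w") as fh:
        json.dump({"stable_set": [list(t) for t in result.stable_set]}, fh, indent=2)
    with open(d / "model.json", "w") as fh:
        json.dump(
            {
                "phi0": result.model.phi0,
                "age_coef": result.model.age_coef,
                "gamma": result.model.gamma,
                "lambda": result.model.lam,
                "phi": {f"{r}|{b}": v for (r, b), v in result.model.phi.items()},
                "psi": {f"{r}|{b}": v for (r, b), v in result.model.psi.items()},
            },
            fh,
            indent=2,
        )


def _stage_roceval(cfg: dict, out: Path, d: Path) -> None:
    features = _load_stage_features(out)
    with open(out / "ssb" / "stable_set.json") as fh:
        stable = [tuple(t) for t in json.load(fh)["stable_set"]]
    summary_path = d / "summary.json"
    if not stable:
        with open(summary_path, "w") as fh:
            json.dump({"note": "stable set empty; evaluation skipped"}, fh)
        logger.warning("stable set empty; ROC evaluation skipped")
        return
    summary = evaluate_stable_classifier(
        features, stable, _ssb_config(cfg),
        n_resamples=cfg.get("roceval", {}).get("n_resamples"),
    )
    pd.DataFrame(
        {
            "auc": summary.auc_samples,
            "pauc01": summary.pauc01_samples,
            "pauc02": summary.pauc02_samples,
            "spauc01": summary.spauc01_samples,
            "spauc02": summary.spauc02_samples,
        }
    ).to_csv(d / "resamples.tsv", sep="\t", index=False)
    summary.subject_scores.to_csv(d / "subject_scores.tsv", sep="\t", index=False)
    for name, (grid, dens) in summary.densities.items():
        pd.DataFrame({name: grid, "density": dens}).to_csv(
            d / f"density_{name}.tsv", sep="\t", index=False
        )
    with open(summary_path, "w") as fh:
        json.dump(summary.medians, fh, indent=2)


def _stage_groupstats(cfg: dict, out: Path, d: Path) -> None:
    gcfg = cfg.get("groupstats", {})
    features = _load_stage_features(out)
    cmap = contrast_map(
        features,
        n_perm=gcfg.get("n_perm", 2000),
        alpha=gcfg.get("alpha", 0.05),
        seed=cfg.get("seed", 0),
    )
    tab = pd.DataFrame(
        {
            "t": cmap.t_values,
            "flagged": cmap.significant != 0,
            "sign": cmap.significant,
        }
    )
    tab.to_csv(d / "contrast.tsv", sep="\t")
    cov = eio.load_covariates(out / "synth" / "covariates.tsv")
    demo = _demographics(cov)
    with open(d / "demographics.json", "w") as fh:
        json.dump(demo | {"t_threshold": cmap.threshold}, fh, indent=2)


def _demographics(cov: pd.DataFrame) -> dict:
    """Demographic-table statistics of the cohort (chi2 for sex and
    handedness, Welch t for age by sex)."""
    pem = cov[cov["group"] == "PEM"]
    ctrl = cov[cov["group"] == "Control"]
    out: dict = {"n_pem": len(pem), "n_ctrl": len(ctrl)}
    try:
        out["chi2_sex"] = chi2_2x2(
            (pem["sex"] == "M").sum(), (pem["sex"] == "F").sum(),
            (ctrl["sex"] == "M").sum(), (ctrl["sex"] == "F").sum(),
        )
        out["chi2_handedness"] = chi2_2x2(
            (pem["handedness"] == "L").sum(), (pem["handedness"] == "R").sum(),
            (ctrl["handedness"] == "L").sum(), (ctrl["handedness"] == "R").sum(),
        )
    except ValueError:
        out["chi2_sex"] = out["chi2_handedness"] = None
    for sex in ("M", "F"):
        a, b = pem[pem["sex"] == sex]["age"], ctrl[ctrl["sex"] == sex]["age"]
        if len(a) >= 2 and len(b) >= 2 and a.std() > 0 and b.std() > 0:
            out[f"welch_t_age_{sex}"] = welch_t_from_summary(
                a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b)
            )
    return out
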