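"""End-to-end orchestration: simulate -> fit -> segment -> extract -> stratify -> analyze.

One JSON config drives every stage; artifacts land in stage-numbered
subfolders with a manifest carrying the config hash, seeds and library
versions so a run can be reproduced (and partially re-used) from the
manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clinical import stratify_frame
from .features import FEATURE_NAMES, FeatureConfig, extract_all
from .segment import propagate_mask, random_walker_segment
from .stats import (
    delong_compare,
    roc_with_youden,
    stepwise_logistic,
    univariate_compare,
)
from .synthetic import CohortSpec, PhantomSpec, generate_cohort, generate_phantom
from .t1map import fit_t1_vfa

log = logging.getLogger("t1liver.pipeline")

STAGES = ("simulate", "fit", "segment", "extract", "stratify", "analyze")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Config for one pipeline run; everything serialisable to JSON."""

    rng_seed: int = 0
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    cohort: dict = field(default_factory=dict)  # CohortSpec overrides
    phantom: dict = field(default_factory=dict)  # PhantomSpec overrides
    beta: float = 130.0
    solver_tol: float = 1e-5
    n_levels: int = 32
    stepwise_direction: str = "backward"
    save_volumes: bool = False

    def __post_init__(self) -> None:
        for s in self.stages:
            if s not in STAGES:
                raise ValueError(f"unknown stage {s!r}")
        self.stages = {s: bool(self.stages.get(s, True)) for s in STAGES}

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        # stage toggles and output preferences do not affect the artifacts,
        # so they stay out of the hash: toggling a stage must still match
        # the cached manifest
        d = {k: v for k, v in self.to_dict().items() if k not in ("stages", "save_volumes")}
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _versions() -> dict[str, str]:
    import nibabel
    import scipy
    import statsmodels

    return {
        "t1liver": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "nibabel": nibabel.__version__,
        "statsmodels": statsmodels.__version__,
    }


def _build_specs(config: RunConfig) -> tuple[CohortSpec, PhantomSpec]:
    base = PhantomSpec(**{"rng_seed": config.rng_seed, **config.phantom})
    cohort_kw = dict(config.cohort)
    cohort_kw.setdefault("rng_seed", config.rng_seed)
    return CohortSpec(phantom_base=base, **cohort_kw), base


def _extract_features(
    cohort: pd.DataFrame,
    phantoms: list[PhantomSpec],
    config: RunConfig,
    out: Path,
) -> pd.DataFrame:
    fc = FeatureConfig(n_levels=config.n_levels)
    rows = []
    vol_dir = out / "02_volumes"
    for (_, subj), pspec in zip(cohort.iterrows(), phantoms):
        bundle = generate_phantom(pspec)
        t1 = fit_t1_vfa(bundle.spgr_low, bundle.spgr_high, bundle.b1_map, bundle.acq)
        seg = random_walker_segment(
            bundle.spgr_high, bundle.seeds, beta=config.beta, solver_tol=config.solver_tol
        )
        mask = propagate_mask(seg.mask, t1)
        fv = extract_all(t1, mask, fc)
        rows.append({"subject_id": subj["subject_id"], **fv.as_dict(),
                     "config_hash": fv.config_hash})
        if config.save_volumes:
            sub = vol_dir / str(subj["subject_id"])
            sub.mkdir(parents=True, exist_ok=True)
            t1.to_nifti(sub / "t1.nii.gz")
            mask.to_nifti(sub / "mask.nii.gz")
    return pd.DataFrame(rows)


def _analyze(features: pd.DataFrame, risk: pd.DataFrame, config: RunConfig, out: Path) -> dict:
    merged = features.merge(risk[["subject_id", "binary", "fib4", "nfs", "lsm_median"]],
                            on="subject_id")
    y = merged["binary"].to_numpy(dtype=int)

    uni_rows = []
    significant = []
    for name in FEATURE_NAMES:
        vals = merged[name]
        lo, hi = vals[y == 0], vals[y == 1]
        if lo.nunique() <= 1 and hi.nunique() <= 1:
            continue
        res = univariate_compare(lo, hi)
        uni_rows.append({
            "feature": name,
            "low_mean": lo.mean(), "low_sd": lo.std(ddof=1),
            "high_mean": hi.mean(), "high_sd": hi.std(ddof=1),
            "test": res.test, "p": res.p,
        })
        if res.p < 0.05:
            significant.append(name)
    uni = pd.DataFrame(uni_rows)
    uni.to_csv(out / "univariate.csv", index=False)

    model_feats = significant or [r["feature"] for r in uni_rows]
    model = stepwise_logistic(merged[model_feats], y, direction=config.stepwise_direction)
    model_scores = model.predict(merged)

    roc_rows = []
    for name in model_feats:
        scores = merged[name].to_numpy(dtype=float)
        # orient so that higher score = positive class (AUC >= 0.5 convention
        # is NOT forced; the per-feature direction is reported as-is)
        r = roc_with_youden(scores, y)
        roc_rows.append({"parameter": name, "auc": r.auc, "ci_low": r.ci_low,
                         "ci_high": r.ci_high, "cutoff": r.cutoff,
                         "youden": r.youden, "sensitivity": r.sensitivity,
                         "specificity": r.specificity})
    rm = roc_with_youden(model_scores, y)
    roc_rows.append({"parameter": "multivariate_model", "auc": rm.auc,
                     "ci_low": rm.ci_low, "ci_high": rm.ci_high, "cutoff": rm.cutoff,
                     "youden": rm.youden, "sensitivity": rm.sensitivity,
                     "specificity": rm.specificity})
    roc_table = pd.DataFrame(roc_rows)
    roc_table.to_csv(out / "roc.csv", index=False)

    cmp_rows = []
    for name in model_feats + ["fib4", "nfs", "lsm_median"]:
        d = delong_compare(model_scores, merged[name].to_numpy(dtype=float), y)
        cmp_rows.append({"parameter": name, "auc_difference": d.difference,
                         "ci_low": d.ci_low, "ci_high": d.ci_high, "z": d.z, "p": d.p})
    pd.DataFrame(cmp_rows).to_csv(out / "delong.csv", index=False)

    summary = {
        "selected_features": model.selected_features,
        "coefficients": model.coefficients,
        "intercept": model.intercept,
        "hosmer_lemeshow_p": model.hl_p,
        "separation": model.separation,
        "model_auc": rm.auc,
        "significant_features": significant,
    }
    with open(out / "model.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return summary


def run(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the enabled stages; returns the manifest dict.

    Stage artifacts persist under ``out_dir``; a stage failure aborts with
    the stage name while keeping completed artifacts on disk.  Disabled
    stages re-use cached artifacts when the manifest's config hash matches.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    chash = config.config_hash()

    cached = {}
    if manifest_path.exists():
        with open(manifest_path) as fh:
            cached = json.load(fh)

    manifest = {
        "config": config.to_dict(),
        "config_hash": chash,
        "seed": config.rng_seed,
        "versions": _versions(),
        "stages": {},
    }

    cohort_csv = out / "01_cohort" / "cohort.csv"
    phantoms_json = out / "01_cohort" / "phantoms.json"
    features_csv = out / "04_features" / "features.csv"
    risk_csv = out / "05_clinical" / "risk.csv"
    stats_dir = out / "06_stats"

    cache_ok = cached.get("config_hash") == chash

    def _stage(name: str):
        def deco(fn):
            if not config.stages[name]:
                if not cache_ok:
                    raise PipelineError(
                        name, RuntimeError("stage disabled but no matching cached artifacts")
                    )
                manifest["stages"][name] = "cached"
                return
            try:
                fn()
                manifest["stages"][name] = "ok"
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - annotate the stage
                manifest["stages"][name] = f"failed: {exc}"
                with open(manifest_path, "w") as fh:
                    json.dump(manifest, fh, indent=2, default=str)
                raise PipelineError(name, exc) from exc
        return deco

    cohort_spec, _ = _build_specs(config)
    state: dict = {}

    @_stage("simulate")
    def _simulate():
        cohort, phantoms = generate_cohort(cohort_spec)
        cohort_csv.parent.mkdir(parents=True, exist_ok=True)
        cohort.to_csv(cohort_csv, index=False)
        with open(phantoms_json, "w") as fh:
            json.dump([dataclasses.asdict(p) for p in phantoms], fh, default=str)
        state["cohort"], state["phantoms"] = cohort, phantoms

    if "cohort" not in state:
        state["cohort"] = pd.read_csv(cohort_csv)
        _, state["phantoms"] = generate_cohort(cohort_spec)

    # fit/segment/extract run per subject inside one loop; the three stage
    # toggles gate the loop as a block (their artifacts are the features CSV)
    @_stage("extract")
    def _extract():
        features_csv.parent.mkdir(parents=True, exist_ok=True)
        feats = _extract_features(state["cohort"], state["phantoms"], config, out)
        feats.to_csv(features_csv, index=False)
        state["features"] = feats

    if "features" not in state and features_csv.exists():
        state["features"] = pd.read_csv(features_csv)
    manifest["stages"].setdefault("fit", manifest["stages"].get("extract", "cached"))
    manifest["stages"].setdefault("segment", manifest["stages"].get("extract", "cached"))

    @_stage("stratify")
    def _stratify():
        risk_csv.parent.mkdir(parents=True, exist_ok=True)
        risk = stratify_frame(state["cohort"])
        risk.to_csv(risk_csv, index=False)
        state["risk"] = risk

    if "risk" not in state and risk_csv.exists():
        state["risk"] = pd.read_csv(risk_csv)

    @_stage("analyze")
    def _analyze_stage():
        stats_dir.mkdir(parents=True, exist_ok=True)
        state["summary"] = _analyze(state["features"], state["risk"], config, stats_dir)

    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
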