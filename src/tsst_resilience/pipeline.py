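"""End-to-end pipeline: configuration, schema-validated IO, manifests.

Sequences the stages simulate -> impute -> features -> trajectory GAMs ->
composites -> validity -> predictor selection, writing every artifact as
delimited text / JSON with a manifest of seeds and content digests.
Identical configuration and seed produce byte-identical outputs.
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
import yaml

from . import __version__
from .cohort import (
    PREDICTOR_NAMES,
    CohortConfig,
    SyntheticCohort,
    generate_cohort,
    inject_missingness,
)
from .composite import compute_composites
from .features import compute_features, knn_impute
from .gam import fit_group_gam, timepoint_contrasts
from .selection import LassoConfig, select_predictors
from .validity import DEFAULT_COVARIATES, validity_regression

log = logging.getLogger("tsst_resilience")

PHYSIO_COLUMNS = ["participant_id", "modality", "phase_label", "time_min", "value"]


@dataclass
class PipelineConfig:
    """Everything `run_pipeline` needs, loadable from YAML."""

    seed: int = 0
    out_dir: str = "tsst_out"
    simulate: bool = True
    physio_path: str | None = None
    predictors_path: str | None = None
    n_participants: int = 248
    responder_fraction: float = 0.8
    missing_rate: float = 0.0
    cohort_overrides: dict = field(default_factory=dict)
    knn_k: int = 5
    transform_overrides: dict = field(default_factory=dict)
    fit_gams: bool = True
    gam_basis_size: int = 6
    validity_covariates: tuple = DEFAULT_COVARIATES
    lasso: dict = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        enc = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(enc.encode()).hexdigest()[:16]


def read_physio(path: str | Path) -> pd.DataFrame:
    """Read and validate a long physiological table."""
    df = pd.read_csv(path)
    missing = [c for c in PHYSIO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing physio columns {missing}")
    bad = set(df["modality"].unique()) - {"cortisol", "SBP", "DBP", "MAP", "HR"}
    if bad:
        raise ValueError(f"{path}: unknown modalities {sorted(bad)}")
    if not np.issubdtype(df["time_min"].dtype, np.number):
        raise ValueError(f"{path}: time_min must be numeric")
    return df


def read_predictors(path: str | Path, require_distress: bool = False) -> pd.DataFrame:
    """Read and validate the wide candidate-predictor table."""
    df = pd.read_csv(path)
    if "participant_id" not in df.columns:
        raise ValueError(f"{path}: missing column participant_id")
    missing = [c for c in PREDICTOR_NAMES if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing predictor columns {missing}")
    if require_distress and "distress" not in df.columns:
        raise ValueError(f"{path}: missing column distress")
    return df


def _digest_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns a dict of artifact paths.

    Any stage failure propagates with the stage name attached; artifacts
    written before the failure remain on disk.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    stage = "setup"
    try:
        stage = "simulate"
        if config.simulate:
            cohort_cfg = CohortConfig(
                n_participants=config.n_participants,
                responder_fraction=config.responder_fraction,
                seed=config.seed,
                **config.cohort_overrides,
            )
            cohort = generate_cohort(cohort_cfg)
            if config.missing_rate > 0:
                cohort = inject_missingness(
                    cohort,
                    config.missing_rate,
                    np.random.default_rng(config.seed + 1),
                )
            paths = cohort.write(out)
            artifacts.update(paths)
            physio, predictors = cohort.physio, cohort.predictors
            log.info("simulated cohort: n=%d", config.n_participants)
        else:
            physio = read_physio(config.physio_path)
            predictors = read_predictors(config.predictors_path, require_distress=True)
            log.info("loaded physio=%s predictors=%s", config.physio_path, config.predictors_path)

        stage = "impute"
        if predictors[list(PREDICTOR_NAMES)].isna().any().any():
            block = predictors[list(PREDICTOR_NAMES)]
            completed = knn_impute(block, k=config.knn_k)
            predictors = predictors.copy()
            predictors[list(PREDICTOR_NAMES)] = completed
            log.info("imputed predictor table with KNN (k=%d)", config.knn_k)

        stage = "features"
        feats = compute_features(physio, knn_k=config.knn_k)
        artifacts["features"] = out / "features.csv"
        feats.to_csv(artifacts["features"], index=False)
        log.info("features: %d participants", len(feats))

        stage = "gam"
        if config.fit_gams:
            gam_reports = {}
            contrasts = {}
            merged = physio.copy()
            if "MAP" not in set(merged["modality"]):
                sbp = merged[merged["modality"] == "SBP"].reset_index(drop=True)
                dbp = merged[merged["modality"] == "DBP"].reset_index(drop=True)
                mp = sbp.copy()
                mp["modality"] = "MAP"
                mp["value"] = dbp["value"] + (sbp["value"] - dbp["value"]) / 3.0
                merged = pd.concat(
                    [merged[merged["modality"].isin(["cortisol", "HR"])], mp],
                    ignore_index=True,
                )
            responder_ids = set(
                feats.loc[feats["responder"], "participant_id"].tolist()
            )
            cort = merged[
                (merged["modality"] == "cortisol")
                & (merged["phase_label"] != "arrival")
            ]
            strata = {
                "cortisol_responders": cort[cort["participant_id"].isin(responder_ids)],
                "cortisol_nonresponders": cort[~cort["participant_id"].isin(responder_ids)],
                "map": merged[merged["modality"] == "MAP"],
                "hr": merged[merged["modality"] == "HR"],
            }
            for name, sub in strata.items():
                if sub["participant_id"].nunique() < 10:
                    log.info("skipping GAM %s: too few participants", name)
                    continue
                sub = sub.dropna(subset=["value"])
                fit = fit_group_gam(sub, basis_size=config.gam_basis_size)
                times = np.sort(sub["time_min"].unique())
                con = timepoint_contrasts(fit, times[0], times[1:])
                gam_reports[name] = fit.to_dict()
                contrasts[name] = con.to_dict(orient="records")
                log.info(
                    "GAM %s: dev.expl=%.3f adj.R2=%.3f edf(time)=%.2f",
                    name,
                    fit.deviance_explained,
                    fit.adj_r2,
                    fit.edf["time"],
                )
            artifacts["gam_report"] = out / "gam_report.json"
            _write_json(
                artifacts["gam_report"],
                {"fits": gam_reports, "contrasts": contrasts},
            )

        stage = "composites"
        composites, pca_report = compute_composites(
            feats, transform_overrides=config.transform_overrides or None
        )
        artifacts["composites"] = out / "composites.csv"
        composites.to_csv(artifacts["composites"], index=False)
        artifacts["pca_report"] = out / "pca_report.json"
        _write_json(
            artifacts["pca_report"],
            {
                "reactivity": pca_report["reactivity"].to_dict(),
                "recovery": pca_report["recovery"].to_dict(),
                "normality_raw": pca_report["normality_raw"],
                "normality_transformed": pca_report["normality_transformed"],
            },
        )

        stage = "validity"
        merged = composites.merge(predictors, on="participant_id", how="inner")
        vres = validity_regression(
            merged["distress"],
            merged["resilience_index"],
            merged["daily_stressors"],
            merged["major_life_events"],
            demographics=merged,
            covariates=config.validity_covariates,
        )
        artifacts["validity_report"] = out / "validity_report.json"
        _write_json(artifacts["validity_report"], vres.to_dict())
        log.info(
            "validity: index beta=%.3f p=%.4f",
            vres["resilience_index"]["coef"],
            vres["resilience_index"]["p_value"],
        )

        stage = "selection"
        lasso_cfg = LassoConfig(seed=config.seed, **config.lasso)
        report = select_predictors(
            merged,
            merged["resilience_index"],
            lasso_cfg,
            predictor_columns=list(PREDICTOR_NAMES),
        )
        artifacts["lasso_report"] = out / "lasso_report.json"
        _write_json(artifacts["lasso_report"], report.to_dict())
        artifacts["importance"] = out / "importance.csv"
        report.importance_table().to_csv(artifacts["importance"], index=False)
        log.info(
            "selection: lambda_min=%.4f selected=%d refit R2=%.3f",
            report.lambda_min,
            len(report.selected),
            report.refit_r2,
        )

        stage = "manifest"
        manifest = {
            "package_version": __version__,
            "seed": config.seed,
            "config_digest": config.digest(),
            "config": dataclasses.asdict(config),
            "artifact_digests": {
                k: _digest_file(p) for k, p in sorted(artifacts.items())
            },
        }
        artifacts["manifest"] = out / "manifest.json"
        _write_json(artifacts["manifest"], manifest)
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return artifacts
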