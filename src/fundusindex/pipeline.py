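"""End-to-end orchestration: simulate -> extract -> fit -> associate.

Each stage reads/writes the plain-text external formats (CSV, PNG, JSON);
a run manifest records the configuration snapshot, seed, and a SHA-256
digest of every output file so that deterministic stages can be verified to
reproduce byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import __version__
from .associations import build_report
from .cohort import (
    CohortConfig,
    config_from_dict,
    covariates_frame,
    render_image,
    sample_covariates,
    sample_scene,
)
from .errors import DataError, StageError
from .features import FEATURE_NAMES, LandmarkSet, extract_features
from .ridge import (
    DEFAULT_LAMBDA_GRID,
    TrainingSet,
    fit_ridge_logistic,
    loocv_index,
    predict_index,
    select_lambda,
)

log = logging.getLogger("fundusindex")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    seed: int
    config: dict
    version: str = __version__
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, outputs: list[Path], seconds: float) -> None:
        self.stages[stage] = {
            "outputs": {str(p): _digest(p) for p in outputs},
            "seconds": round(seconds, 3),
        }

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))


def simulate_stage(config: CohortConfig, outdir: Path) -> list[Path]:
    """Write cohort.csv plus one PNG image and landmark JSON per subject."""
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    (outdir / "landmarks").mkdir(parents=True, exist_ok=True)
    records = sample_covariates(config)
    cohort_path = outdir / "cohort.csv"
    covariates_frame(records).to_csv(cohort_path, index=False, float_format="%.6f")
    outputs = [cohort_path]
    for record in records:
        scene = sample_scene(record, config)
        img, landmarks = render_image(scene, image_size=config.image_size)
        img_path = outdir / "images" / f"{record.subject_id}.png"
        Image.fromarray(img).save(img_path)
        lm_path = outdir / "landmarks" / f"{record.subject_id}.json"
        landmarks.to_json(lm_path)
        outputs += [img_path, lm_path]
    return outputs


def extract_stage(images_dir, landmarks_dir, out_csv) -> Path:
    """Run 42-parameter extraction over an image/landmark directory pair."""
    images_dir, landmarks_dir = Path(images_dir), Path(landmarks_dir)
    rows = {}
    image_paths = sorted(images_dir.glob("*.png"))
    if not image_paths:
        raise DataError(f"no PNG images found in {images_dir}")
    for img_path in image_paths:
        subject_id = img_path.stem
        lm_path = landmarks_dir / f"{subject_id}.json"
        if not lm_path.exists():
            raise DataError(f"missing landmark file for {subject_id}: {lm_path}")
        image = np.asarray(Image.open(img_path).convert("RGB"))
        landmarks = LandmarkSet.from_json(lm_path)
        landmarks.validate(image_shape=image.shape)
        rows[subject_id] = extract_features(image, landmarks)
    frame = pd.DataFrame(
        {sid: fv.values for sid, fv in rows.items()}, index=list(FEATURE_NAMES)
    ).T
    frame.index.name = "subject_id"
    out_csv = Path(out_csv)
    out_csv.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(out_csv, float_format="%.10g")
    return out_csv


def training_set_from_tables(
    features: pd.DataFrame, covariates: pd.DataFrame
) -> TrainingSet:
    """Join a feature table (indexed by subject_id) with covariate sex labels.

    Rows with any missing parameter are excluded listwise.
    """
    feat = features.dropna()
    cov = covariates.set_index("subject_id")
    common = sorted(set(feat.index) & set(cov.index))
    if not common:
        raise DataError("no overlapping subject ids between features and covariates")
    feat = feat.loc[common]
    y = (cov.loc[common, "sex"] == "female").astype(int).to_numpy()
    return TrainingSet(
        X=feat.to_numpy(dtype=float),
        y=y,
        ids=list(common),
        feature_names=tuple(feat.columns),
    )


def fit_stage(
    features_csv,
    covariates_csv,
    out_index_csv,
    out_model_json,
    lam: float | str = "auto",
    loocv: bool = True,
    lambda_grid=DEFAULT_LAMBDA_GRID,
) -> tuple[Path, Path]:
    """Fit the ridge model, write index.csv (loo + final rows) and model.json."""
    features = pd.read_csv(features_csv, index_col="subject_id")
    covariates = pd.read_csv(covariates_csv)
    data = training_set_from_tables(features, covariates)
    if lam == "auto":
        lam = select_lambda(data, grid=lambda_grid)
        log.info("selected lambda=%g by cross-validation", lam)
    lam = float(lam)

    rows = []
    if loocv:
        result = loocv_index(data, lam)
        model = result.model
        rows += [
            {"subject_id": sid, "fundus_sex_index": val, "fold": "loo"}
            for sid, val in zip(result.ids, result.index)
        ]
        log.info("LOOCV complete: %d fits, AROC=%.3f", result.n_models, result.aroc)
    else:
        model = fit_ridge_logistic(data, lam)
    final_index = predict_index(model, data.X)
    rows += [
        {"subject_id": sid, "fundus_sex_index": val, "fold": "final"}
        for sid, val in zip(data.ids, final_index)
    ]

    out_index_csv, out_model_json = Path(out_index_csv), Path(out_model_json)
    pd.DataFrame(rows).to_csv(out_index_csv, index=False, float_format="%.10g")
    payload = model.to_dict()
    payload["loocv_aroc"] = result.aroc if loocv else None
    out_model_json.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return out_index_csv, out_model_json


def associate_stage(index_csv, covariates_csv, outdir, features_csv=None) -> list[Path]:
    """Build the association report from index + covariates (+ features)."""
    index = pd.read_csv(index_csv)
    index = index[index["fold"] == "loo"] if "fold" in index and (
        index["fold"] == "loo"
    ).any() else index
    covariates = pd.read_csv(covariates_csv)
    features = (
        pd.read_csv(features_csv, index_col="subject_id")
        if features_csv is not None
        else None
    )
    report = build_report(index, covariates, features=features)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    json_path = outdir / "report.json"
    md_path = outdir / "report.md"
    json_path.write_text(report.to_json())
    md_path.write_text(report.to_markdown())
    return [json_path, md_path]


def run_pipeline(
    config: CohortConfig | dict,
    outdir,
    lam: float | str = "auto",
    with_stepwise: bool = True,
) -> RunManifest:
    """Execute simulate -> extract -> fit -> associate and write manifest.json.

    Any stage failure is re-raised as a StageError carrying the stage name.
    """
    def run(stage, fn, *args, **kwargs):
        start = time.perf_counter()
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - wrap with stage context
            raise StageError(stage, exc) from exc
        elapsed = time.perf_counter() - start
        log.info("stage %s finished in %.2f s", stage, elapsed)
        return result, elapsed

    def configure():
        cfg = config_from_dict(config) if isinstance(config, dict) else config
        cfg.validate()
        return cfg

    config, _ = run("configure", configure)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=config.seed, config=_config_dict(config))

    outputs, dt = run("simulate", simulate_stage, config, outdir)
    manifest.record("simulate", outputs, dt)

    features_csv = outdir / "features.csv"
    (_, dt) = run(
        "extract", extract_stage, outdir / "images", outdir / "landmarks", features_csv
    )
    manifest.record("extract", [features_csv], dt)

    (fit_outputs, dt) = run(
        "fit",
        fit_stage,
        features_csv,
        outdir / "cohort.csv",
        outdir / "index.csv",
        outdir / "model.json",
        lam,
    )
    manifest.record("fit", list(fit_outputs), dt)

    (report_outputs, dt) = run(
        "associate",
        associate_stage,
        outdir / "index.csv",
        outdir / "cohort.csv",
        outdir / "report",
        features_csv if with_stepwise else None,
    )
    manifest.record("associate", report_outputs, dt)

    manifest.write(outdir / "manifest.json")
    return manifest


def _config_dict(config: CohortConfig) -> dict:
    payload = asdict(config)
    for key in ("height_params", "axial_params", "age_params"):
        payload[key] = {sex: list(v) for sex, v in payload[key].items()}
    return payload
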