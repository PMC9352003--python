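"""End-to-end pipeline runner: vision -> Brix prediction -> final grade.

Images and spectra belonging to the same fruit are paired by shared sample
id: the image file stem must match a sample column in the spectra CSV.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from .chemometrics.brix import classify_brix
from .chemometrics.preprocess import SpectraSet, downsample_wavelengths, msc, snv
from .config import ChemometricsConfig, PipelineConfig
from .errors import PairingError
from .grading import GradeResult, grade_apple
from .io import load_model_json, read_image, read_spectra_csv
from .vision import measure_appearance

log = logging.getLogger("applegrade")

__all__ = ["run_pipeline", "grade_result_to_dict"]


def grade_result_to_dict(res: GradeResult, sample_id: str | None = None) -> dict:
    d = {
        "quality_grade": res.quality_grade,
        "size_grade": res.size_grade,
        "brix_grade": res.brix_grade,
        "appearance": res.appearance.to_dict(),
    }
    if sample_id is not None:
        d["sample_id"] = sample_id
    return d


def preprocess_spectra(spectra: SpectraSet, cfg: ChemometricsConfig) -> SpectraSet:
    """Apply the configured decimation / MSC / SNV chain."""
    out = downsample_wavelengths(spectra, cfg.keep_every)
    if cfg.apply_msc:
        out = msc(out)
    if cfg.apply_snv:
        out = snv(out)
    return out


def _predict_brix(model, extras, spectra: SpectraSet, cfg: ChemometricsConfig) -> np.ndarray:
    # raw acquisition grids are preprocessed down to the grid the model saw
    if spectra.n_wavelengths != len(extras["wavelengths"]):
        spectra = preprocess_spectra(spectra, cfg)
    idx = extras.get("selected_indices")
    X = spectra.reflectance
    if idx is not None and X.shape[1] == len(extras["wavelengths"]):
        X = X[:, idx]
    return model.predict(X)


def run_pipeline(
    image_paths,
    spectra_path,
    brix_model_path,
    config: PipelineConfig | None = None,
    out_path=None,
) -> list[dict]:
    """Grade a batch of fruits; returns (and optionally writes as JSON
    lines) one record per fruit.  An empty batch is a valid no-op."""
    cfg = config or PipelineConfig()
    image_paths = [Path(p) for p in image_paths]
    records: list[dict] = []

    if image_paths:
        spectra, ids = read_spectra_csv(spectra_path)
        model, extras = load_model_json(brix_model_path)
        id_to_row = {sid: i for i, sid in enumerate(ids)}
        missing = [p.stem for p in image_paths if p.stem not in id_to_row]
        if missing:
            raise PairingError(f"no spectrum column for image stems: {missing}")
        brix_pred = _predict_brix(model, extras, spectra, cfg.chemometrics)
        for p in image_paths:
            appearance = measure_appearance(read_image(p), cfg.vision)
            brix = float(brix_pred[id_to_row[p.stem]])
            result = grade_apple(appearance, classify_brix(max(brix, 0.0)))
            rec = grade_result_to_dict(result, sample_id=p.stem)
            rec["brix_predicted"] = brix
            records.append(rec)
            log.info("graded %s: %s / %s", p.stem, result.quality_grade, result.size_grade)

    if out_path is not None:
        Path(out_path).write_text("".join(json.dumps(r) + "\n" for r in records))
    return records
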