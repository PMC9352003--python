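"""File formats: spectra/Brix CSVs, calibration pairs, model JSON, masks.

Spectra CSV layout: first column ``wavelength_nm``, one column per sample
(sample ids as headers).  Brix CSV: columns ``sample_id, brix``.
Calibration pairs CSV: columns ``wp_px, wr_mm``.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .chemometrics.preprocess import SpectraSet
from .chemometrics.pls import PlsModel
from .errors import InvalidParameterError
from .vision import SizeCalibration

__all__ = [
    "read_image",
    "write_mask",
    "read_spectra_csv",
    "write_spectra_csv",
    "read_brix_csv",
    "write_brix_csv",
    "read_pairs_csv",
    "write_pairs_csv",
    "save_model_json",
    "load_model_json",
    "calibration_to_dict",
]


def read_image(path) -> np.ndarray:
    img = iio.imread(path)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.shape[-1] == 4:
        img = img[..., :3]
    return np.asarray(img, dtype=np.uint8)


def write_mask(path, mask: np.ndarray) -> None:
    iio.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))


def read_spectra_csv(path, transpose: bool = False) -> tuple[SpectraSet, list[str]]:
    """Load spectra; returns the set and the sample ids (column order)."""
    df = pd.read_csv(path)
    if transpose:
        df = df.set_index(df.columns[0]).T.reset_index(names="wavelength_nm")
    if df.columns[0] != "wavelength_nm":
        raise InvalidParameterError("first column must be wavelength_nm")
    wl = df["wavelength_nm"].to_numpy(dtype=float)
    ids = [str(c) for c in df.columns[1:]]
    r = df.iloc[:, 1:].to_numpy(dtype=float).T  # (N, W)
    return SpectraSet(wavelengths=wl, reflectance=r), ids


def write_spectra_csv(path, spectra: SpectraSet, sample_ids=None) -> None:
    ids = sample_ids or [f"s{i:03d}" for i in range(spectra.n_samples)]
    df = pd.DataFrame(spectra.reflectance.T, columns=ids)
    df.insert(0, "wavelength_nm", spectra.wavelengths)
    df.to_csv(path, index=False)


def read_brix_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"sample_id", "brix"} <= set(df.columns):
        raise InvalidParameterError("brix CSV needs sample_id and brix columns")
    df["sample_id"] = df["sample_id"].astype(str)
    return df


def write_brix_csv(path, sample_ids, brix) -> None:
    pd.DataFrame({"sample_id": sample_ids, "brix": brix}).to_csv(path, index=False)


def read_pairs_csv(path) -> np.ndarray:
    df = pd.read_csv(path)
    if not {"wp_px", "wr_mm"} <= set(df.columns):
        raise InvalidParameterError("pairs CSV needs wp_px and wr_mm columns")
    return df[["wp_px", "wr_mm"]].to_numpy(dtype=float)


def write_pairs_csv(path, pairs: np.ndarray) -> None:
    pd.DataFrame(np.asarray(pairs), columns=["wp_px", "wr_mm"]).to_csv(path, index=False)


def calibration_to_dict(cal: SizeCalibration) -> dict:
    return {
        "slope": cal.slope,
        "intercept": cal.intercept,
        "r_squared": cal.r_squared,
        "residual_variance": cal.residual_variance,
        "n_pairs": cal.n_pairs,
    }


def save_model_json(
    path,
    model: PlsModel,
    wavelengths: np.ndarray,
    selected_indices=None,
    metrics: dict | None = None,
    meta: dict | None = None,
) -> None:
    """Serialize a fitted Brix model: coefficients, centering terms, the
    wavelength grid it expects, the selected subset, and run metadata."""
    payload = {
        "n_components": model.n_components,
        "regression_coefficients": model.regression_coefficients.tolist(),
        "x_mean": model.x_mean.tolist(),
        "y_mean": model.y_mean,
        "x_weights": model.x_weights.tolist(),
        "x_loadings": model.x_loadings.tolist(),
        "y_loadings": model.y_loadings.tolist(),
        "wavelengths": np.asarray(wavelengths).tolist(),
        "selected_indices": None
        if selected_indices is None
        else np.asarray(selected_indices).tolist(),
        "metrics": metrics,
        "meta": meta or {},
    }
    Path(path).write_text(json.dumps(payload))


def load_model_json(path) -> tuple[PlsModel, dict]:
    d = json.loads(Path(path).read_text())
    model = PlsModel(
        n_components=d["n_components"],
        x_weights=np.asarray(d["x_weights"], dtype=float),
        x_loadings=np.asarray(d["x_loadings"], dtype=float),
        y_loadings=np.asarray(d["y_loadings"], dtype=float),
        regression_coefficients=np.asarray(d["regression_coefficients"], dtype=float),
        x_mean=np.asarray(d["x_mean"], dtype=float),
        y_mean=float(d["y_mean"]),
    )
    extras = {
        "wavelengths": np.asarray(d["wavelengths"], dtype=float),
        "selected_indices": None
        if d.get("selected_indices") is None
        else np.asarray(d["selected_indices"], dtype=int),
        "metrics": d.get("metrics"),
        "meta": d.get("meta", {}),
    }
    return model, extras
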