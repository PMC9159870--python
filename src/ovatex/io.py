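"""File I/O: grayscale images, CSV feature tables, JSON model files."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .logistic import ULRModel

__all__ = [
    "read_image",
    "write_image",
    "read_feature_table",
    "write_feature_table",
    "save_model",
    "load_model",
]

MODEL_FORMAT = "ovatex-ulr-1"


def read_image(path) -> np.ndarray:
    """Load a PNG/TIFF image as a float grid scaled to [0, 1].

    8- and 16-bit single-channel images are supported; RGB(A) inputs are
    collapsed by unweighted channel mean (ultrasound captures are gray).
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            if getattr(im, "n_frames", 1) > 1:
                raise ValueError(f"multi-frame image not supported: {path}")
            arr = np.asarray(im)
    except (OSError, SyntaxError) as exc:
        raise ValueError(f"cannot read image {path}: {exc}") from exc
    if arr.dtype == np.uint8:
        scale = 255.0
    elif arr.dtype == np.uint16:
        scale = 65535.0
    else:
        scale = None
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=2)
    elif arr.ndim != 2:
        raise ValueError(f"unsupported image layout {arr.shape} in {path}")
    arr = arr.astype(float)
    if scale is not None:
        return arr / scale
    if arr.size and arr.max() > 1.0:  # integer-coded float file
        arr = arr / arr.max()
    return arr


def write_image(image, path) -> None:
    """Save a [0, 1] float grid as an 8-bit grayscale PNG/TIFF."""
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    Image.fromarray(np.round(arr * 255).astype(np.uint8)).save(path)


def write_feature_table(table: pd.DataFrame, path) -> None:
    if table.columns.duplicated().any():
        raise ValueError("duplicate column names in feature table")
    table.to_csv(path, index=False)


def read_feature_table(path, require_label: bool = True) -> pd.DataFrame:
    """Read a features CSV, validating the schema.

    Every non-filename column must be numeric and complete; if
    ``require_label`` the table must carry a binary ``label`` column.
    """
    df = pd.read_csv(path)
    if require_label and "label" not in df.columns:
        raise ValueError(f"feature table {path} lacks a 'label' column")
    for col in df.columns:
        if col == "filename":
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.index[vals.isna()]
        if len(bad):
            raise ValueError(
                f"non-numeric or missing value in {path}, column {col!r}, "
                f"row(s) {list(bad[:5])}"
            )
        df[col] = vals
    if "label" in df.columns and len(df) and not df["label"].isin([0, 1]).all():
        raise ValueError(f"labels in {path} must be 0 or 1")
    return df


def save_model(model: ULRModel, path) -> None:
    """Serialize a fitted model to JSON (coefficients + scaling + metadata)."""
    if len(model.feature_names) == 0:
        raise ValueError("refusing to save a model with no features")
    payload = {
        "format": MODEL_FORMAT,
        "alpha": model.alpha,
        "betas": model.betas.tolist(),
        "feature_names": model.feature_names,
        "standardize_means": model.standardize_means.tolist(),
        "standardize_sds": model.standardize_sds.tolist(),
        "ridge_lambda": model.ridge_lambda,
        "converged": model.converged,
        "n_iter": model.n_iter,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_model(path) -> ULRModel:
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"corrupt model file {path}: {exc}") from exc
    if payload.get("format") != MODEL_FORMAT:
        raise ValueError(
            f"model file {path} has format {payload.get('format')!r}, "
            f"expected {MODEL_FORMAT!r}"
        )
    return ULRModel(
        alpha=payload["alpha"],
        betas=np.array(payload["betas"]),
        feature_names=list(payload["feature_names"]),
        standardize_means=np.array(payload["standardize_means"]),
        standardize_sds=np.array(payload["standardize_sds"]),
        ridge_lambda=payload["ridge_lambda"],
        converged=payload["converged"],
        n_iter=payload["n_iter"],
    )
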