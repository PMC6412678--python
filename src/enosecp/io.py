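"""Feature-table and model persistence.

Feature tables travel as plain wide CSV: one row per specimen, one column
per feature, and a final ``label`` column when labels are known.  Lines
starting with ``#`` are treated as metadata comments.  Fitted conformal
models are stored as a joblib blob next to a JSON metadata file.
"""

from __future__ import annotations

import json
from pathlib import Path

import joblib
import numpy as np
import pandas as pd

from enosecp.conformal import ACPModel, ICPModel
from enosecp.features import FeatureTable

__all__ = [
    "read_feature_table",
    "write_feature_table",
    "save_model",
    "load_model",
]


def write_feature_table(
    table: FeatureTable, path: str | Path, *, header_comment: str | None = None
) -> None:
    """Write a feature table to CSV (optionally with a leading # comment)."""
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        table.to_dataframe().to_csv(fh, index=False)


def read_feature_table(path: str | Path, *, require_labels: bool = False) -> FeatureTable:
    """Read a feature table from CSV.

    Rejects ragged rows (naming the offending line) and non-numeric feature
    cells.  A missing ``label`` column is accepted unless ``require_labels``.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, comment="#")
    except pd.errors.ParserError as err:
        raise ValueError(f"malformed CSV {path}: {err}") from err
    feature_cols = [c for c in frame.columns if c != "label"]
    bad = frame.isna().to_numpy()
    if bad.any():
        row = int(np.nonzero(bad.any(axis=1))[0][0])
        raise ValueError(f"ragged or missing cells at data row {row} of {path}")
    try:
        values = frame[feature_cols].to_numpy(dtype=float)
    except (TypeError, ValueError) as err:
        raise ValueError(f"non-numeric feature cell in {path}: {err}") from err
    labels = frame["label"].to_numpy() if "label" in frame.columns else None
    if require_labels and labels is None:
        raise ValueError(f"{path} has no label column")
    return FeatureTable(values=values, names=feature_cols, labels=labels)


def save_model(model: ICPModel | ACPModel, path: str | Path) -> None:
    """Persist a fitted conformal model (joblib blob + JSON metadata)."""
    path = Path(path)
    if isinstance(model, ACPModel):
        meta = {
            "framework": "acp",
            "K": model.K,
            "label_set": model.label_set.tolist(),
            "n_calibration": [f.n_calibration for f in model.folds],
        }
    else:
        meta = {
            "framework": "icp",
            "label_set": model.label_set.tolist(),
            "n_calibration": model.n_calibration,
        }
    joblib.dump(model, path)
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))


def load_model(path: str | Path) -> ICPModel | ACPModel:
    return joblib.load(path)
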