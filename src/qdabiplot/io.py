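"""Readers and writers: labelled CSV matrices, layout JSON, region-grid
tables, label files and confusion matrices.

CSV dialect: comma-separated, UTF-8, header row required, '.' decimal.
Values are written at full (shortest round-trip) precision so a
write-then-read round trip reproduces the matrix exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .biplot import BiplotLayout, CalibratedAxis, RegionGrid
from .discriminant import DataError, LabeledData, centre_and_index

__all__ = [
    "read_labeled_csv",
    "write_labeled_csv",
    "layout_to_json",
    "layout_from_json",
    "write_region_grid",
    "confusion_matrix",
    "write_labels",
]


def read_labeled_csv(path, group_col="group") -> LabeledData:
    """Read a samples-by-variables CSV with one group-label column.

    ``group_col`` is a column name or integer position.  All remaining
    columns must be numeric with no missing values (no imputation).
    """
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise DataError(f"could not parse {path}: {exc}") from exc
    if isinstance(group_col, int):
        if group_col >= df.shape[1]:
            raise DataError(f"group column index {group_col} out of range")
        group_name = df.columns[group_col]
    else:
        if group_col not in df.columns:
            raise DataError(
                f"group column {group_col!r} not found; columns are "
                f"{list(df.columns)}"
            )
        group_name = group_col
    labels = df[group_name].tolist()
    values = df.drop(columns=[group_name])
    for col in values.columns:
        numeric = pd.to_numeric(values[col], errors="coerce")
        bad = numeric.isna() & values[col].notna()
        if bad.any():
            raise DataError(
                f"non-numeric value at row {int(bad.idxmax())}, column {col!r}"
            )
        if numeric.isna().any():
            raise DataError(
                f"missing value at row {int(numeric.isna().idxmax())}, "
                f"column {col!r}"
            )
        values[col] = numeric
    return centre_and_index(
        values.to_numpy(dtype=float), labels, variable_names=list(values.columns)
    )


def write_labeled_csv(data: LabeledData, path, group_col: str = "group") -> None:
    """Write the original-scale matrix plus group column (full precision)."""
    df = pd.DataFrame(data.raw, columns=data.variable_names)
    df[group_col] = [data.class_labels[g] for g in data.groups]
    df.to_csv(path, index=False)


def layout_to_json(layout: BiplotLayout, groups=None, path=None) -> str:
    """Serialize a layout (scores, back-map, axes, markers) to JSON.

    ``groups`` optionally records the per-sample class index so a plot can be
    re-rendered from the JSON alone.  The region grid is not embedded (it is
    recomputable from the layout); use :func:`write_region_grid` for a table.
    """
    def arr(a):
        return None if a is None else np.asarray(a).tolist()

    obj = {
        "layout_kind": layout.layout_kind,
        "scores": arr(layout.scores),
        "loadings": arr(layout.loadings),
        "centre_offset": arr(layout.centre_offset),
        "phi_scale": arr(layout.phi_scale),
        "phi_offset": arr(layout.phi_offset),
        "priors": arr(layout.priors),
        "class_means_display": arr(layout.class_means_display),
        "lda_scale": layout.lda_scale,
        "class_labels": layout.class_labels,
        "groups": arr(groups),
        "aspect": layout.aspect,
        "axes": [
            {
                "variable_name": ax.variable_name,
                "direction": arr(ax.direction),
                "offset": arr(ax.offset),
                "centre_value": ax.centre_value,
                "markers": [[v, arr(pos)] for v, pos in ax.markers],
            }
            for ax in layout.axes
        ],
    }
    text = json.dumps(obj, indent=1)
    if path is not None:
        Path(path).write_text(text)
    return text


def layout_from_json(source) -> tuple[BiplotLayout, np.ndarray | None]:
    """Inverse of :func:`layout_to_json`; returns (layout, groups-or-None)."""
    if isinstance(source, (str, Path)) and Path(str(source)).exists():
        obj = json.loads(Path(source).read_text())
    else:
        obj = json.loads(source)

    def arr(key):
        v = obj.get(key)
        return None if v is None else np.asarray(v, dtype=float)

    layout = BiplotLayout(
        scores=arr("scores"),
        layout_kind=obj["layout_kind"],
        loadings=arr("loadings"),
        centre_offset=arr("centre_offset"),
        phi_scale=arr("phi_scale"),
        phi_offset=arr("phi_offset"),
        priors=arr("priors"),
        class_means_display=arr("class_means_display"),
        lda_scale=obj.get("lda_scale"),
        class_labels=obj.get("class_labels"),
        aspect=obj.get("aspect", 1.0),
    )
    layout.axes = [
        CalibratedAxis(
            variable_name=a["variable_name"],
            direction=np.asarray(a["direction"], dtype=float),
            markers=[(v, np.asarray(pos, dtype=float)) for v, pos in a["markers"]],
            offset=np.asarray(a["offset"], dtype=float),
            centre_value=a.get("centre_value", 0.0),
        )
        for a in obj["axes"]
    ]
    groups = obj.get("groups")
    if groups is not None:
        groups = np.asarray(groups, dtype=int)
    return layout, groups


def write_region_grid(grid: RegionGrid, path, class_labels=None, sep=",") -> None:
    """Export a region grid as a delimited (x, y, label) table."""
    XX, YY = np.meshgrid(grid.x, grid.y)
    lab = grid.labels.ravel()
    if class_labels is not None:
        lab = np.asarray([class_labels[j] for j in lab])
    pd.DataFrame({"x": XX.ravel(), "y": YY.ravel(), "label": lab}).to_csv(
        path, index=False, sep=sep
    )


def confusion_matrix(true_groups, predicted_groups, class_labels) -> pd.DataFrame:
    """Resubstitution confusion matrix: rows = true class, columns = predicted."""
    J = len(class_labels)
    counts = np.zeros((J, J), dtype=int)
    np.add.at(counts, (np.asarray(true_groups), np.asarray(predicted_groups)), 1)
    return pd.DataFrame(counts, index=class_labels, columns=class_labels)


def write_labels(data: LabeledData, predicted, path) -> None:
    """Per-sample true and predicted labels as CSV."""
    pd.DataFrame(
        {
            "sample": np.arange(data.n),
            "true": [data.class_labels[g] for g in data.groups],
            "predicted": [data.class_labels[g] for g in predicted],
        }
    ).to_csv(path, index=False)
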