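"""Delimited-text readers/writers for count tables, labels, models, truth."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .ensemble import EnsembleModel, from_json, to_json
from .simulate import SimulationConfig


def _detect_sep(path) -> str:
    with open(path) as fh:
        first = fh.readline()
    if "\t" in first:
        return "\t"
    if "," in first:
        return ","
    raise ValueError(f"{path}: could not detect delimiter (expected tab or comma)")


def read_table(path, orientation: str = "samples_as_rows") -> pd.DataFrame:
    """Read a numeric count/abundance table with header row and ID column.

    Returns a DataFrame with samples in rows regardless of on-disk
    orientation.  Non-numeric cells and negative values are rejected with
    the offending row/column named; duplicate feature names are an error.
    """
    if orientation not in ("samples_as_rows", "samples_as_cols"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = _detect_sep(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"{path}: duplicate column names: {', '.join(dupes)}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    if orientation == "samples_as_cols":
        df = df.T
    df.index.name = None
    df.columns.name = None
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    if df.columns.duplicated().any():
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate feature names: {', '.join(dupes)}")
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise ValueError(
                f"{path}: non-numeric value {bad.iloc[0]!r} at row {bad.index[0]!r}, "
                f"column {col!r}"
            ) from None
    neg = df < 0
    if neg.to_numpy().any():
        i, j = np.argwhere(neg.to_numpy())[0]
        raise ValueError(
            f"{path}: negative value at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    return df


def read_labels(path, label_column: str | None = None) -> pd.Series:
    """Read a two-column (sample ID, binary label) delimited file."""
    df = pd.read_csv(path, sep=_detect_sep(path), index_col=0)
    if label_column is None:
        if df.shape[1] != 1:
            raise ValueError(
                f"{path}: has {df.shape[1]} label columns; pass label_column"
            )
        series = df.iloc[:, 0]
    else:
        if label_column not in df.columns:
            raise ValueError(f"{path}: no column named {label_column!r}")
        series = df[label_column]
    series.index = series.index.map(str)
    vals = set(pd.unique(series))
    if not vals <= {0, 1}:
        raise ValueError(f"{path}: labels must be binary in {{0,1}}, got {sorted(vals)}")
    return series.astype(int)


def align_labels(table: pd.DataFrame, labels: pd.Series) -> np.ndarray:
    """Order labels to the table's samples; mismatches list the offending IDs."""
    missing = [sid for sid in table.index if sid not in labels.index]
    if missing:
        raise ValueError(f"samples without labels: {', '.join(map(str, missing[:20]))}")
    return labels.loc[table.index].to_numpy()


def write_counts_tsv(path, counts, feature_names, sample_ids) -> None:
    pd.DataFrame(counts, index=sample_ids, columns=feature_names).to_csv(
        path, sep="\t", index_label="sample_id"
    )


def write_labels_tsv(path, sample_ids, y) -> None:
    pd.DataFrame({"label": np.asarray(y, dtype=int)}, index=sample_ids).to_csv(
        path, sep="\t", index_label="sample_id"
    )


def write_truth_json(path, config: SimulationConfig, feature_names) -> None:
    """Sidecar recording the planted partitions and coefficients by name."""
    doc = {
        "n": config.n,
        "p": config.p,
        "alpha_star": config.alpha_star,
        "dispersion": config.dispersion,
        "sequencing_depth_range": list(config.sequencing_depth_range),
        "zero_inflation": config.zero_inflation,
        "seed": config.seed,
        "planted": [
            {
                "numerator": [feature_names[j] for j in part.j_plus],
                "denominator": [feature_names[j] for j in part.j_minus],
                "beta_star": beta_star,
                "ratio_type": ratio_type,
            }
            for part, beta_star, ratio_type in config.planted
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def save_model(model: EnsembleModel, path) -> None:
    Path(path).write_text(to_json(model) + "\n")


def load_model(path) -> EnsembleModel:
    return from_json(Path(path).read_text())


def write_predictions_tsv(path, sample_ids, logits, probabilities) -> None:
    pd.DataFrame(
        {"logit": logits, "probability": probabilities}, index=sample_ids
    ).to_csv(path, sep="\t", index_label="sample_id")
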