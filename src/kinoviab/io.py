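"""Readers and writers for the pipeline's tabular interchange formats.

Everything is plain CSV/TSV with explicit schemas: long-format inhibition
records, wide omics matrices keyed by cell line, LL.4 parameter tables,
long viability records, interaction edge lists, and kinase annotations.
Concentrations are stored in molar using scientific notation.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import InhibitionProfile

INHIBITION_COLS = ["compound", "protein", "concentration",
                   "relative_intensity"]
PARAMS_COLS = ["cell_line", "compound", "b", "c", "d", "e"]
VIABILITY_COLS = ["cell_line", "compound", "concentration", "viability"]
EDGE_COLS = ["node_a", "node_b", "confidence"]


def _check_columns(df: pd.DataFrame, expected: list[str], what: str) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing columns {missing}")


def write_inhibition_records(df: pd.DataFrame, path) -> None:
    _check_columns(df, INHIBITION_COLS, "inhibition records")
    df[INHIBITION_COLS].to_csv(path, index=False, float_format="%.10g")


def read_inhibition_records(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, INHIBITION_COLS, "inhibition records")
    return df


def write_omics_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index_label="cell_line", float_format="%.10g")


def read_omics_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="cell_line")


def write_params(df: pd.DataFrame, path) -> None:
    _check_columns(df, PARAMS_COLS, "dose-response parameters")
    df[PARAMS_COLS].to_csv(path, index=False, float_format="%.10g")


def read_params(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, PARAMS_COLS, "dose-response parameters")
    return df


def write_viability(df: pd.DataFrame, path) -> None:
    _check_columns(df, VIABILITY_COLS, "viability records")
    df[VIABILITY_COLS].to_csv(path, index=False, float_format="%.10g")


def read_viability(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, VIABILITY_COLS, "viability records")
    return df


def write_edge_list(df: pd.DataFrame, path) -> None:
    _check_columns(df, EDGE_COLS, "edge list")
    df[EDGE_COLS].to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_edge_list(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _check_columns(df, EDGE_COLS, "edge list")
    return df


def write_annotation(df: pd.DataFrame, path) -> None:
    _check_columns(df, ["protein", "class"], "kinase annotation")
    df[["protein", "class"]].to_csv(path, index=False)


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, ["protein", "class"], "kinase annotation")
    return df


def write_profile(profile: InhibitionProfile, path, sidecar: dict | None = None
                  ) -> None:
    """Dense profile as wide CSV plus a JSON provenance sidecar."""
    profile.to_frame().to_csv(path, index=False, float_format="%.10g")
    meta = {"compounds": profile.compounds, "proteins": profile.proteins,
            "dose_grid": [float(x) for x in profile.dose_grid]}
    meta.update(sidecar or {})
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))


def read_profile(path) -> InhibitionProfile:
    meta = json.loads(Path(str(path) + ".json").read_text())
    df = pd.read_csv(path)
    grid = np.asarray(meta["dose_grid"], dtype=float)
    n_c, n_x = len(meta["compounds"]), grid.size
    cols = ["act_" + p for p in meta["proteins"]]
    df = df.sort_values(["compound", "concentration"],
                        key=lambda s: s.map(
                            {c: i for i, c in enumerate(meta["compounds"])})
                        if s.name == "compound" else s)
    tensor = df[cols].to_numpy(dtype=float).reshape(n_c, n_x, len(cols))
    return InhibitionProfile(meta["compounds"], meta["proteins"], grid, tensor)


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format="%.10g")
    schema = {"key_columns": ["cell_line", "compound", "concentration"],
              "response": "viability",
              "features": [c for c in table.columns
                           if c not in ("cell_line", "compound",
                                        "concentration", "viability")]}
    Path(str(path) + ".json").write_text(json.dumps(schema, indent=1))


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
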