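"""CSV/JSON readers and writers for the pipeline's file interfaces.

All tables are comma-separated UTF-8 with a mandatory header row;
missing values are empty fields. The atlas travels as JSON with Allen
structure-graph field names (id, acronym, name, parent_structure_id).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .atlas import AtlasHierarchy

DESIGN_COLUMNS = [
    "animal_id",
    "pair_id",
    "sex",
    "partner_type",
    "timepoint",
    "block",
    "behavior_included",
    "ieg_included",
]


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, index=False)


def read_design(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(DESIGN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    df["behavior_included"] = df["behavior_included"].astype(bool)
    df["ieg_included"] = df["ieg_included"].astype(bool)
    return df


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, index_label="animal_id")


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="animal_id")
    if (df.to_numpy() < 0).any():
        raise ValueError("count matrix contains negative entries")
    return df


def write_behavior(behavior: pd.DataFrame, path) -> None:
    behavior.to_csv(path, index_label="animal_id")


def read_behavior(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="animal_id")


def write_connectivity(conn: pd.DataFrame, path) -> None:
    conn.to_csv(path, index_label="origin")


def read_connectivity(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="origin")
    if not list(df.index) == list(df.columns):
        raise ValueError("connectivity matrix row and column labels differ")
    if (df.to_numpy() < 0).any():
        raise ValueError("connectivity matrix contains negative entries")
    return df


def write_atlas(atlas: AtlasHierarchy, path) -> None:
    atlas.to_json(path)


def read_atlas(path) -> AtlasHierarchy:
    return AtlasHierarchy.from_json(path)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
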