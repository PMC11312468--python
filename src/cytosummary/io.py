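"""Typed containers for single-cell feature data and well profiles, with CSV I/O.

The interchange dialect follows CellProfiler-style per-object exports: a header
row, metadata columns prefixed ``Metadata_``, and every remaining column a
numeric morphological feature. One row is one segmented cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WellKey",
    "SingleCellTable",
    "SampleSet",
    "ProfileTable",
    "SchemaError",
    "AlignmentError",
    "read_single_cell_table",
    "write_single_cell_table",
    "align_features",
    "read_profiles",
    "write_profiles",
]

#: metadata roles every table must carry
_REQUIRED_ROLES = ("plate", "well", "compound")
_OPTIONAL_ROLES = ("moa", "dose")

#: canonical metadata column names used internally
META_COLS = ["plate_id", "well_id", "compound_id", "moa", "dose"]


class SchemaError(ValueError):
    """A column-role mapping does not match the file."""


class AlignmentError(ValueError):
    """No common feature subset across tables."""


class WellKey(NamedTuple):
    plate_id: str
    well_id: str
    compound_id: str


@dataclass
class SingleCellTable:
    """Per-cell feature matrix plus per-row well/plate/compound metadata.

    ``meta`` has columns plate_id, well_id, compound_id, moa, dose (moa/dose
    may be missing values); ``X`` is the M_total x D float matrix; ``features``
    the ordered feature-name list.
    """

    meta: pd.DataFrame
    X: np.ndarray
    features: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if len(self.features) != len(set(self.features)):
            raise ValueError("duplicate feature names")
        if self.X.shape[1] != len(self.features):
            raise ValueError(
                f"feature count mismatch: matrix has {self.X.shape[1]} columns, "
                f"{len(self.features)} names"
            )
        if len(self.meta) != self.X.shape[0]:
            raise ValueError("metadata row count does not match feature matrix")
        for col in ("plate_id", "well_id", "compound_id"):
            vals = self.meta[col]
            if vals.isna().any() or (vals.astype(str).str.len() == 0).any():
                raise ValueError(f"empty or missing {col} in metadata")
        self.meta = self.meta.reset_index(drop=True)

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def well_keys(self) -> list[WellKey]:
        """Unique wells in first-appearance order."""
        seen: dict[WellKey, None] = {}
        for p, w, c in zip(
            self.meta["plate_id"], self.meta["well_id"], self.meta["compound_id"]
        ):
            seen.setdefault(WellKey(str(p), str(w), str(c)), None)
        return list(seen)

    def iter_wells(self) -> Iterator["SampleSet"]:
        """Yield one SampleSet per well, cells in table order."""
        keys = pd.MultiIndex.from_frame(
            self.meta[["plate_id", "well_id", "compound_id"]].astype(str)
        )
        for key in self.well_keys():
            mask = np.asarray(keys == key)
            yield SampleSet(well_key=key, X=self.X[mask])

    def subset_rows(self, mask: np.ndarray) -> "SingleCellTable":
        return SingleCellTable(
            meta=self.meta.loc[np.asarray(mask)].reset_index(drop=True),
            X=self.X[np.asarray(mask)],
            features=list(self.features),
        )


@dataclass
class SampleSet:
    """The M x D feature set of one well — one "set" in the Deep Sets sense."""

    well_key: WellKey
    X: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 2 or self.X.shape[0] < 1:
            raise ValueError("sample set must be an M x D matrix with M >= 1")

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]


@dataclass
class ProfileTable:
    """One aggregated profile vector per well, plus carried metadata.

    ``method`` tags the aggregation route: "average" or "model".
    """

    meta: pd.DataFrame  # plate_id, well_id, compound_id, moa, dose
    values: np.ndarray  # K x L
    method: str
    features: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("profile values must be 2-D")
        if len(self.meta) != self.values.shape[0]:
            raise ValueError("metadata row count does not match profiles")
        if not self.features:
            self.features = [f"f_{i + 1:04d}" for i in range(self.values.shape[1])]
        if len(self.features) != self.values.shape[1]:
            raise ValueError("feature-name count does not match profile width")
        keys = list(
            zip(self.meta["plate_id"], self.meta["well_id"], self.meta["compound_id"])
        )
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate well keys in profile table")
        self.meta = self.meta.reset_index(drop=True)

    @property
    def n_wells(self) -> int:
        return self.values.shape[0]

    def well_keys(self) -> list[WellKey]:
        return [
            WellKey(str(p), str(w), str(c))
            for p, w, c in zip(
                self.meta["plate_id"], self.meta["well_id"], self.meta["compound_id"]
            )
        ]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_DEFAULT_SCHEMA = {
    "plate": "Metadata_Plate",
    "well": "Metadata_Well",
    "compound": "Metadata_Compound",
    "moa": "Metadata_MoA",
    "dose": "Metadata_Dose",
}


def read_single_cell_table(
    path, schema: dict[str, str] | None = None
) -> SingleCellTable:
    """Read a per-cell CSV into a :class:`SingleCellTable`.

    ``schema`` maps metadata roles (plate, well, compound, optionally moa and
    dose) to column names. Every column not named in the schema is treated as
    a numeric feature; non-numeric cells become missing values to be dropped
    downstream.
    """
    schema = dict(_DEFAULT_SCHEMA if schema is None else schema)
    df = pd.read_csv(path, float_precision="round_trip")
    if len(df) == 0:
        raise ValueError(f"no data rows in {path}")
    for role in _REQUIRED_ROLES:
        col = schema.get(role)
        if col is None or col not in df.columns:
            raise SchemaError(
                f"required metadata role {role!r} maps to column {col!r}, "
                f"absent from {path}"
            )
    meta = pd.DataFrame(
        {
            "plate_id": df[schema["plate"]].astype(str),
            "well_id": df[schema["well"]].astype(str),
            "compound_id": df[schema["compound"]].astype(str),
        }
    )
    for role, col in (("moa", schema.get("moa")), ("dose", schema.get("dose"))):
        name = "moa" if role == "moa" else "dose"
        if col is not None and col in df.columns:
            meta[name] = df[col]
        else:
            meta[name] = np.nan
    schema_cols = {c for c in schema.values() if c in df.columns}
    feat_cols = [c for c in df.columns if c not in schema_cols]
    feats = df[feat_cols].apply(pd.to_numeric, errors="coerce")
    return SingleCellTable(meta=meta, X=feats.to_numpy(np.float64), features=feat_cols)


def write_single_cell_table(table: SingleCellTable, path) -> str:
    """Write a single-cell table in the canonical CSV dialect."""
    out = pd.DataFrame(
        {
            "Metadata_Plate": table.meta["plate_id"],
            "Metadata_Well": table.meta["well_id"],
            "Metadata_Compound": table.meta["compound_id"],
            "Metadata_MoA": table.meta["moa"],
            "Metadata_Dose": table.meta["dose"],
        }
    )
    for j, name in enumerate(table.features):
        out[name] = table.X[:, j]
    out.to_csv(path, index=False)
    return str(path)


def align_features(tables: Sequence[SingleCellTable]) -> list[SingleCellTable]:
    """Restrict every table to the shared feature subset, in sorted order.

    Mirrors the practice of keeping only the features available on all plates;
    the retained features are ordered lexicographically for cross-run
    determinism.
    """
    if not tables:
        raise ValueError("need at least one table")
    common = set(tables[0].features)
    for t in tables[1:]:
        common &= set(t.features)
    if not common:
        raise AlignmentError("no features shared by all tables")
    order = sorted(common)
    out = []
    for t in tables:
        idx = [t.features.index(f) for f in order]
        out.append(
            SingleCellTable(meta=t.meta.copy(), X=t.X[:, idx], features=list(order))
        )
    return out


def write_profiles(profiles: ProfileTable, path) -> str:
    """Write a profile table to CSV; round-trip safe to full stored precision."""
    if profiles.n_wells == 0:
        raise ValueError("refusing to write an empty profile table")
    out = pd.DataFrame(
        {
            "Metadata_Plate": profiles.meta["plate_id"],
            "Metadata_Well": profiles.meta["well_id"],
            "Metadata_Compound": profiles.meta["compound_id"],
            "Metadata_MoA": profiles.meta["moa"],
            "Metadata_Dose": profiles.meta["dose"],
            "Metadata_Method": profiles.method,
        }
    )
    for j, name in enumerate(profiles.features):
        out[name] = profiles.values[:, j]
    out.to_csv(path, index=False, float_format="%.17g")
    return str(path)


def read_profiles(path) -> ProfileTable:
    df = pd.read_csv(path, float_precision="round_trip")
    meta = pd.DataFrame(
        {
            "plate_id": df["Metadata_Plate"].astype(str),
            "well_id": df["Metadata_Well"].astype(str),
            "compound_id": df["Metadata_Compound"].astype(str),
            "moa": df.get("Metadata_MoA", np.nan),
            "dose": df.get("Metadata_Dose", np.nan),
        }
    )
    method = str(df["Metadata_Method"].iloc[0]) if "Metadata_Method" in df else "average"
    feat_cols = [c for c in df.columns if not c.startswith("Metadata_")]
    return ProfileTable(
        meta=meta,
        values=df[feat_cols].to_numpy(np.float64),
        method=method,
        features=feat_cols,
    )
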