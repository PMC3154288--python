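"""The FeatureTable container: records x named numeric attributes.

Thin wrapper around a pandas DataFrame carrying the numeric matrix, the
single categorical ``nterm`` column, the T/F labels and the schema. Every
downstream stage (cleaning, weighting, clustering, trees, networks) consumes
and returns FeatureTables; column order always follows schema order for the
surviving attributes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import DEFAULT_SCHEMA, FeatureSchema


@dataclass
class FeatureTable:
    values: pd.DataFrame  # index = record ids, columns = numeric attributes
    labels: pd.Series | None = None  # values "T"/"F" (or NaN), same index
    nterm: pd.Series | None = None  # categorical column, same index
    schema: FeatureSchema = field(default_factory=lambda: DEFAULT_SCHEMA)

    def __post_init__(self) -> None:
        if self.labels is not None:
            self.labels = self.labels.reindex(self.values.index)
        if self.nterm is not None:
            self.nterm = self.nterm.reindex(self.values.index)

    # -- basic introspection -------------------------------------------------
    @property
    def record_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def attributes(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_records(self) -> int:
        return len(self.values)

    @property
    def n_attributes(self) -> int:
        return self.values.shape[1]

    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def label_array(self) -> np.ndarray:
        """Labels as a 0/1 array (T=0, F=1); raises on missing labels."""
        if self.labels is None or self.labels.isna().any():
            raise ValueError("table has records without T/F labels")
        return (self.labels == "F").to_numpy(dtype=int)

    # -- construction helpers ------------------------------------------------
    def select(self, attributes: list[str]) -> "FeatureTable":
        """Restrict to the given numeric attributes (schema order preserved)."""
        ordered = sorted(attributes, key=self.schema.sort_key)
        return FeatureTable(
            self.values[ordered].copy(), self.labels, self.nterm, self.schema
        )

    def take(self, indices: np.ndarray) -> "FeatureTable":
        return FeatureTable(
            self.values.iloc[indices].copy(),
            None if self.labels is None else self.labels.iloc[indices].copy(),
            None if self.nterm is None else self.nterm.iloc[indices].copy(),
            self.schema,
        )

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.values.copy(),
            None if self.labels is None else self.labels.copy(),
            None if self.nterm is None else self.nterm.copy(),
            self.schema,
        )

    # -- I/O -----------------------------------------------------------------
    def to_tsv(self, path: str | Path, manifest: str | Path | None = None) -> None:
        """Write TSV: id column first, numeric attributes, nterm, label last."""
        df = self.values.copy()
        if self.nterm is not None:
            df["nterm"] = self.nterm
        if self.labels is not None:
            df["label"] = self.labels
        df.index.name = "id"
        df.to_csv(path, sep="\t")
        if manifest is not None:
            with open(manifest, "w") as fh:
                json.dump(self.schema.to_manifest(), fh, indent=1)

    @classmethod
    def from_tsv(cls, path: str | Path, schema: FeatureSchema | None = None) -> "FeatureTable":
        df = pd.read_csv(path, sep="\t", index_col="id")
        df.index = df.index.astype(str)
        labels = df.pop("label") if "label" in df.columns else None
        nterm = df.pop("nterm") if "nterm" in df.columns else None
        return cls(df.astype(float), labels, nterm, schema or DEFAULT_SCHEMA)
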