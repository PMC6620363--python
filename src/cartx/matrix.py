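"""Expression matrices and feature annotation.

The two containers used throughout the package are thin, validated wrappers
around :class:`pandas.DataFrame`:

* :class:`ExpressionMatrix` — a features × samples numeric matrix carrying a
  unit tag (``raw_count``, ``FPKM``, ``TPM`` or ``log2``).
* :class:`FeatureAnnotation` — per-feature metadata: symbol, biotype
  (coding / lncRNA / miRNA / other), feature length in bp, functional flags
  (TF, histone, membrane, CAR, CD19) and optional cell-type marker membership.

Both round-trip losslessly through TSV at six significant digits.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

VALID_UNITS = ("raw_count", "FPKM", "TPM", "log2")
VALID_BIOTYPES = ("coding", "lncRNA", "miRNA", "other")
VALID_FLAGS = ("TF", "histone", "membrane", "CAR", "CD19")

FLOAT_FORMAT = "%.6g"


class CartxError(ValueError):
    """Base class for validation errors raised by this package."""


@dataclass
class ExpressionMatrix:
    """A features × samples expression matrix with a unit tag.

    Parameters
    ----------
    data
        DataFrame indexed by feature id, columns are sample ids.
    unit
        One of ``raw_count``, ``FPKM``, ``TPM``, ``log2``. Values must be
        non-negative for the first three.
    """

    data: pd.DataFrame
    unit: str = "raw_count"

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise CartxError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise CartxError(f"duplicate feature ids: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise CartxError(f"duplicate sample ids: {dups[:5]}")
        self.data = self.data.astype(float)
        if self.unit != "log2" and (self.data.values < 0).any():
            raise CartxError(f"negative values not allowed for unit {self.unit!r}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_features(self, features: Sequence[str]) -> "ExpressionMatrix":
        missing = [f for f in features if f not in self.data.index]
        if missing:
            raise CartxError(f"features not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.data.loc[list(features)], self.unit)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.data.columns]
        if missing:
            raise CartxError(f"samples not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.data[list(samples)], self.unit)

    def log2(self, pseudocount: float = 1.0) -> "ExpressionMatrix":
        """Return log2(value + pseudocount) with unit tag ``log2``."""
        if self.unit == "log2":
            raise CartxError("matrix is already on log2 scale")
        return ExpressionMatrix(np.log2(self.data + pseudocount), "log2")

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)

    @classmethod
    def from_tsv(cls, path: str | Path, unit: str) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col="feature_id")
        return cls(df, unit)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ExpressionMatrix({self.n_features} features x {self.n_samples} "
            f"samples, unit={self.unit!r})"
        )


ANNOTATION_COLUMNS = ["symbol", "biotype", "length_bp", "flags", "marker_of"]


@dataclass
class FeatureAnnotation:
    """Per-feature metadata table.

    ``table`` is indexed by feature id with columns ``symbol``, ``biotype``,
    ``length_bp``, ``flags`` (comma-joined subset of TF/histone/membrane/
    CAR/CD19, empty string for none) and ``marker_of`` (cell-type name or
    empty string).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ANNOTATION_COLUMNS if c not in self.table.columns]
        if missing:
            raise CartxError(f"annotation missing columns: {missing}")
        if self.table.index.has_duplicates:
            raise CartxError("duplicate feature ids in annotation")
        bad = set(self.table["biotype"]) - set(VALID_BIOTYPES)
        if bad:
            raise CartxError(f"unknown biotypes: {sorted(bad)}")
        if (self.table["length_bp"] < 1).any():
            bad_ids = self.table.index[self.table["length_bp"] < 1].tolist()
            raise CartxError(f"length_bp < 1 for features: {bad_ids[:5]}")
        self.table = self.table.copy()
        self.table["flags"] = self.table["flags"].fillna("").astype(str)
        self.table["marker_of"] = self.table["marker_of"].fillna("").astype(str)
        for flags in self.table["flags"]:
            for f in _split_flags(flags):
                if f not in VALID_FLAGS:
                    raise CartxError(f"unknown flag {f!r}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.table.index)

    def lengths(self, features: Iterable[str]) -> pd.Series:
        features = list(features)
        missing = [f for f in features if f not in self.table.index]
        if missing:
            raise CartxError(f"no annotation for features: {missing[:5]}")
        return self.table.loc[features, "length_bp"].astype(float)

    def has_flag(self, flag: str) -> pd.Series:
        """Boolean Series over features: does the feature carry ``flag``?"""
        if flag not in VALID_FLAGS:
            raise CartxError(f"unknown flag {flag!r}")
        return self.table["flags"].map(lambda s: flag in _split_flags(s))

    def features_with_flag(self, flag: str) -> list[str]:
        mask = self.has_flag(flag)
        return list(self.table.index[mask])

    def features_of_biotype(self, biotype: str) -> list[str]:
        if biotype not in VALID_BIOTYPES:
            raise CartxError(f"unknown biotype {biotype!r}")
        return list(self.table.index[self.table["biotype"] == biotype])

    def markers_of(self, cell_type: str) -> list[str]:
        return list(self.table.index[self.table["marker_of"] == cell_type])

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureAnnotation":
        df = pd.read_csv(path, sep="\t", index_col="feature_id", keep_default_na=False)
        df["length_bp"] = df["length_bp"].astype(int)
        return cls(df)


def _split_flags(flags: str) -> list[str]:
    return [f for f in str(flags).split(",") if f]


@dataclass
class SampleMetadata:
    """Sample table: patient, timepoint (D0/D14) and remission label (R/NR)."""

    table: pd.DataFrame  # index: sample_id; columns: patient, timepoint, remission

    def __post_init__(self) -> None:
        for col in ("patient", "timepoint", "remission"):
            if col not in self.table.columns:
                raise CartxError(f"metadata missing column {col!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def patients(self) -> list[str]:
        return list(dict.fromkeys(self.table["patient"]))

    def remissive_patients(self) -> list[str]:
        sub = self.table[self.table["remission"] == "R"]
        return list(dict.fromkeys(sub["patient"]))

    def sample_for(self, patient: str, timepoint: str) -> str:
        mask = (self.table["patient"] == patient) & (self.table["timepoint"] == timepoint)
        hits = list(self.table.index[mask])
        if len(hits) != 1:
            raise CartxError(f"expected one sample for ({patient}, {timepoint}); got {hits}")
        return hits[0]

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleMetadata":
        return cls(pd.read_csv(path, sep="\t", index_col="sample_id"))
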