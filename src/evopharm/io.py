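"""Readers and writers for the tabular formats used across the pipeline.

All tables are TSV with mandatory headers, decimal point, no thousands
separators. Gene identity is by symbol string, case-sensitive. Floats are
written at full precision so that write-then-read round-trips are exact for
integers and well below 1e-12 for reals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger("evopharm")

VARIANT_COLUMNS = [
    "patient_id", "sample_id", "timepoint", "gene", "protein_change",
    "ref_count", "alt_count",
]


class ValidationError(ValueError):
    """Raised when an input table violates its contract."""


# ---------------------------------------------------------------- variants

@dataclass
class VariantTable:
    """Per-patient, per-timepoint somatic variant records with read counts.

    One row per (sample, gene, protein_change). VAF = alt/(alt+ref) is
    computed on demand. Patients need >=2 distinct timepoints to be eligible
    for longitudinal analysis; `longitudinal_patients` lists them.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"missing column(s): {missing}")
        df = df[VARIANT_COLUMNS].reset_index(drop=True)
        for col in ("timepoint", "ref_count", "alt_count"):
            values = pd.to_numeric(df[col], errors="coerce")
            if values.isna().any() or (values % 1 != 0).any():
                bad = int(df.index[values.isna() | (values % 1 != 0)][0])
                raise ValidationError(f"non-integer {col} at row {bad}")
            df[col] = values.astype(int)
        if (df["timepoint"] < 1).any():
            bad = int(df.index[df["timepoint"] < 1][0])
            raise ValidationError(f"timepoint < 1 at row {bad}")
        if ((df["ref_count"] < 0) | (df["alt_count"] < 0)).any():
            raise ValidationError("negative read count")
        total = df["ref_count"] + df["alt_count"]
        if (total <= 0).any():
            bad = int(df.index[total <= 0][0])
            raise ValidationError(f"zero coverage (ref+alt == 0) at row {bad}")
        key = df[["sample_id", "gene", "protein_change"]]
        dup = key.duplicated()
        if dup.any():
            bad = int(df.index[dup][0])
            raise ValidationError(
                f"duplicate (sample_id, gene, protein_change) key at row {bad}"
            )
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def vaf(self) -> pd.Series:
        """Variant allele fraction alt/(alt+ref) per row."""
        return self.df["alt_count"] / (self.df["alt_count"] + self.df["ref_count"])

    def with_vaf(self) -> pd.DataFrame:
        return self.df.assign(vaf=self.vaf())

    def timepoints(self, patient_id: str) -> list[int]:
        sub = self.df[self.df["patient_id"] == patient_id]
        return sorted(sub["timepoint"].unique())

    def longitudinal_patients(self) -> list[str]:
        counts = self.df.groupby("patient_id")["timepoint"].nunique()
        return sorted(counts.index[counts >= 2])


def read_variant_table(path: str | Path) -> VariantTable:
    df = pd.read_csv(path, sep="\t")
    return VariantTable(df)


def write_variant_table(table: VariantTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


# -------------------------------------------------------------- expression

@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of non-negative expression values."""

    df: pd.DataFrame  # index: gene symbols; columns: sample ids

    def __post_init__(self) -> None:
        if self.df.index.duplicated().any():
            raise ValidationError("duplicate gene identifiers")
        if self.df.columns.duplicated().any():
            raise ValidationError("duplicate sample identifiers")
        values = self.df.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValidationError("non-finite expression values")
        if (values < 0).any():
            raise ValidationError("negative expression values")

    @property
    def genes(self) -> list[str]:
        return list(self.df.index)

    @property
    def samples(self) -> list[str]:
        return list(self.df.columns)


def read_expression(path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.df.to_csv(path, sep="\t")


# --------------------------------------------------------------- gene sets

@dataclass
class GeneSetCollection:
    """Named ordered gene sets, as exchanged in GMT files."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def items(self):
        return self.sets.items()


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: name, description, then tab-separated genes."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"GMT line {lineno}: expected >=3 tab-separated fields"
                )
            name, description, *genes = fields
            genes = [g for g in genes if g]
            if name in sets:
                raise ValidationError(f"GMT line {lineno}: duplicate set name {name!r}")
            sets[name] = genes
            descriptions[name] = description
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as handle:
        for name, genes in collection.items():
            desc = collection.descriptions.get(name, "")
            handle.write("\t".join([name, desc, *genes]) + "\n")


# -------------------------------------------------------- survival / misc

def read_survival_table(path: str | Path) -> pd.DataFrame:
    """Survival TSV: subject_id, time_months, event, score."""
    df = pd.read_csv(path, sep="\t")
    required = ["subject_id", "time_months", "event", "score"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"missing column(s): {missing}")
    if (df["time_months"] <= 0).any():
        raise ValidationError("time_months must be > 0")
    if not df["event"].isin([0, 1]).all():
        raise ValidationError("event must be 0 or 1")
    return df


def write_survival_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_fusion_table(path: str | Path) -> dict[str, set[str]]:
    """Fusion TSV (sample_id, fusion_name) -> sample -> set of fusions."""
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "fusion_name"):
        if col not in df.columns:
            raise ValidationError(f"missing column(s): ['{col}']")
    out: dict[str, set[str]] = {}
    for sample, sub in df.groupby("sample_id"):
        out[str(sample)] = set(sub["fusion_name"].astype(str))
    return out


def write_fusion_table(fusions: dict[str, set[str]], path: str | Path) -> None:
    rows = [
        {"sample_id": sample, "fusion_name": name}
        for sample in sorted(fusions)
        for name in sorted(fusions[sample])
    ]
    pd.DataFrame(rows, columns=["sample_id", "fusion_name"]).to_csv(
        path, sep="\t", index=False
    )


def read_dose_response_csv(path: str | Path) -> pd.DataFrame:
    """Plate CSV: dose_a, dose_b, viability, replicate."""
    df = pd.read_csv(path)
    required = ["dose_a", "dose_b", "viability", "replicate"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"missing column(s): {missing}")
    return df
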