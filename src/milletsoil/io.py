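"""Data model and CSV/TSV input-output for trial tables.

Two containers cover everything downstream:

* :class:`SoilSampleTable` — replicate-level soil observations keyed by
  (treatment, year, replicate), one column per measured variable.
* :class:`AbundanceTable` — a taxa x samples relative-abundance matrix for
  one kingdom, with the phylum encoded in each taxon label.

Files are plain UTF-8 CSV/TSV with a single header row and '.' decimals so
fixtures round-trip bit-identically.  Missing values are rejected: the
trial is complete-case.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

KINGDOMS = ("bacteria", "fungi", "archaea")

KEY_COLUMNS = ("treatment", "year", "replicate")

#: Separator between phylum and species in taxon labels, e.g.
#: ``Proteobacteria|sp003``.
TAXON_SEP = "|"


class SchemaError(ValueError):
    """A table does not match the expected column layout."""


class ValidationError(ValueError):
    """A table parses but violates a data-model invariant."""


def phylum_of(taxon: str) -> str:
    """Phylum part of a ``phylum|species`` taxon label (the label itself
    when no separator is present)."""
    return taxon.split(TAXON_SEP, 1)[0]


@dataclass
class SoilSampleTable:
    """Replicate-level soil observations.

    ``data`` holds one row per (treatment, year, replicate) with the key
    columns first and one numeric column per variable.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    @property
    def variables(self) -> list[str]:
        return [c for c in self.data.columns if c not in KEY_COLUMNS]

    @property
    def sample_keys(self) -> list[str]:
        return [
            f"{t}_{y}_{r}"
            for t, y, r in zip(self.data["treatment"], self.data["year"],
                               self.data["replicate"])
        ]

    def validate(self) -> None:
        df = self.data
        for col in KEY_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"missing required column {col!r}")
        if df.empty:
            raise SchemaError("soil table has no rows")
        dup = df.duplicated(subset=list(KEY_COLUMNS))
        if dup.any():
            key = df.loc[dup.idxmax(), list(KEY_COLUMNS)].tolist()
            raise ValidationError(f"duplicate sample key {tuple(key)}")
        for var in self.variables:
            col = pd.to_numeric(df[var], errors="coerce")
            if col.isna().any():
                row = int(col.isna().idxmax())
                raise ValidationError(
                    f"non-numeric or missing value in {var!r} at row {row}")
            self.data[var] = col.astype(float)
        if "pH" in df.columns:
            ph = df["pH"].to_numpy(float)
            if ((ph <= 0) | (ph >= 14)).any():
                raise ValidationError("pH outside (0, 14)")
        for var in self.variables:
            if var == "pH":
                continue
            if (df[var].to_numpy(float) <= 0).any() and var != "EMF":
                raise ValidationError(f"non-positive value in {var!r}")

    def subset(self, year: int | None = None,
               treatment: str | None = None) -> "SoilSampleTable":
        df = self.data
        if year is not None:
            df = df[df["year"] == year]
        if treatment is not None:
            df = df[df["treatment"] == treatment]
        return SoilSampleTable(df.reset_index(drop=True).copy())

    def group_means(self) -> pd.DataFrame:
        """Mean of every variable per (treatment, year)."""
        return (self.data.groupby(["treatment", "year"], observed=True)
                [self.variables].mean().reset_index())


@dataclass
class AbundanceTable:
    """Taxa x samples abundance matrix for one kingdom.

    ``matrix`` rows are taxa (index = labels like ``Phylum|species``),
    columns are sample keys.  ``as_relative`` converts counts to
    column-normalized relative abundances; the conversion is idempotent.
    """

    kingdom: str
    matrix: pd.DataFrame

    def __post_init__(self) -> None:
        if self.kingdom not in KINGDOMS:
            raise ValidationError(f"unknown kingdom {self.kingdom!r}")
        vals = self.matrix.to_numpy(float)
        if (vals < 0).any():
            raise ValidationError("negative abundance value")
        zero = vals.sum(axis=0) == 0
        if zero.any():
            bad = self.matrix.columns[np.argmax(zero)]
            raise ValidationError(f"sample {bad!r} has zero total abundance")

    @property
    def taxa(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def samples(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def phyla(self) -> list[str]:
        return [phylum_of(t) for t in self.taxa]

    def as_relative(self) -> "AbundanceTable":
        # exact no-op on already-normalized data keeps the conversion
        # idempotent and file round-trips bit-stable
        if self.is_relative():
            return self
        rel = self.matrix.div(self.matrix.sum(axis=0), axis=1)
        return AbundanceTable(self.kingdom, rel)

    def is_relative(self, tol: float = 1e-9) -> bool:
        return bool(np.allclose(self.matrix.sum(axis=0), 1.0, atol=tol))


def load_soil_table(path) -> SoilSampleTable:
    """Read a replicate-level soil CSV (header row, key columns +
    variables)."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"empty or headerless file: {path}") from exc
    return SoilSampleTable(df)


def write_soil_table(table: SoilSampleTable, path) -> None:
    table.data.to_csv(path, index=False)


def load_abundance_table(path, kingdom: str) -> AbundanceTable:
    """Read a taxa x samples TSV (first column taxon label) and return
    relative abundances; count matrices are renormalized per sample."""
    df = pd.read_csv(path, sep="\t", index_col=0,
                     float_precision="round_trip")
    if df.shape[1] == 0:
        raise SchemaError(f"no sample columns in {path}")
    table = AbundanceTable(kingdom, df.astype(float))
    return table.as_relative()


def write_abundance_table(table: AbundanceTable, path) -> None:
    out = table.matrix.copy()
    out.index.name = "taxon"
    out.to_csv(path, sep="\t")
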