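"""Shared in-memory containers for the biomarker pipeline.

The pipeline moves three kinds of tabular data around:

* :class:`NpxMatrix` — targeted-proteomics measurements on the NPX scale
  (log2-normalized protein expression from proximity extension assays),
  samples in rows, proteins in columns, with a per-protein limit of
  detection (LOD) and a per-sample panel-run label.
* :class:`CountMatrix` — small-RNA sequencing counts, miRNA in rows,
  samples in columns, with an optional per-sample technical batch label.
* sample metadata — a plain :class:`pandas.DataFrame` validated by
  :func:`validate_meta`, one row per sample, carrying the clinical and
  technical covariates (cohort, compartment, MS subtype, age, sex, dates,
  conversion status).

Statistical results are plain DataFrames with the columns listed in
:data:`STAT_COLUMNS`; signature sets are ``dict[str, list[str]]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "NpxMatrix",
    "CountMatrix",
    "validate_meta",
    "validate_signatures",
    "check_aligned",
    "STAT_COLUMNS",
    "stat_frame",
    "DAYS_PER_YEAR",
    "META_COLUMNS",
    "SUBTYPES",
    "COMPARTMENTS",
]

#: Calendar convention used for every date difference in the package.
DAYS_PER_YEAR = 365.25

SUBTYPES = ("control", "RR", "SP", "PP")
COMPARTMENTS = ("serum", "CSF")

META_COLUMNS = [
    "sample_id",
    "individual_id",
    "cohort",
    "compartment",
    "subtype",
    "age",
    "sex",
    "sample_date",
    "converter",
    "conversion_date",
]

#: Standard column layout for per-analyte statistical results.
STAT_COLUMNS = ["analyte_id", "comparison", "beta", "se", "p", "fdr", "n"]


class FormatError(ValueError):
    """Raised when an input file or container violates the format contract."""


@dataclass
class NpxMatrix:
    """Samples x proteins NPX matrix with censoring information.

    Attributes
    ----------
    values
        float DataFrame, samples in rows, proteins in columns. Entries that
        are below the limit of detection hold ``NaN`` until
        :func:`msmark.proteomics.impute_lod` replaces them by LOD/sqrt(2).
    lod
        per-protein limit of detection (NPX units), indexed like columns.
    run
        per-sample panel-run label, indexed like rows.
    below_lod
        boolean DataFrame, same shape as ``values``; True marks censored
        entries as flagged by the vendor export (or the simulator).
    """

    values: pd.DataFrame
    lod: pd.Series
    run: pd.Series
    below_lod: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.below_lod is None:
            self.below_lod = pd.DataFrame(
                False, index=self.values.index, columns=self.values.columns
            )
        self.validate()

    # -- views ---------------------------------------------------------
    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def protein_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_proteins(self) -> int:
        return self.values.shape[1]

    # -- contracts -----------------------------------------------------
    def validate(self) -> None:
        self.values.index.name = "sample_id"
        self.values.columns.name = "protein_id"
        if self.values.columns.duplicated().any():
            raise FormatError("duplicate protein IDs in NPX matrix")
        if self.values.index.duplicated().any():
            raise FormatError("duplicate sample IDs in NPX matrix")
        missing_lod = self.values.columns.difference(self.lod.index)
        if len(missing_lod):
            raise FormatError(
                "missing LOD for measured protein(s): " + ", ".join(map(str, missing_lod))
            )
        self.lod = self.lod.reindex(self.values.columns).astype(float)
        if not np.isfinite(self.lod.to_numpy()).all():
            bad = self.lod.index[~np.isfinite(self.lod.to_numpy())]
            raise FormatError("non-finite LOD for: " + ", ".join(map(str, bad)))
        self.run = self.run.reindex(self.values.index)
        if self.run.isna().any():
            raise FormatError("missing run label for some samples")
        self.below_lod = self.below_lod.reindex(
            index=self.values.index, columns=self.values.columns
        ).fillna(False).astype(bool)

    def copy(self) -> "NpxMatrix":
        return NpxMatrix(
            self.values.copy(), self.lod.copy(), self.run.copy(), self.below_lod.copy()
        )

    def subset(self, samples=None, proteins=None) -> "NpxMatrix":
        """Row/column subset keeping LOD, run and censoring flags aligned."""
        v = self.values
        if samples is not None:
            v = v.loc[samples]
        if proteins is not None:
            v = v[proteins]
        return NpxMatrix(
            v.copy(),
            self.lod.loc[v.columns].copy(),
            self.run.loc[v.index].copy(),
            self.below_lod.loc[v.index, v.columns].copy(),
        )


@dataclass
class CountMatrix:
    """miRNA x sample non-negative integer count matrix.

    ``batch`` is optional at construction (raw vendor exports carry no batch
    column); analyses that adjust for batch attach it from the metadata via
    :meth:`attach_batch`.
    """

    counts: pd.DataFrame
    batch: pd.Series | None = None

    def __post_init__(self) -> None:
        self.validate()

    @property
    def mirna_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def validate(self) -> None:
        self.counts.index.name = "mirna_id"
        self.counts.columns.name = "sample_id"
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()].unique()
            raise FormatError("duplicate miRNA IDs: " + ", ".join(map(str, dup)))
        if self.counts.columns.duplicated().any():
            raise FormatError("duplicate sample IDs in count matrix")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                i, j = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
                raise FormatError(
                    f"non-integer count at ({self.counts.index[i]}, {self.counts.columns[j]})"
                )
            self.counts = self.counts.round().astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative count at ({self.counts.index[i]}, {self.counts.columns[j]})"
            )
        if self.batch is not None:
            self.batch = self.batch.reindex(self.counts.columns)
            if self.batch.isna().any():
                raise FormatError("missing batch label for some samples")

    def attach_batch(self, meta: pd.DataFrame) -> "CountMatrix":
        batch = meta.set_index("sample_id")["batch"].reindex(self.counts.columns)
        return CountMatrix(self.counts.copy(), batch)

    def copy(self) -> "CountMatrix":
        return CountMatrix(self.counts.copy(), None if self.batch is None else self.batch.copy())


def validate_meta(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a sample-metadata table.

    Enforces: required columns present, ISO-8601 dates, positive ages,
    subtype/compartment drawn from the known vocabularies, unique sample IDs,
    unique (individual, compartment, date) triples, and the converter
    contract (``conversion_date`` present iff ``converter``).
    """
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError("metadata missing column(s): " + ", ".join(missing))
    meta = meta.copy()
    for col in ("sample_date", "conversion_date"):
        meta[col] = pd.to_datetime(meta[col], format="ISO8601", errors="raise")
    meta["converter"] = meta["converter"].astype(bool)
    meta["age"] = meta["age"].astype(float)
    if (meta["age"] <= 0).any():
        raise FormatError("ages must be > 0")
    for col, vocab in (("subtype", SUBTYPES), ("compartment", COMPARTMENTS)):
        bad = set(meta[col]) - set(vocab)
        if bad:
            raise FormatError(f"unknown {col} value(s): {sorted(bad)}")
    if meta["sample_id"].duplicated().any():
        raise FormatError("duplicate sample IDs in metadata")
    key = meta[["individual_id", "compartment", "sample_date"]]
    if key.duplicated().any():
        raise FormatError("duplicate (individual, compartment, date) in metadata")
    has_date = meta["conversion_date"].notna()
    if (has_date != meta["converter"]).any():
        raise FormatError("conversion_date must be present iff converter is True")
    return meta


def validate_signatures(sigs: dict[str, list[str]]) -> dict[str, list[str]]:
    for name, ids in sigs.items():
        if not ids:
            raise FormatError(f"empty signature set: {name}")
        if len(set(ids)) != len(ids):
            raise FormatError(f"duplicate miRNA IDs in signature set {name}")
    return sigs


def check_aligned(sample_ids, meta: pd.DataFrame, context: str = "matrix") -> None:
    """Raise if any measured sample is absent from the metadata."""
    orphans = pd.Index(sample_ids).difference(meta["sample_id"])
    if len(orphans):
        raise FormatError(
            f"{context}: sample(s) without metadata: " + ", ".join(map(str, orphans[:10]))
        )


def stat_frame(records: list[dict]) -> pd.DataFrame:
    """Assemble per-analyte results into the standard StatResult layout."""
    df = pd.DataFrame(records, columns=STAT_COLUMNS + [c for c in (records[0] if records else {}) if c not in STAT_COLUMNS])
    for col in STAT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return df
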