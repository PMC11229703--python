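"""Readers and writers for the pipeline's tabular formats.

Formats
-------
NPX (wide)
    CSV, one row per sample. First column ``sample_id``, second column
    ``run`` (panel-run label), remaining columns one per protein. Censored
    (below-LOD) cells hold the literal token ``<LOD``; unparseable numeric
    cells become missing. A companion LOD file (CSV: ``protein_id,lod``)
    supplies one limit of detection per protein.
Counts
    TSV, first column ``mirna_id``, remaining columns one per sample,
    non-negative integer cells.
Metadata
    CSV with the columns in :data:`msmark.datamodel.META_COLUMNS`;
    dates ISO-8601.
Signatures
    GMT-like: one tab-separated line per cell type —
    ``name<TAB>description<TAB>miRNA1<TAB>miRNA2...``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datamodel import (
    META_COLUMNS,
    CountMatrix,
    FormatError,
    NpxMatrix,
    validate_meta,
    validate_signatures,
)

log = logging.getLogger("msmark")

BELOW_LOD_TOKEN = "<LOD"


# ---------------------------------------------------------------------------
# NPX
# ---------------------------------------------------------------------------

def read_npx(path, lod_path) -> NpxMatrix:
    """Read a wide-format NPX CSV plus its per-protein LOD file."""
    raw = pd.read_csv(path, dtype=str).set_index("sample_id")
    if "run" not in raw.columns:
        raise FormatError("NPX file lacks the 'run' column")
    run = raw.pop("run")
    below = raw == BELOW_LOD_TOKEN
    values = raw.mask(below).apply(pd.to_numeric, errors="coerce")
    lod_tab = pd.read_csv(lod_path)
    lod = lod_tab.set_index("protein_id")["lod"].astype(float)
    missing = values.columns.difference(lod.index)
    if len(missing):
        raise FormatError(
            "missing LOD for measured protein(s): " + ", ".join(map(str, missing))
        )
    m = NpxMatrix(values, lod.loc[values.columns], run, below)
    log.info("read_npx: %d samples x %d proteins from %s", m.n_samples, m.n_proteins, path)
    return m


def write_npx(m: NpxMatrix, path, lod_path) -> None:
    out = m.values.astype(object).copy()
    out = out.mask(m.below_lod, BELOW_LOD_TOKEN)
    out.insert(0, "run", m.run)
    out.index.name = "sample_id"
    out.to_csv(path)
    pd.DataFrame({"protein_id": m.lod.index, "lod": m.lod.to_numpy()}).to_csv(
        lod_path, index=False
    )


def read_npx_long(path, lod_path) -> NpxMatrix:
    """Read a long-format vendor-style export.

    Expected columns: ``sample_id, run, protein_id, npx``; censored rows may
    carry the ``<LOD`` token in the ``npx`` column.
    """
    tab = pd.read_csv(path, dtype=str)
    need = {"sample_id", "run", "protein_id", "npx"}
    if not need.issubset(tab.columns):
        raise FormatError("long NPX file needs columns " + ", ".join(sorted(need)))
    below_mask = tab["npx"] == BELOW_LOD_TOKEN
    tab = tab.assign(_below=below_mask, npx=pd.to_numeric(tab["npx"], errors="coerce"))
    values = tab.pivot(index="sample_id", columns="protein_id", values="npx")
    below = tab.pivot(index="sample_id", columns="protein_id", values="_below").fillna(False)
    run = tab.drop_duplicates("sample_id").set_index("sample_id")["run"]
    lod = pd.read_csv(lod_path).set_index("protein_id")["lod"].astype(float)
    missing = values.columns.difference(lod.index)
    if len(missing):
        raise FormatError(
            "missing LOD for measured protein(s): " + ", ".join(map(str, missing))
        )
    return NpxMatrix(values, lod.loc[values.columns], run.loc[values.index], below)


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------

def read_counts(path) -> CountMatrix:
    raw = pd.read_csv(path, sep="\t")
    raw = raw.set_index(raw.columns[0])
    raw.index.name = "mirna_id"
    arr = raw.apply(pd.to_numeric, errors="raise")
    bad = ~np.isclose(arr.to_numpy(dtype=float), np.round(arr.to_numpy(dtype=float)))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise FormatError(f"non-integer count at ({arr.index[i]}, {arr.columns[j]})")
    neg = arr.to_numpy() < 0
    if neg.any():
        i, j = np.argwhere(neg)[0]
        raise FormatError(f"negative count at ({arr.index[i]}, {arr.columns[j]})")
    c = CountMatrix(arr.astype(np.int64))
    log.info("read_counts: %d miRNAs x %d samples from %s", *c.counts.shape, path)
    return c


def write_counts(c: CountMatrix, path) -> None:
    c.counts.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Metadata
# ---------------------------------------------------------------------------

def read_meta(path) -> pd.DataFrame:
    meta = pd.read_csv(path)
    return validate_meta(meta)


def write_meta(meta: pd.DataFrame, path) -> None:
    out = meta.copy()
    for col in ("sample_date", "conversion_date"):
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
    out[META_COLUMNS + [c for c in out.columns if c not in META_COLUMNS]].to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# Signature sets (GMT-like)
# ---------------------------------------------------------------------------

def read_signatures(path) -> dict[str, list[str]]:
    sigs: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"line {lineno}: empty signature set")
            name, _desc, *ids = parts
            ids = [i for i in ids if i]
            if not ids:
                raise FormatError(f"line {lineno}: empty signature set {name!r}")
            if len(set(ids)) != len(ids):
                raise FormatError(f"line {lineno}: duplicate miRNA ID in set {name!r}")
            sigs[name] = ids
    return validate_signatures(sigs)


def write_signatures(sigs: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, ids in sigs.items():
            fh.write("\t".join([name, "."] + list(ids)) + "\n")


# ---------------------------------------------------------------------------
# key=value config
# ---------------------------------------------------------------------------

def read_config(path) -> dict[str, str]:
    """Parse a plain-text ``key=value`` config file (one pair per line,
    ``#`` comments allowed)."""
    cfg: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise FormatError(f"config line without '=': {line!r}")
            key, val = line.split("=", 1)
            cfg[key.strip()] = val.strip()
    return cfg
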