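"""Shared statistical helpers: BH-FDR and design-matrix construction."""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_fdr", "design_matrix"]


def bh_fdr(p) -> np.ndarray:
    """Benjamini–Hochberg adjusted P-values (step-up).

    NaN entries are passed through untouched and do not count toward the
    number of tests. The family is exactly the non-missing entries of ``p``:
    callers are responsible for handing in one comparison family at a time
    (one comparison x compartment x cohort).
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.sum():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def design_matrix(
    meta: pd.DataFrame,
    covars: list[str],
    group_col: str | None = None,
    group_levels: tuple | None = None,
) -> pd.DataFrame:
    """Build a full-rank fixed-effect design matrix.

    Columns: intercept; optional group indicator (1 for ``group_levels[1]``,
    0 for ``group_levels[0]``, named ``group``); then one column per
    covariate — ``age`` centred, ``sex`` as an M indicator, any other
    covariate (e.g. ``batch``) expanded to treatment-coded dummies.
    Rows follow ``meta``; callers subset/drop-NA beforehand.
    """
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(meta))}
    if group_col is not None:
        if group_levels is None:
            raise ValueError("group_levels required with group_col")
        grp = meta[group_col]
        unknown = set(grp) - set(group_levels)
        if unknown:
            raise ValueError(f"samples outside contrast levels: {sorted(unknown)}")
        cols["group"] = (grp == group_levels[1]).to_numpy(dtype=float)
    for cov in covars:
        if cov == "age":
            age = meta["age"].to_numpy(dtype=float)
            cols["age"] = age - age.mean()
        elif cov == "sex":
            cols["sex_M"] = (meta["sex"] == "M").to_numpy(dtype=float)
        else:
            series = meta[cov].astype("category")
            for level in series.cat.categories[1:]:
                cols[f"{cov}_{level}"] = (series == level).to_numpy(dtype=float)
    return pd.DataFrame(cols, index=meta.index)
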