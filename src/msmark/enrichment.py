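"""Cell-type signature extraction and single-sample enrichment scoring.

miRNA expression profiles are strongly cell-type specific, so the cell
types shedding miRNAs into a biofluid can be read off a sample's profile.
For each cell type in an expression atlas, the signature is the top-k
(default 10) most highly expressed miRNAs in that cell type. A sample's
enrichment score for a cell type is an ssGSEA-style statistic: miRNAs are
ranked by expression within the sample and a weighted Kolmogorov–Smirnov
random walk accumulates rank^w-weighted steps for in-signature miRNAs
against uniform steps for the rest; the score is the sum of the walk's
in-minus-out deviations over the full list. Scores are rank-based, hence
invariant to any strictly monotone transform of a sample's profile; they
are normalized across samples by the global score range.
"""

from __future__ import annotations

import logging
from importlib import resources

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata

from .datamodel import stat_frame, validate_signatures
from .stats import bh_fdr

log = logging.getLogger("msmark")

__all__ = [
    "load_atlas",
    "load_toy_atlas",
    "extract_signatures",
    "ssgsea_score",
    "score_matrix",
    "score_associations",
]


def load_atlas(path) -> pd.DataFrame:
    """Load a cell-type x miRNA expression atlas (TSV, first column the
    cell-type name)."""
    atlas = pd.read_csv(path, sep="\t", index_col=0)
    return atlas.astype(float)


def load_toy_atlas() -> pd.DataFrame:
    """Packaged synthetic toy atlas (immune + neurological cell types).

    A small, fully synthetic stand-in for a published cell-type miRNA
    atlas, for tests and worked examples only.
    """
    with resources.files("msmark.data").joinpath("toy_atlas.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", index_col=0).astype(float)


def extract_signatures(atlas: pd.DataFrame, k: int = 10) -> dict[str, list[str]]:
    """Top-k most highly expressed miRNAs per cell type.

    ``atlas`` is cell-type x miRNA. Ties at the rank-k boundary are broken
    lexicographically (logged). Cell types with fewer than k miRNAs yield a
    smaller set with a warning.
    """
    sigs: dict[str, list[str]] = {}
    for cell_type, row in atlas.iterrows():
        expr = row.dropna()
        if len(expr) < k:
            log.warning("extract_signatures: %s has only %d miRNAs (< k=%d)",
                        cell_type, len(expr), k)
        # sort by (-expression, name): lexicographic winner on ties
        order = sorted(expr.index, key=lambda mid: (-expr[mid], str(mid)))
        top = order[: min(k, len(order))]
        if len(order) > len(top) and expr[order[len(top) - 1]] == expr[order[len(top)]]:
            log.info("extract_signatures: tie at rank %d for %s broken lexicographically",
                     k, cell_type)
        sigs[str(cell_type)] = [str(m) for m in top]
    return validate_signatures(sigs)


def ssgsea_score(x: pd.Series, sig: list[str], w: float = 0.25) -> float:
    """Weighted-KS random-walk enrichment score of one sample for one set.

    miRNAs are ranked by expression (descending; average ranks for ties, so
    the top miRNA carries rank N). Walking down the descending-expression
    list (ties ordered by name), an in-set miRNA advances the in-walk by
    rank^w / (sum of rank^w over the set's measured miRNAs) and any out-set
    miRNA advances the out-walk by 1/(N − m). The score is the sum over all
    positions of (in-walk − out-walk). Raises if no signature miRNA is
    measured.
    """
    x = x.dropna()
    members = [m for m in sig if m in x.index]
    if not members:
        raise ValueError("signature has no overlap with measured miRNAs")
    names = np.array(x.index, dtype=object)
    vals = x.to_numpy(dtype=float)
    ranks = rankdata(vals)  # ascending with average ties: top expression = N
    order = sorted(range(len(vals)), key=lambda i: (-vals[i], str(names[i])))
    in_set = np.isin(names, members)
    n, m = len(vals), int(in_set.sum())
    if n == m:
        raise ValueError("signature covers the whole measured universe")
    weights = ranks**w
    denom_in = weights[in_set].sum()
    p_in = p_out = 0.0
    score = 0.0
    for i in order:
        if in_set[i]:
            p_in += weights[i] / denom_in
        else:
            p_out += 1.0 / (n - m)
        score += p_in - p_out
    return float(score)


def score_matrix(
    x: pd.DataFrame,
    sigs: dict[str, list[str]],
    w: float = 0.25,
    normalize: bool = True,
) -> pd.DataFrame:
    """Sample x cell-type enrichment-score matrix.

    ``x`` is miRNA x sample (QC-passed, normalized, log-transformed).
    With ``normalize``, scores are divided by the global range
    (max − min over the whole matrix), the usual cross-sample calibration
    for single-sample enrichment.
    """
    validate_signatures(sigs)
    scores = pd.DataFrame(index=x.columns, columns=list(sigs), dtype=float)
    for sample in x.columns:
        profile = x[sample]
        for cell_type, sig in sigs.items():
            try:
                scores.loc[sample, cell_type] = ssgsea_score(profile, sig, w)
            except ValueError:
                log.info("score_matrix: no overlap for %s in %s", cell_type, sample)
                scores.loc[sample, cell_type] = np.nan
    if normalize:
        rng = np.nanmax(scores.to_numpy()) - np.nanmin(scores.to_numpy())
        if rng > 0:
            scores = scores / rng
    return scores


def score_associations(
    scores: pd.DataFrame,
    anchor: pd.Series,
    t: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Associate enrichment scores with an anchor protein and with time
    from conversion.

    Per cell type: (a) OLS score ~ anchor, Wald P on the anchor slope; (b)
    if ``t`` is given (frame with columns ``t``, ``status`` as produced by
    :func:`msmark.longitudinal.time_from_conversion`), the interaction
    model score ~ t + status + t:status. BH-FDR across cell types within
    each family. Returns ``{"anchor": ..., "time": ...}``.
    """
    idx = scores.index.intersection(anchor.index)
    a = anchor.loc[idx].to_numpy(dtype=float)
    anchor_rows = []
    for cell_type in scores.columns:
        y = scores.loc[idx, cell_type].to_numpy(dtype=float)
        ok = ~np.isnan(y)
        X = np.column_stack([np.ones(ok.sum()), a[ok] - a[ok].mean()])
        fit = sm.OLS(y[ok], X).fit()
        anchor_rows.append({"analyte_id": cell_type, "comparison": "score_vs_anchor",
                            "beta": float(fit.params[1]), "se": float(fit.bse[1]),
                            "p": float(fit.pvalues[1]), "n": int(ok.sum())})
    anchor_res = stat_frame(anchor_rows)
    anchor_res["fdr"] = bh_fdr(anchor_res["p"])
    out = {"anchor": anchor_res}

    if t is not None:
        from .longitudinal import interaction_model
        out["time"] = interaction_model(scores.loc[idx.intersection(t.index)],
                                        _fake_meta(scores.index), t, covars=())
    return out


def _fake_meta(sample_ids) -> pd.DataFrame:
    """Minimal metadata frame for score-level interaction fits (scores carry
    no age/sex; the time model here uses none)."""
    return pd.DataFrame({
        "sample_id": list(sample_ids),
        "individual_id": list(sample_ids),
        "age": 50.0,
        "sex": "F",
    }).set_index("sample_id").reset_index()
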