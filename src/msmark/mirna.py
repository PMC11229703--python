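"""miRNA library QC, normalization and descriptive structure.

Sequencing libraries from cell-free serum and CSF are shallow and variable;
two per-sample gates guard against failed libraries:

* library diversity — the number of distinct miRNAs with count > 1 must
  exceed 100 in serum and 50 in CSF (CSF profiles are intrinsically less
  diverse);
* library size — total aligned miRNA counts must exceed 1000.

Depth normalization uses DESeq2-style median-of-ratios size factors, and the
descriptive transform is log2(count / size_factor + 1). Inferential results
use the negative-binomial model in :mod:`msmark.nbde`; the log transform only
feeds correlations, PCA and plots.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA

from .datamodel import CountMatrix, FormatError

log = logging.getLogger("msmark")

__all__ = ["library_qc", "qc_report", "size_factors", "transform_log", "pca_profiles"]

DIVERSITY_CUTOFF = {"serum": 100, "CSF": 50}
LIBSIZE_CUTOFF = {"serum": 1000, "CSF": 1000}


def qc_report(c: CountMatrix, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-sample QC table: diversity, total counts, pass flag, reason."""
    compartment = meta.set_index("sample_id")["compartment"].reindex(c.sample_ids)
    if compartment.isna().any():
        missing = list(compartment.index[compartment.isna()])
        raise FormatError("unknown compartment for sample(s): " + ", ".join(missing[:10]))
    unknown = set(compartment) - set(DIVERSITY_CUTOFF)
    if unknown:
        raise FormatError(f"unknown compartment value(s): {sorted(unknown)}")
    diversity = (c.counts > 1).sum(axis=0)
    total = c.counts.sum(axis=0)
    rows = []
    for s in c.sample_ids:
        comp = compartment[s]
        div_ok = diversity[s] > DIVERSITY_CUTOFF[comp]
        tot_ok = total[s] > LIBSIZE_CUTOFF[comp]
        reason = "" if div_ok and tot_ok else ("low diversity" if not div_ok else "low total")
        if not div_ok and not tot_ok:
            reason = "low diversity; low total"
        rows.append({
            "sample_id": s, "compartment": comp,
            "diversity": int(diversity[s]), "total": int(total[s]),
            "passed": bool(div_ok and tot_ok), "reason": reason,
        })
    return pd.DataFrame(rows)


def library_qc(c: CountMatrix, meta: pd.DataFrame) -> CountMatrix:
    """Drop samples failing the compartment-specific diversity/size gates."""
    report = qc_report(c, meta)
    failed = report.loc[~report["passed"]]
    for _, row in failed.iterrows():
        log.info("library_qc: dropping %s (%s; diversity=%d, total=%d)",
                 row["sample_id"], row["reason"], row["diversity"], row["total"])
    keep = report.loc[report["passed"], "sample_id"]
    out = CountMatrix(
        c.counts[keep].copy(),
        None if c.batch is None else c.batch.loc[keep].copy(),
    )
    return out


def size_factors(c: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    The reference profile is the per-miRNA geometric mean over samples,
    restricted to miRNAs with no zero count; each sample's factor is the
    median ratio of its counts to the reference. If no miRNA is all-nonzero
    the method falls back to total-count ratios (logged).
    """
    counts = c.counts.to_numpy(dtype=float)
    nonzero = (counts > 0).all(axis=1)
    if nonzero.sum() == 0:
        log.warning("size_factors: no all-nonzero miRNA; falling back to total-count ratios")
        totals = counts.sum(axis=0)
        s = totals / sps.gmean(totals)
        return pd.Series(s, index=c.sample_ids, name="size_factor")
    ref = sps.gmean(counts[nonzero], axis=1)  # per-miRNA geometric mean
    ratios = counts[nonzero] / ref[:, None]
    s = np.median(ratios, axis=0)
    s = s / sps.gmean(s)
    return pd.Series(s, index=c.sample_ids, name="size_factor")


def transform_log(c: CountMatrix, s: pd.Series) -> pd.DataFrame:
    """log2(count / size_factor + 1), miRNA x sample."""
    s = s.reindex(c.sample_ids)
    if (s <= 0).any() or s.isna().any():
        raise ValueError("size factors must be positive for every sample")
    return np.log2(c.counts / s + 1.0)


def pca_profiles(x: pd.DataFrame, n_components: int = 10) -> tuple[pd.DataFrame, np.ndarray]:
    """Centered PCA of sample profiles.

    ``x`` is feature x sample (as produced by :func:`transform_log`); samples
    are projected onto the top components. Returns (scores: sample x PC,
    explained-variance fractions).
    """
    mat = x.T.to_numpy(dtype=float)
    n_components = min(n_components, mat.shape[0] - 1 if mat.shape[0] > 1 else 1, mat.shape[1])
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(mat - mat.mean(axis=0, keepdims=True))
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return pd.DataFrame(scores, index=x.columns, columns=cols), pca.explained_variance_ratio_
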