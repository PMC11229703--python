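"""Proteomics quality control: LOD imputation, detection filtering and
cross-run bridging harmonization.

The targeted-proteomics platform reports protein levels in NPX units (log2
scale) together with a per-protein limit of detection (LOD). Values below
the LOD are censored; they are replaced by LOD/sqrt(2), the conventional
substitute for left-censored log-scale measurements. Proteins detected in
no more than 25% of samples are removed before analysis.

When two panel runs are pooled, a set of bridging samples measured on both
runs estimates a per-protein between-run offset. Proteins whose bridging
measurements correlate well between runs (Pearson r above a gate, default
0.7) are harmonized by shifting the second run so that the median bridging
difference vanishes; poorly correlated proteins are excluded from pooled
analyses (per-cohort analyses still use them, since those never mix runs).
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datamodel import FormatError, NpxMatrix

log = logging.getLogger("msmark")

__all__ = ["impute_lod", "detection_filter", "bridge_correct"]


def impute_lod(m: NpxMatrix) -> NpxMatrix:
    """Replace every below-LOD entry by LOD/sqrt(2) for its protein.

    Above-LOD entries are untouched; applying the operation twice equals
    applying it once (the censoring flags are preserved, the values are
    deterministic functions of the LOD).
    """
    out = m.copy()
    fill = out.lod / math.sqrt(2.0)
    for j, protein in enumerate(out.values.columns):
        mask = out.below_lod[protein]
        if mask.any():
            out.values.loc[mask, protein] = fill.iloc[j]
    if out.values.isna().any().any():
        n = int(out.values.isna().sum().sum())
        log.warning("impute_lod: %d entries remain missing (not LOD-flagged)", n)
    return out


def detection_filter(m: NpxMatrix, min_frac: float = 0.25) -> NpxMatrix:
    """Keep proteins detected (above LOD) in strictly more than ``min_frac``
    of the samples of this matrix.

    The detection rate is evaluated on the matrix as given; to apply the
    rule per compartment and cohort — the intended use — subset the matrix
    to one stratum first.
    """
    detected = ~m.below_lod & m.values.notna()
    frac = detected.mean(axis=0)
    keep = frac > min_frac
    dropped = list(m.values.columns[~keep])
    if dropped:
        log.info("detection_filter: dropped %d/%d proteins (<= %.0f%% detection): %s",
                 len(dropped), m.n_proteins, 100 * min_frac, ", ".join(map(str, dropped[:15])))
    if keep.sum() == 0:
        warnings.warn("detection_filter removed every protein", stacklevel=2)
    return m.subset(proteins=m.values.columns[keep])


def bridge_correct(
    run1: NpxMatrix,
    run2: NpxMatrix,
    bridging_ids: list[str],
    r_gate: float = 0.7,
    offset_stat: str = "median",
) -> tuple[NpxMatrix, pd.DataFrame]:
    """Harmonize a second panel run onto the first via bridging samples.

    For each protein shared by both runs, the Pearson correlation ``r``
    between the two runs over the bridging samples is computed. If
    ``r > r_gate`` (strict), the per-protein offset ``delta`` — by default
    the median over bridging samples of (run1 − run2) — is added to every
    run-2 value of that protein, making the median bridging difference
    exactly zero. Proteins at or below the gate are flagged
    ``excluded-from-pooling`` and left uncorrected.

    Returns the pooled matrix (all run-1 samples plus corrected run-2
    samples, bridging re-measurements dropped in favour of their run-1
    originals; only gate-passing proteins) and a per-protein report with
    columns ``protein_id, r, delta, decision``. Run-1 values are never
    altered.
    """
    bridging_ids = list(bridging_ids)
    if len(bridging_ids) < 3:
        raise FormatError("bridging correction needs at least 3 bridging samples")
    for ids, run, name in ((run1.sample_ids, run1, "run1"), (run2.sample_ids, run2, "run2")):
        missing = pd.Index(bridging_ids).difference(ids)
        if len(missing):
            raise FormatError(f"bridging sample(s) missing from {name}: {', '.join(missing)}")
    shared = run1.protein_ids.intersection(run2.protein_ids)
    if offset_stat not in ("median", "mean"):
        raise ValueError("offset_stat must be 'median' or 'mean'")

    b1 = run1.values.loc[bridging_ids, shared]
    b2 = run2.values.loc[bridging_ids, shared]
    rows = []
    corrected2 = run2.values[shared].copy()
    for protein in shared:
        x, y = b1[protein], b2[protein]
        ok = x.notna() & y.notna()
        if ok.sum() < 3 or x[ok].std() == 0 or y[ok].std() == 0:
            r = np.nan
        else:
            r = float(sps.pearsonr(x[ok], y[ok]).statistic)
        if np.isfinite(r) and r > r_gate:
            diffs = (x - y)[ok]
            delta = float(diffs.median() if offset_stat == "median" else diffs.mean())
            corrected2[protein] = corrected2[protein] + delta
            decision = "corrected"
        else:
            delta = np.nan
            decision = "excluded-from-pooling"
        rows.append({"protein_id": protein, "r": r, "delta": delta, "decision": decision})
    report = pd.DataFrame(rows)
    keep = report.loc[report["decision"] == "corrected", "protein_id"]
    log.info("bridge_correct: %d/%d shared proteins pass r > %.2f",
             len(keep), len(shared), r_gate)

    run2_keep = run2.sample_ids.difference(bridging_ids)
    pooled_values = pd.concat(
        [run1.values[keep], corrected2.loc[run2_keep, keep]], axis=0
    )
    pooled_below = pd.concat(
        [run1.below_lod[keep], run2.below_lod.loc[run2_keep, keep]], axis=0
    )
    pooled_run = pd.concat([run1.run, run2.run.loc[run2_keep]])
    pooled = NpxMatrix(pooled_values, run1.lod.loc[keep], pooled_run, pooled_below)
    return pooled, report
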