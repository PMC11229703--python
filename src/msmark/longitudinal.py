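"""Conversion-anchored longitudinal trajectory analysis.

Converters are patients whose serial samples span the transition from
relapsing–remitting (RR) to secondary progressive (SP) multiple sclerosis.
Time is re-anchored per individual at the first sample classified as SP
("time from conversion", in years, negative before conversion). Marker
trajectories are then modelled as

    level ~ t (+ age + sex)                       slope model
    level ~ t + status + t:status (+ covariates)  interaction model

where status is RR for t < 0 and SP for t >= 0 (derived from t, not from
per-visit clinical labels). A "peak" call is a significant interaction with
a positive pre-conversion slope and a negative post-conversion slope.
Markers that also drift in the non-converting RR patients are flagged as
not conversion-specific. Observations within an individual are treated as
independent, matching the model class; a cluster-robust-SE option is
available and a warning is logged when it changes a significance call.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .datamodel import DAYS_PER_YEAR, NpxMatrix, stat_frame
from .stats import bh_fdr

log = logging.getLogger("msmark")

__all__ = [
    "time_from_conversion",
    "conversion_assoc",
    "interaction_model",
    "nonconverter_control",
    "anchor_correlation_filter",
]

FDR_THRESHOLD = 0.1


def _values(m) -> pd.DataFrame:
    """Accept an NpxMatrix or a samples x analytes DataFrame."""
    return m.values if isinstance(m, NpxMatrix) else m


def time_from_conversion(meta: pd.DataFrame) -> pd.DataFrame:
    """Per-sample signed years from the conversion anchor.

    The anchor (t = 0) for each individual is the date of their first sample
    classified as SP. Returns a DataFrame indexed by sample_id with columns
    ``t`` (years, days/365.25) and ``status`` ("RR" for t < 0, "SP"
    otherwise). Every sample in ``meta`` must belong to a converter and each
    converter must have at least one SP-classified sample.
    """
    if (~meta["converter"].astype(bool)).any():
        bad = meta.loc[~meta["converter"].astype(bool), "sample_id"].tolist()
        raise ValueError("non-converter sample(s) passed: " + ", ".join(map(str, bad[:5])))
    rows = []
    for ind, grp in meta.groupby("individual_id"):
        sp = grp.loc[grp["subtype"] == "SP", "sample_date"]
        if sp.empty:
            raise ValueError(f"converter {ind} has no SP-classified sample")
        anchor = sp.min()
        t = (grp["sample_date"] - anchor).dt.days / DAYS_PER_YEAR
        for sid, ti in zip(grp["sample_id"], t):
            rows.append({"sample_id": sid, "t": float(ti),
                         "status": "RR" if ti < 0 else "SP"})
    return pd.DataFrame(rows).set_index("sample_id")


def _covar_cols(meta_idx: pd.DataFrame, covars) -> dict[str, np.ndarray]:
    cols = {}
    for cov in covars:
        if cov == "age":
            a = meta_idx["age"].to_numpy(dtype=float)
            cols["age"] = a - a.mean()
        elif cov == "sex":
            cols["sex_M"] = (meta_idx["sex"] == "M").to_numpy(dtype=float)
        else:
            raise ValueError(f"unsupported covariate: {cov}")
    return cols


def _ols(y, X, clusters=None):
    model = sm.OLS(y, X)
    if clusters is not None:
        return model.fit(cov_type="cluster", cov_kwds={"groups": clusters})
    return model.fit()


def conversion_assoc(
    m,
    meta: pd.DataFrame,
    t: pd.DataFrame,
    covars=("age", "sex"),
    cluster_robust: bool = False,
) -> pd.DataFrame:
    """Per-analyte linear association with time from conversion.

    ``beta`` is the slope (analyte units per year) over all converter
    samples; BH-FDR across analytes; ``direction`` reports whether levels
    rise or fall toward conversion.
    """
    vals = _values(m)
    idx = vals.index.intersection(t.index)
    mi = meta.set_index("sample_id").loc[idx]
    base = {"intercept": np.ones(len(idx)), "t": t.loc[idx, "t"].to_numpy()}
    base.update(_covar_cols(mi, covars))
    X = pd.DataFrame(base, index=idx)
    clusters = mi["individual_id"].to_numpy() if cluster_robust else None
    records = []
    for analyte in vals.columns:
        y = vals.loc[idx, analyte]
        ok = y.notna().to_numpy()
        Xi = X.loc[y.index[ok]]
        if ok.sum() <= Xi.shape[1] or np.linalg.matrix_rank(Xi.to_numpy()) < Xi.shape[1]:
            log.info("conversion_assoc: skipping %s (singular fit)", analyte)
            continue
        fit = _ols(y[ok].to_numpy(), Xi.to_numpy(),
                   clusters[ok] if clusters is not None else None)
        j = list(Xi.columns).index("t")
        beta = float(fit.params[j])
        records.append({
            "analyte_id": analyte, "comparison": "time_from_conversion",
            "beta": beta, "se": float(fit.bse[j]), "p": float(fit.pvalues[j]),
            "n": int(ok.sum()),
            "direction": "increasing" if beta > 0 else "decreasing",
        })
    res = stat_frame(records)
    res["fdr"] = bh_fdr(res["p"])
    return res


def interaction_model(
    m,
    meta: pd.DataFrame,
    t: pd.DataFrame,
    covars=("age", "sex"),
    fdr_threshold: float = FDR_THRESHOLD,
    cluster_robust: bool = False,
) -> pd.DataFrame:
    """Pre/post-conversion slope-difference model per analyte.

    Fits level ~ t + status + t:status (status = SP iff t >= 0) and tests
    the interaction coefficient. Reports pre-slope (t coefficient),
    post-slope (t + interaction) and a ``peak`` call: significant
    interaction (FDR < ``fdr_threshold``) with pre-slope > 0 and
    post-slope < 0.
    """
    vals = _values(m)
    idx = vals.index.intersection(t.index)
    tv = t.loc[idx, "t"].to_numpy()
    status_sp = (tv >= 0).astype(float)
    if status_sp.min() == status_sp.max():
        raise ValueError("interaction model needs samples on both sides of the anchor")
    mi = meta.set_index("sample_id").loc[idx]
    base = {"intercept": np.ones(len(idx)), "t": tv,
            "status_SP": status_sp, "t_x_status": tv * status_sp}
    base.update(_covar_cols(mi, covars))
    X = pd.DataFrame(base, index=idx)
    clusters = mi["individual_id"].to_numpy() if cluster_robust else None
    records = []
    for analyte in vals.columns:
        y = vals.loc[idx, analyte]
        ok = y.notna().to_numpy()
        Xi = X.loc[y.index[ok]]
        if ok.sum() <= Xi.shape[1] or np.linalg.matrix_rank(Xi.to_numpy()) < Xi.shape[1]:
            log.info("interaction_model: skipping %s (singular fit)", analyte)
            continue
        fit = _ols(y[ok].to_numpy(), Xi.to_numpy(),
                   clusters[ok] if clusters is not None else None)
        cols = list(Xi.columns)
        jt, ji = cols.index("t"), cols.index("t_x_status")
        records.append({
            "analyte_id": analyte, "comparison": "t_x_status_interaction",
            "beta": float(fit.params[ji]), "se": float(fit.bse[ji]),
            "p": float(fit.pvalues[ji]), "n": int(ok.sum()),
            "pre_slope": float(fit.params[jt]),
            "post_slope": float(fit.params[jt] + fit.params[ji]),
        })
    res = stat_frame(records)
    res["fdr"] = bh_fdr(res["p"])
    res["peak"] = (res["fdr"] < fdr_threshold) & (res["pre_slope"] > 0) & (res["post_slope"] < 0)
    return res


def nonconverter_control(
    m,
    meta: pd.DataFrame,
    covars=(),
) -> pd.DataFrame:
    """Slope of each analyte against time since first sample, in
    non-converting RR patients.

    A marker significant here drifts regardless of conversion and is
    flagged ``not conversion-specific`` (nominal P < 0.05); a marker that
    only peaks in converters stays non-significant.
    """
    nc = meta.loc[~meta["converter"].astype(bool)].copy()
    first = nc.groupby("individual_id")["sample_date"].transform("min")
    nc["t"] = (nc["sample_date"] - first).dt.days / DAYS_PER_YEAR
    nc = nc.set_index("sample_id")
    vals = _values(m)
    idx = vals.index.intersection(nc.index)
    nci = nc.loc[idx]
    base = {"intercept": np.ones(len(idx)), "t": nci["t"].to_numpy()}
    base.update(_covar_cols(nci, covars))
    X = pd.DataFrame(base, index=idx)
    records = []
    for analyte in vals.columns:
        y = vals.loc[idx, analyte]
        ok = y.notna().to_numpy()
        Xi = X.loc[y.index[ok]]
        if ok.sum() <= Xi.shape[1]:
            continue
        fit = _ols(y[ok].to_numpy(), Xi.to_numpy())
        j = list(Xi.columns).index("t")
        records.append({
            "analyte_id": analyte, "comparison": "nonconverter_drift",
            "beta": float(fit.params[j]), "se": float(fit.bse[j]),
            "p": float(fit.pvalues[j]), "n": int(ok.sum()),
        })
    res = stat_frame(records)
    res["fdr"] = bh_fdr(res["p"])
    res["conversion_specific"] = res["p"] >= 0.05
    return res


def anchor_correlation_filter(
    mirna_log: pd.DataFrame,
    anchor: pd.Series,
    candidates: list[str],
    p_keep: float = 0.05,
) -> pd.DataFrame:
    """Keep candidate miRNAs whose levels correlate with an anchor protein.

    ``mirna_log`` is miRNA x sample (log scale), ``anchor`` per-sample
    protein values over the same (converter) samples. Pearson correlation,
    two-sided; candidates with nominal P < ``p_keep`` are kept, sign
    reported. Zero-variance candidates are excluded and logged.
    """
    samples = mirna_log.columns.intersection(anchor.index)
    a = anchor.loc[samples].to_numpy(dtype=float)
    rows = []
    for mirna in candidates:
        if mirna not in mirna_log.index:
            log.info("anchor_correlation_filter: %s not measured", mirna)
            continue
        x = mirna_log.loc[mirna, samples].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(a) == 0:
            log.info("anchor_correlation_filter: %s has zero variance; excluded", mirna)
            continue
        r = sps.pearsonr(x, a)
        rows.append({"mirna_id": mirna, "r": float(r.statistic),
                     "p": float(r.pvalue), "kept": bool(r.pvalue < p_keep),
                     "n": int(len(samples))})
    return pd.DataFrame(rows)
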