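"""Cross-sectional protein comparisons with covariate adjustment and BH-FDR.

Two-group contrasts use Welch t-tests; k-group contrasts use one-way ANOVA,
with an optional Shapiro–Wilk gate that switches to Kruskal–Wallis (or
Mann–Whitney for two groups) when normality is rejected. Covariate-adjusted
contrasts fit per-protein linear models NPX ~ group + age + sex and report
the Wald statistic for the group term. P-values are BH-adjusted within the
family of proteins tested in one comparison (one compartment, one cohort);
the study-wide significance convention is FDR < 0.1.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .datamodel import NpxMatrix, check_aligned, stat_frame
from .stats import bh_fdr, design_matrix

log = logging.getLogger("msmark")

__all__ = [
    "group_test",
    "adjusted_test",
    "compartment_compare",
    "profile_correlations",
]

FDR_THRESHOLD = 0.1


def _align(m: NpxMatrix, meta: pd.DataFrame) -> pd.DataFrame:
    check_aligned(m.sample_ids, meta, "NPX matrix")
    return meta.set_index("sample_id").loc[m.sample_ids]


def group_test(
    m: NpxMatrix,
    meta: pd.DataFrame,
    groups: list[str],
    group_col: str = "subtype",
    normality_gate: bool = False,
    gate_alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-protein unadjusted group comparison.

    Two groups: Welch t-test, ``beta`` = mean(groups[1]) − mean(groups[0]).
    More than two: one-way ANOVA (no single effect size; ``beta`` is NaN).
    With ``normality_gate``, a Shapiro–Wilk test per group at ``gate_alpha``
    switches the analyte to the rank-based test (Mann–Whitney /
    Kruskal–Wallis).
    """
    if len(groups) < 2:
        raise ValueError("need at least two group labels")
    mm = _align(m, meta)
    label = f"{group_col}:" + "_vs_".join(groups)
    records = []
    for protein in m.protein_ids:
        vals = m.values[protein]
        series = [vals[(mm[group_col] == g).to_numpy()].dropna() for g in groups]
        if any(len(s) < 2 for s in series):
            log.info("group_test: skipping %s (group with n<2)", protein)
            continue
        if all(s.nunique() <= 1 for s in series) and len({s.iloc[0] for s in series}) == 1:
            # all values identical everywhere: no evidence either way
            records.append({"analyte_id": protein, "comparison": label,
                            "beta": 0.0, "se": np.nan, "p": 1.0, "n": sum(map(len, series))})
            continue
        use_rank = False
        if normality_gate:
            use_rank = any(
                len(s) >= 3 and s.nunique() > 1 and sps.shapiro(s).pvalue < gate_alpha
                for s in series
            )
        beta = se = np.nan
        if len(groups) == 2:
            a, b = series
            beta = float(b.mean() - a.mean())
            se = float(np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b)))
            if use_rank:
                p = float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)
            else:
                p = float(sps.ttest_ind(a, b, equal_var=False).pvalue)
        else:
            if use_rank:
                p = float(sps.kruskal(*series).pvalue)
            else:
                p = float(sps.f_oneway(*series).pvalue)
        records.append({"analyte_id": protein, "comparison": label,
                        "beta": beta, "se": se, "p": p, "n": int(sum(map(len, series)))})
    res = stat_frame(records)
    res["fdr"] = bh_fdr(res["p"])
    return res


def posthoc_pairwise(
    m: NpxMatrix,
    meta: pd.DataFrame,
    groups: list[str],
    significant: list[str],
    group_col: str = "subtype",
) -> pd.DataFrame:
    """Pairwise Welch t-tests within the significant analyte set, BH within
    that family."""
    frames = []
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1:]:
            sub = m.subset(proteins=significant)
            frames.append(group_test(sub, meta, [g1, g2], group_col))
    out = pd.concat(frames, ignore_index=True)
    out["fdr"] = bh_fdr(out["p"])
    return out


def adjusted_test(
    m: NpxMatrix,
    meta: pd.DataFrame,
    contrast: tuple[str, str],
    covars: list[str] = ("age", "sex"),
    group_col: str = "subtype",
) -> pd.DataFrame:
    """Per-protein linear model NPX ~ group + covariates (default age, sex).

    ``beta`` is the NPX difference contrast[1] − contrast[0]; P is the Wald
    test for the group coefficient. Samples with missing covariates are
    excluded listwise (logged).
    """
    mm = _align(m, meta)
    keep = mm[group_col].isin(contrast)
    mm = mm.loc[keep.to_numpy()]
    needed = [c for c in covars if c != "sex"] + (["sex"] if "sex" in covars else [])
    complete = mm[needed].notna().all(axis=1) if needed else pd.Series(True, index=mm.index)
    if (~complete).any():
        log.info("adjusted_test: excluding %d samples with missing covariates",
                 int((~complete).sum()))
        mm = mm.loc[complete]
    X = design_matrix(mm, list(covars), group_col=group_col, group_levels=contrast)
    label = f"{group_col}:{contrast[0]}_vs_{contrast[1]}|" + "+".join(covars)
    records = []
    for protein in m.protein_ids:
        y = m.values.loc[mm.index, protein]
        ok = y.notna().to_numpy()
        if ok.sum() < X.shape[1] + 1:
            continue
        Xi, yi = X.loc[y.index[ok]], y[ok]
        if np.linalg.matrix_rank(Xi.to_numpy()) < Xi.shape[1]:
            log.info("adjusted_test: skipping %s (collinear design)", protein)
            continue
        fit = sm.OLS(yi.to_numpy(), Xi.to_numpy()).fit()
        j = list(Xi.columns).index("group")
        records.append({"analyte_id": protein, "comparison": label,
                        "beta": float(fit.params[j]), "se": float(fit.bse[j]),
                        "p": float(fit.pvalues[j]), "n": int(ok.sum())})
    res = stat_frame(records)
    res["fdr"] = bh_fdr(res["p"])
    return res


def compartment_compare(
    serum: NpxMatrix,
    csf: NpxMatrix,
    pairing: pd.DataFrame,
) -> pd.DataFrame:
    """Paired serum-vs-CSF comparison per protein.

    ``pairing`` has columns ``individual_id, serum_sample, csf_sample``.
    For each protein shared by both matrices: paired t-test on serum − CSF
    differences, BH-FDR over proteins, direction, and the Pearson
    correlation across individuals between compartments.
    """
    shared = serum.protein_ids.intersection(csf.protein_ids)
    records = []
    for protein in shared:
        s = serum.values.loc[pairing["serum_sample"], protein].to_numpy()
        c = csf.values.loc[pairing["csf_sample"], protein].to_numpy()
        ok = ~np.isnan(s) & ~np.isnan(c)
        if ok.sum() < 3:
            log.info("compartment_compare: skipping %s (<3 complete pairs)", protein)
            continue
        d = s[ok] - c[ok]
        beta = float(d.mean())
        if np.allclose(d, d[0]):
            p, se = (1.0 if np.isclose(d[0], 0.0) else 0.0), np.nan
        else:
            t = sps.ttest_rel(s[ok], c[ok])
            p, se = float(t.pvalue), float(d.std(ddof=1) / np.sqrt(ok.sum()))
        if s[ok].std() > 0 and c[ok].std() > 0:
            r = float(sps.pearsonr(s[ok], c[ok]).statistic)
        else:
            r = np.nan
        records.append({
            "analyte_id": protein, "comparison": "serum_vs_CSF_paired",
            "beta": beta, "se": se, "p": p, "n": int(ok.sum()),
            "direction": "higher_in_serum" if beta > 0 else "higher_in_CSF",
            "r_serum_csf": r,
        })
    res = stat_frame(records)
    res["fdr"] = bh_fdr(res["p"])
    return res


def profile_correlations(
    serum: NpxMatrix,
    csf: NpxMatrix,
    pairing: pd.DataFrame,
) -> dict:
    """Within-compartment vs within-individual profile correlations.

    Within-compartment: Pearson correlation over proteins between every pair
    of distinct samples of the same compartment. Within-individual: the
    correlation between one individual's serum and CSF profiles. Returns the
    two correlation vectors and their medians.
    """
    shared = serum.protein_ids.intersection(csf.protein_ids)

    def _pairwise(values: pd.DataFrame) -> np.ndarray:
        corr = np.corrcoef(values.to_numpy(dtype=float))
        iu = np.triu_indices(corr.shape[0], k=1)
        return corr[iu]

    within_serum = _pairwise(serum.values.loc[pairing["serum_sample"], shared])
    within_csf = _pairwise(csf.values.loc[pairing["csf_sample"], shared])
    within_type = np.concatenate([within_serum, within_csf])

    s = serum.values.loc[pairing["serum_sample"], shared].to_numpy(dtype=float)
    c = csf.values.loc[pairing["csf_sample"], shared].to_numpy(dtype=float)
    within_individual = np.array([
        np.corrcoef(s[i], c[i])[0, 1] for i in range(len(pairing))
    ])
    return {
        "within_type": within_type,
        "within_individual": within_individual,
        "median_within_type": float(np.nanmedian(within_type)),
        "median_within_individual": float(np.nanmedian(within_individual)),
    }
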