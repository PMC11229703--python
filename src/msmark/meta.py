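"""Cross-cohort meta-analysis of per-analyte effect estimates.

Candidate analytes are those with nominal P below a gate (default 0.1) in
at least one cohort (configurable to require both). Their per-cohort effect
estimates are combined by inverse-variance fixed-effect meta-analysis; a
DerSimonian–Laird random-effects variant is provided for heterogeneous
analytes. BH-FDR is applied across the selected candidate set, matching
the convention of correcting for "the number of analytes tested".
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_fdr

log = logging.getLogger("msmark")

__all__ = [
    "select_candidates",
    "fixed_effect_meta",
    "random_effect_meta",
    "meta_analyse",
]


def select_candidates(
    res1: pd.DataFrame,
    res2: pd.DataFrame,
    p_gate: float = 0.1,
    rule: str = "at-least-one",
) -> list[str]:
    """Analytes with nominal P < ``p_gate`` in one (default) or both cohorts.

    Only analytes present in both result sets are eligible (the meta-analysis
    needs an estimate from each cohort).
    """
    if rule not in ("at-least-one", "both"):
        raise ValueError("rule must be 'at-least-one' or 'both'")
    p1 = res1.set_index("analyte_id")["p"]
    p2 = res2.set_index("analyte_id")["p"]
    shared = p1.index.intersection(p2.index)
    a, b = p1.loc[shared] < p_gate, p2.loc[shared] < p_gate
    hit = (a | b) if rule == "at-least-one" else (a & b)
    selected = list(shared[hit.to_numpy()])
    log.info("select_candidates: %d analytes selected (gate P<%g, rule=%s)",
             len(selected), p_gate, rule)
    return selected


def fixed_effect_meta(betas, ses) -> dict:
    """Inverse-variance fixed-effect combination.

    w_i = 1/SE_i^2; beta = sum(w b)/sum(w); SE = 1/sqrt(sum w);
    z = beta/SE with a two-sided normal P; 95% CI = beta +/- 1.96 SE.
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if len(b) < 2:
        raise ValueError("meta-analysis needs at least 2 estimates")
    if (s <= 0).any() or not np.isfinite(s).all():
        raise ValueError("all standard errors must be positive and finite")
    w = 1.0 / s**2
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    z = beta / se
    p = float(2.0 * sps.norm.sf(abs(z)))
    return {"beta": beta, "se": se, "z": z, "p": p,
            "ci_low": beta - 1.96 * se, "ci_high": beta + 1.96 * se}


def random_effect_meta(betas, ses) -> dict:
    """DerSimonian–Laird random-effects combination.

    Q = sum w (b - b_fixed)^2; tau^2 = max(0, (Q - (k-1)) /
    (sum w - sum w^2 / sum w)); weights 1/(SE^2 + tau^2), then as fixed.
    Homogeneous inputs (Q <= k-1) give tau^2 = 0 and reduce to the
    fixed-effect result.
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    fixed = fixed_effect_meta(b, s)
    w = 1.0 / s**2
    k = len(b)
    q = float(np.sum(w * (b - fixed["beta"]) ** 2))
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    wr = 1.0 / (s**2 + tau2)
    beta = float(np.sum(wr * b) / np.sum(wr))
    se = float(1.0 / np.sqrt(np.sum(wr)))
    z = beta / se
    p = float(2.0 * sps.norm.sf(abs(z)))
    return {"beta": beta, "se": se, "z": z, "p": p, "q": q, "tau2": tau2,
            "ci_low": beta - 1.96 * se, "ci_high": beta + 1.96 * se}


def meta_analyse(
    res1: pd.DataFrame,
    res2: pd.DataFrame,
    p_gate: float = 0.1,
    rule: str = "at-least-one",
    method: str = "fixed",
) -> pd.DataFrame:
    """Select candidates and combine both cohorts' estimates per analyte.

    Returns one row per candidate with per-cohort beta/SE, the meta beta,
    SE, CI, P, Q, tau^2 and BH-FDR across the candidate set.
    """
    selected = select_candidates(res1, res2, p_gate, rule)
    r1 = res1.set_index("analyte_id")
    r2 = res2.set_index("analyte_id")
    rows = []
    for analyte in selected:
        b = [r1.loc[analyte, "beta"], r2.loc[analyte, "beta"]]
        s = [r1.loc[analyte, "se"], r2.loc[analyte, "se"]]
        if not np.isfinite(b).all() or not np.isfinite(s).all() or min(s) <= 0:
            log.info("meta_analyse: skipping %s (missing estimate)", analyte)
            continue
        re_ = random_effect_meta(b, s)
        m = fixed_effect_meta(b, s) if method == "fixed" else re_
        rows.append({
            "analyte_id": analyte,
            "beta_cohort1": float(b[0]), "se_cohort1": float(s[0]),
            "beta_cohort2": float(b[1]), "se_cohort2": float(s[1]),
            "beta": m["beta"], "se": m["se"],
            "ci_low": m["ci_low"], "ci_high": m["ci_high"],
            "p": m["p"], "q": re_["q"], "tau2": re_["tau2"],
            "p_random": re_["p"],
        })
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = bh_fdr(out["p"])
    return out
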