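"""Biomarker panel evaluation: backward selection and cross-validated ROC.

Candidate proteins are combined in a logistic model for a binary contrast
(e.g. MS vs control). Backward selection starts from the full model and
repeatedly drops the feature whose removal most improves AIC, stopping when
no removal helps; the procedure is deterministic given the data. Panel
performance is summarized by stratified 10-fold cross-validated ROC/AUC
(mean ± SD across folds), with seed-reproducible fold assignment. By
default selection runs once on the full data (optimistic but matching
common practice for this design); per-fold selection is available.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .datamodel import NpxMatrix

log = logging.getLogger("msmark")

__all__ = ["backward_select", "cv_auc"]


def _logit_fit(X: np.ndarray, y: np.ndarray):
    """Logistic fit returning (loglik, n_params, predict_fn, ridge_used).

    Separation or non-convergence falls back to a ridge-stabilized fit
    (small L2 penalty), with a warning.
    """
    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
            if res.mle_retvals.get("converged", False) and np.isfinite(res.params).all() \
                    and np.abs(res.params).max() < 30:
                return float(res.llf), Xc.shape[1], res.params, False
        except Exception:
            pass
        warnings.warn("separation detected; using ridge-stabilized logistic fit",
                      stacklevel=2)
        res = sm.GLM(y, Xc, family=sm.families.Binomial()).fit_regularized(
            alpha=1e-3, L1_wt=0.0
        )
        params = np.asarray(res.params)
        eta = Xc @ params
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        llf = float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
        return llf, Xc.shape[1], params, True


def _aic(llf: float, k: int) -> float:
    return 2 * k - 2 * llf


def backward_select(
    m: NpxMatrix | pd.DataFrame,
    labels: pd.Series,
    candidates: list[str],
) -> list[str]:
    """AIC-guided backward elimination over a logistic model.

    Starts from the full candidate model; at each step drops the feature
    whose removal most decreases AIC; stops when no removal improves.
    Duplicated (collinear) informative features collapse to one copy, since
    dropping a duplicate costs a parameter and no likelihood. An empty
    (intercept-only) model is allowed.
    """
    values = m.values if isinstance(m, NpxMatrix) else m
    missing = set(candidates) - set(values.columns)
    if missing:
        raise ValueError(f"candidate(s) not measured: {sorted(missing)}")
    y = labels.loc[values.index].to_numpy(dtype=float)
    current = list(candidates)
    llf, k, _, _ = _logit_fit(values[current].to_numpy(dtype=float), y)
    best_aic = _aic(llf, k)
    while current:
        trial = []
        for feat in current:
            rest = [f for f in current if f != feat]
            X = values[rest].to_numpy(dtype=float) if rest else np.empty((len(y), 0))
            llf, k, _, _ = _logit_fit(X, y)
            trial.append((_aic(llf, k), feat))
        trial.sort(key=lambda pair: (pair[0], pair[1]))
        if trial[0][0] < best_aic:
            best_aic = trial[0][0]
            current.remove(trial[0][1])
            log.info("backward_select: dropped %s (AIC %.2f)", trial[0][1], best_aic)
        else:
            break
    return current


def cv_auc(
    m: NpxMatrix | pd.DataFrame,
    labels: pd.Series,
    features: list[str],
    folds: int = 10,
    seed: int = 0,
    select_per_fold: bool = False,
) -> dict:
    """Stratified k-fold cross-validated ROC/AUC for a logistic panel.

    Returns ``{"auc_mean", "auc_sd", "fold_aucs", "roc"}`` where ``roc`` is
    the pooled ROC curve (FPR/TPR DataFrame over out-of-fold scores). With
    ``select_per_fold``, backward selection is re-run inside each training
    fold (unbiased variant).
    """
    values = m.values if isinstance(m, NpxMatrix) else m
    y = labels.loc[values.index].to_numpy(dtype=float)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("labels must be binary")
    if counts.min() < folds:
        raise ValueError(f"need >= {folds} samples per class for {folds}-fold stratified CV")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_aucs = []
    pooled_scores = np.full(len(y), np.nan)
    for train, test in skf.split(values.to_numpy(), y):
        feats = features
        if select_per_fold:
            feats = backward_select(values.iloc[train], labels.iloc[train], list(features))
            if not feats:
                feats = list(features)
        Xtr = values.iloc[train][feats].to_numpy(dtype=float)
        Xte = values.iloc[test][feats].to_numpy(dtype=float)
        _, _, params, _ = _logit_fit(Xtr, y[train])
        scores = sm.add_constant(Xte, has_constant="add") @ params
        pooled_scores[test] = scores
        fold_aucs.append(roc_auc_score(y[test], scores))
    fpr, tpr, _ = roc_curve(y, pooled_scores)
    return {
        "auc_mean": float(np.mean(fold_aucs)),
        "auc_sd": float(np.std(fold_aucs, ddof=1)),
        "fold_aucs": [float(a) for a in fold_aucs],
        "roc": pd.DataFrame({"fpr": fpr, "tpr": tpr}),
    }
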