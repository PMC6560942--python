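"""Presence-background model evaluation: ROC AUC, the true skill statistic,
sample-size-corrected AIC with Akaike weights, and the side-by-side model
comparison table.

Background cells stand in for absences throughout (presence-only data), so
the maximum achievable AUC is below 1 and AUC/TSS measure discrimination of
presences from the landscape, not from true absences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import maxent as mx

__all__ = [
    "compute_auc",
    "compute_tss",
    "compute_aicc",
    "aicc_formula",
    "akaike_weights",
    "compare_models",
    "EvaluationResult",
]


def compute_auc(presence_scores, background_scores) -> float:
    """Probability that a random presence outscores a random background cell
    (rank-sum form; ties count one half)."""
    pres = np.asarray(presence_scores, dtype=float)
    bg = np.asarray(background_scores, dtype=float)
    if pres.size == 0 or bg.size == 0:
        raise ValueError("score lists must be non-empty")
    ranks = rankdata(np.concatenate([pres, bg]))
    u = ranks[: pres.size].sum() - pres.size * (pres.size + 1) / 2.0
    return float(u / (pres.size * bg.size))


def compute_tss(
    presence_scores, background_scores, threshold: float | str = "auto"
) -> tuple[float, float]:
    """True skill statistic = sensitivity + specificity - 1.

    Sensitivity is the fraction of presences scoring at or above the
    threshold; specificity the fraction of background below it.  ``auto``
    picks the threshold maximising sensitivity + specificity (ties resolved
    to the lowest threshold).  Returns ``(TSS, threshold)``.
    """
    pres = np.sort(np.asarray(presence_scores, dtype=float))
    bg = np.sort(np.asarray(background_scores, dtype=float))
    if pres.size == 0 or bg.size == 0:
        raise ValueError("score lists must be non-empty")

    def tss_at(t: float) -> float:
        sens = np.mean(pres >= t)
        spec = np.mean(bg < t)
        return float(sens + spec - 1.0)

    if threshold != "auto":
        return tss_at(float(threshold)), float(threshold)
    candidates = np.unique(np.concatenate([pres, bg]))
    # vectorised sens/spec over all candidate cutoffs
    sens = 1.0 - np.searchsorted(pres, candidates, side="left") / pres.size
    spec = np.searchsorted(bg, candidates, side="left") / bg.size
    scores = sens + spec - 1.0
    best = int(np.argmax(scores))  # argmax returns the first (lowest) maximiser
    return float(scores[best]), float(candidates[best])


def log_likelihood(model: "mx.MaxentModel", presences, background) -> float:
    """Sum over presences of the log of the raw output re-normalised over the
    given background (the likelihood used for information criteria)."""
    pres_raw = mx.predict_values(model, presences, output="raw")
    bg_raw = mx.predict_values(model, background, output="raw")
    return float(np.sum(np.log(pres_raw / bg_raw.sum())))


def aicc_formula(k: int, n: int, lnl: float) -> float:
    """AICc = 2k - 2 lnL + 2k(k+1)/(n-k-1); NaN when n <= k + 1."""
    if n <= k + 1:
        return float("nan")
    return 2 * k - 2 * lnl + 2 * k * (k + 1) / (n - k - 1)


def compute_aicc(model: "mx.MaxentModel", presences, background) -> float:
    """Sample-size-corrected AIC with k = number of nonzero weights and the
    likelihood of the raw output re-normalised over the background.

    Undefined (NaN) when n <= k + 1, as in the standard formulation.
    """
    k = model.n_nonzero
    pres = mx._as_covariates(presences, model.variables)
    n = len(next(iter(pres.values())))
    return aicc_formula(k, n, log_likelihood(model, pres, background))


def akaike_weights(aiccs) -> np.ndarray:
    """Relative support w_i = exp(-delta_i / 2), normalised; missing (NaN)
    entries get weight 0."""
    a = np.asarray(aiccs, dtype=float)
    finite = np.isfinite(a)
    if not finite.any():
        raise ValueError("no finite AICc values")
    w = np.zeros_like(a)
    d = a[finite] - a[finite].min()
    ew = np.exp(-d / 2.0)
    w[finite] = ew / ew.sum()
    return w


@dataclass
class EvaluationResult:
    model_id: str
    variables: tuple[str, ...]
    auc: float
    tss: float
    tss_threshold: float
    aicc: float
    akaike_weight: float
    p10_threshold: float
    n_params_k: int
    n_presences: int


def compare_models(
    model_specs: dict[str, list[str]],
    presences,
    background,
    classes=mx.ALL_FEATURE_CLASSES,
    reg_multiplier: float = 2.5,
    max_iter: int = 5000,
    cv_folds: int = 10,
    seed: int = 0,
    n_hinge_knots: int = 30,
) -> pd.DataFrame:
    """Fit one model per variable subset and report the comparison table.

    AUC is the cross-validated mean; TSS, AICc, the Akaike weight and the
    10th-percentile training threshold come from the full-data fit.  Rows
    are ranked by AICc.
    """
    from .postprocess import compute_threshold

    if len(model_specs) < 2:
        raise ValueError("need at least two model specs to compare")
    all_vars = sorted({v for spec in model_specs.values() for v in spec})
    bg = mx._as_covariates(background, all_vars)
    pres = mx._as_covariates(presences, all_vars)
    rows = []
    for model_id, variables in model_specs.items():
        feats = mx.build_features(bg, variables, classes, n_hinge_knots=n_hinge_knots)
        model = mx.fit_maxent(
            pres, bg, feats, reg_multiplier=reg_multiplier,
            max_iter=max_iter, model_id=model_id,
        )
        cv = mx.cross_validate(
            pres, bg, feats, k=cv_folds, seed=seed,
            reg_multiplier=reg_multiplier, max_iter=max_iter,
        )
        tr_scores = mx.predict_values(model, pres)
        bg_scores = mx.predict_values(model, bg)
        tss, tss_t = compute_tss(tr_scores, bg_scores)
        rows.append(
            {
                "model_id": model_id,
                "variables": "+".join(variables),
                "auc": cv.mean_auc,
                "tss": tss,
                "tss_threshold": tss_t,
                "aicc": compute_aicc(model, pres, bg),
                "p10_threshold": compute_threshold(tr_scores, "p10"),
                "k": model.n_nonzero,
                "n_presences": model.n_presences,
                "training_gain": model.training_gain,
            }
        )
    table = pd.DataFrame(rows)
    table["akaike_weight"] = akaike_weights(table["aicc"].to_numpy())
    return table.sort_values("aicc", kind="stable").reset_index(drop=True)
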