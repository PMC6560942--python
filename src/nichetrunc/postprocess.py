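"""Thresholding, ensemble intersection, suitable-area accounting by
protected-area status and tree cover, and the current-vs-historical niche
shift comparison.

Suitability maps are turned into presence-absence maps with a training-
presence threshold; "at or above the threshold" counts as present, so the
training presence that defines the threshold is itself classified present.
Areas are cell counts times the (equal-area) cell area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .grids import GridGeometry
from .occurrences import OccurrenceSet, adjust_temperatures

__all__ = [
    "compute_threshold",
    "ensemble_intersection",
    "AreaSummary",
    "area_summary",
    "percent_area_change",
    "niche_shift_test",
    "niche_shift_report",
    "THRESHOLD_METHODS",
]

THRESHOLD_METHODS = ("p10", "mtp", "maxss", "eqss")


def compute_threshold(
    training_scores, method: str = "p10", background_scores=None
) -> float:
    """Suitability cutoff from the training presences.

    p10
        10th-percentile training presence: the score at 0-based index
        ``floor(0.1 m)`` of the ascending sort, so at least 90% of training
        presences score at or above it.
    mtp
        minimum training presence (zero training omission).
    maxss / eqss
        maximise sensitivity + specificity / minimise |sens - spec| against
        the background scores.
    """
    scores = np.sort(np.asarray(training_scores, dtype=float))
    if scores.size == 0:
        raise ValueError("training scores must be non-empty")
    method = method.lower()
    if method == "p10":
        return float(scores[int(np.floor(0.1 * scores.size))])
    if method == "mtp":
        return float(scores[0])
    if method in ("maxss", "eqss"):
        if background_scores is None:
            raise ValueError(f"{method} requires background scores")
        bg = np.sort(np.asarray(background_scores, dtype=float))
        candidates = np.unique(np.concatenate([scores, bg]))
        sens = 1.0 - np.searchsorted(scores, candidates, side="left") / scores.size
        spec = np.searchsorted(bg, candidates, side="left") / bg.size
        if method == "maxss":
            return float(candidates[np.argmax(sens + spec)])
        return float(candidates[np.argmin(np.abs(sens - spec))])
    raise ValueError(f"unknown threshold method {method!r}")


def ensemble_intersection(maps, thresholds) -> np.ndarray:
    """Per-cell count of suitability maps at or above their own threshold.

    Derived masks: "min one model" is count >= 1, "all models" is
    count == len(maps).  Cells that are nodata in every map are nan.
    """
    maps = [np.asarray(m, dtype=float) for m in maps]
    thresholds = list(np.atleast_1d(thresholds))
    if len(maps) != len(thresholds):
        raise ValueError("need one threshold per map")
    shape = maps[0].shape
    if any(m.shape != shape for m in maps):
        raise ValueError("maps are not co-registered")
    count = np.zeros(shape)
    any_valid = np.zeros(shape, dtype=bool)
    for m, t in zip(maps, thresholds):
        valid = np.isfinite(m)
        any_valid |= valid
        count += np.where(valid & (m >= t), 1.0, 0.0)
    count[~any_valid] = np.nan
    return count


@dataclass
class AreaSummary:
    """Suitable-area totals (km²) stratified by protected-area status and
    nested tree-cover classes (>= 75% within >= 50%)."""

    total_km2: float
    within_pa_km2: float
    within_pa_treecov50_km2: float
    within_pa_treecov75_km2: float
    outside_pa_treecov50_km2: float
    outside_pa_treecov75_km2: float

    def to_dict(self) -> dict[str, float]:
        return {
            "total_km2": self.total_km2,
            "within_pa_km2": self.within_pa_km2,
            "within_pa_treecov50_km2": self.within_pa_treecov50_km2,
            "within_pa_treecov75_km2": self.within_pa_treecov75_km2,
            "outside_pa_treecov50_km2": self.outside_pa_treecov50_km2,
            "outside_pa_treecov75_km2": self.outside_pa_treecov75_km2,
        }


def area_summary(
    suitable: np.ndarray,
    pa: np.ndarray,
    treecov: np.ndarray,
    geometry: GridGeometry,
) -> AreaSummary:
    """Tally suitable cells by protection and tree cover; area = count × cell area."""
    suitable = np.asarray(suitable, dtype=float)
    pa = np.asarray(pa, dtype=float)
    treecov = np.asarray(treecov, dtype=float)
    if not (suitable.shape == pa.shape == treecov.shape == geometry.shape):
        raise ValueError("layers are not co-registered with the geometry")
    a = geometry.cell_area
    suit = suitable == 1
    inside = pa == 1
    tc50 = treecov >= 50
    tc75 = treecov >= 75
    return AreaSummary(
        total_km2=float(suit.sum() * a),
        within_pa_km2=float((suit & inside).sum() * a),
        within_pa_treecov50_km2=float((suit & inside & tc50).sum() * a),
        within_pa_treecov75_km2=float((suit & inside & tc75).sum() * a),
        outside_pa_treecov50_km2=float((suit & ~inside & tc50).sum() * a),
        outside_pa_treecov75_km2=float((suit & ~inside & tc75).sum() * a),
    )


def percent_area_change(area_current: float, area_with_hist: float) -> float:
    """Percent change of suitable area when historical records are added."""
    if area_current <= 0:
        raise ValueError("current area must be positive")
    return 100.0 * (area_with_hist - area_current) / area_current


def niche_shift_test(current_values, historical_values) -> dict[str, float]:
    """Compare a variable between current and historical records.

    Reports both medians and a two-sided Mann-Whitney U test: exact by
    enumeration for combined n <= 12 without ties, the tie-corrected normal
    approximation otherwise.  A pooled sample with zero variance carries no
    evidence of a shift (p = 1).
    """
    cur = np.asarray(current_values, dtype=float)
    hist = np.asarray(historical_values, dtype=float)
    if cur.size == 0 or hist.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([cur, hist])
    out = {
        "median_current": float(np.median(cur)),
        "median_historical": float(np.median(hist)),
    }
    if np.all(pooled == pooled[0]):
        # all ranks tied: U at its mean, no evidence either way
        out.update(U=cur.size * hist.size / 2.0, p_two_sided=1.0)
        return out
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= 12 and not has_ties) else "asymptotic"
    res = mannwhitneyu(cur, hist, alternative="two-sided", method=method)
    out.update(U=float(res.statistic), p_two_sided=float(min(res.pvalue, 1.0)))
    return out


def niche_shift_report(
    occ: OccurrenceSet, variables, deltas=(0.0,)
) -> pd.DataFrame:
    """Niche-shift table: one row per variable (and per temperature
    adjustment delta), comparing current vs historical record values."""
    rows = []
    for delta in deltas:
        adj = adjust_temperatures(occ, delta)
        df = adj.modelling_records() if "valid" in adj.df.columns else adj.df
        cur = df[df["period"] == "current"]
        hist = df[df["period"] == "historical"]
        for v in variables:
            res = niche_shift_test(cur[v].to_numpy(), hist[v].to_numpy())
            rows.append({"variable": v, "delta": delta, **res})
    return pd.DataFrame(rows)
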