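"""Rectilinear bioclimatic envelope model.

The envelope is the axis-aligned box in climate space spanned by the
calibration records: a cell is climatically suitable iff every one of the
five climate variables (PANN, PDryQ, MinTCM, MTCQ, MTWQ) lies within the
records' min-max bounds (closed intervals).  Because the bounds are exact
minima and maxima, adding records can only widen the envelope — which is
what makes the model a clean probe for niche truncation: including
historical records never shrinks, and typically grows, the suitable area.

The historical-climate sensitivity scheme subtracts a fixed delta (°C) from
the temperature values of the historical records before the bounds are
taken, emulating the cooler climate those records were observed in.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .grids import ENVELOPE_VARIABLES, GridStack
from .occurrences import OccurrenceSet, adjust_temperatures

__all__ = [
    "EnvelopeModel",
    "fit_envelope",
    "predict_envelope",
    "species_envelope_overlap",
]


@dataclass
class EnvelopeModel:
    """Per-variable [min, max] bounds defining the suitable region."""

    bounds: dict[str, tuple[float, float]]
    variables: tuple[str, ...] = ENVELOPE_VARIABLES
    calibration: str = "current"   # current-only | current+historical
    delta: float = 0.0

    def __post_init__(self) -> None:
        for v in self.variables:
            if v not in self.bounds:
                raise ValueError(f"missing bounds for {v!r}")
            lo, hi = self.bounds[v]
            if lo > hi:
                raise ValueError(f"{v}: min {lo} exceeds max {hi}")

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            fh.write(f"# calibration: {self.calibration}\n# delta: {self.delta}\n")
            w = csv.writer(fh)
            w.writerow(["variable", "min", "max"])
            for v in self.variables:
                lo, hi = self.bounds[v]
                w.writerow([v, repr(lo), repr(hi)])

    @classmethod
    def from_csv(cls, path) -> "EnvelopeModel":
        calibration, delta = "current", 0.0
        bounds = {}
        order = []
        for line in Path(path).read_text().splitlines():
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition(":")
                if key.strip() == "calibration":
                    calibration = val.strip()
                elif key.strip() == "delta":
                    delta = float(val)
                continue
            var, lo, hi = line.split(",")
            if var == "variable":
                continue
            bounds[var] = (float(lo), float(hi))
            order.append(var)
        return cls(bounds, tuple(order), calibration, delta)


def fit_envelope(
    occ: OccurrenceSet, variables=ENVELOPE_VARIABLES, delta: float = 0.0
) -> EnvelopeModel:
    """Exact per-variable min/max bounds over the calibration records.

    ``delta`` (°C, >= 0) is subtracted from the temperature variables of the
    historical records before the scan; precipitation is untouched.
    """
    variables = tuple(variables)
    occ = adjust_temperatures(occ, delta)
    df = occ.modelling_records() if "valid" in occ.df.columns else occ.df
    if len(df) < 2:
        raise ValueError("need at least 2 records to fit an envelope")
    bounds = {}
    for v in variables:
        if v not in df.columns:
            raise ValueError(f"covariate {v!r} missing from the records")
        vals = df[v].to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValueError(f"covariate {v!r} has missing values")
        bounds[v] = (float(vals.min()), float(vals.max()))
    periods = set(df["period"])
    calibration = "current+historical" if "historical" in periods else "current"
    return EnvelopeModel(bounds, variables, calibration, delta)


def predict_envelope(model: EnvelopeModel, stack: GridStack) -> np.ndarray:
    """Binary suitability layer: 1 where every variable is within bounds
    (inclusive), 0 otherwise, nan where any variable is nodata."""
    for v in model.variables:
        if v not in stack:
            raise ValueError(f"variable {v!r} missing from the stack")
    valid = stack.valid_mask(model.variables)
    ok = np.ones(stack.geometry.shape, dtype=bool)
    for v in model.variables:
        lo, hi = model.bounds[v]
        layer = stack[v]
        ok &= (layer >= lo) & (layer <= hi)
    out = np.where(ok, 1.0, 0.0)
    out[~valid] = np.nan
    return out


def species_envelope_overlap(
    models: dict[str, EnvelopeModel], stack: GridStack
) -> np.ndarray:
    """Per-cell count of species envelopes containing the cell."""
    if not models:
        raise ValueError("no envelope models given")
    total = None
    for model in models.values():
        layer = predict_envelope(model, stack)
        total = layer if total is None else total + layer
    return total
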