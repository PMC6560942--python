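"""Synthetic landscapes and occurrence sets with the statistical structure
the analysis assumes, so the whole pipeline is testable without any
downloaded rasters.

The generator emulates a mountainous subtropical region: a spatially
autocorrelated elevation surface, temperature surfaces tied to elevation
through a lapse rate and to each other through a shared climatic driver
(reproducing the strong inter-variable Pearson correlations of real
bioclimatic grids, e.g. r = 0.98 between annual mean temperature and the
coldest-month minimum), positively inter-correlated precipitation surfaces
that are wetter where it is warmer, tree cover that increases with elevation
and decreases with human influence, human pressure (HII, population density)
concentrated in the lowlands, and a blobby protected-area mask.

The true suitability niche is a product of Gaussian responses in climate
space.  Historical records sample the full niche; current records sample the
niche *truncated* to high-elevation, low-human-pressure cells — the refugee
pattern whereby a species survives only where people are not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .grids import GridGeometry, GridStack
from .occurrences import GENUS, OccurrenceSet

__all__ = [
    "SimulationConfig",
    "simulate_landscape",
    "true_suitability",
    "simulate_occurrences",
    "simulate_dataset",
]

# analytic construction: each temperature variable v is
#   offset_v + driver + sigma_v * noise,   sigma_v = sd(driver) * sqrt(1/r^2 - 1)
# so corr(AMT, v) = r by design (AMT carries no independent noise).
_DEFAULT_CORRELATIONS = {
    ("AMT", "MinTCM"): 0.98,
    ("AMT", "MTCQ"): 0.96,
    ("AMT", "MTWQ"): 0.92,
    ("PANN", "PWetQ"): 0.94,
    ("PDryQ", "PColdQ"): 0.98,
}

_TEMP_OFFSETS = {"AMT": 0.0, "MinTCM": -14.0, "MTCQ": -8.0, "MTWQ": 9.0}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study system.

    Defaults describe the scenario used throughout the test-bed: a 60 x 60
    grid of 5-km cells (a 300-km square), elevation centred on 2500 m with
    ~900 m spread, a 6 °C/km lapse rate, a niche centred at MTCQ = 8 °C and
    PANN = 1400 mm, and anthropogenic truncation confining current presences
    to cells above 3000 m with HII <= 20.
    """

    seed: int = 0
    n_rows: int = 60
    n_cols: int = 60
    cell_size: float = 5.0
    spatial_correlation_length: float = 5.0  # cells
    climate_correlation_targets: dict = field(
        default_factory=lambda: dict(_DEFAULT_CORRELATIONS)
    )
    lapse_rate: float = 6.0  # °C per km of elevation
    niche_center: dict = field(default_factory=lambda: {"MTCQ": 8.0, "PANN": 1400.0})
    niche_width: dict = field(default_factory=lambda: {"MTCQ": 3.5, "PANN": 350.0})
    elev_cutoff: float = 3000.0  # m; current records only above this
    hii_cutoff: float = 20.0     # current records only at or below this
    n_current: int = 150
    n_historical: int = 60

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.niche_width.values()):
            raise ValueError("niche widths must be positive")
        if any(not -1 < r < 1 for r in self.climate_correlation_targets.values()):
            raise ValueError("correlation targets must lie in (-1, 1)")


def _smooth_field(rng: np.random.Generator, shape, length: float) -> np.ndarray:
    """Standardised spatially autocorrelated field (smoothed white noise)."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=length, mode="reflect")
    return (f - f.mean()) / f.std()


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.corrcoef(a.ravel(), b.ravel())[0, 1])


def simulate_landscape(cfg: SimulationConfig) -> GridStack:
    """Generate the full co-registered raster stack.

    Raises if any configured correlation target is missed by more than 0.05
    (which flags an unattainable mixing configuration rather than silently
    returning a mis-specified landscape).
    """
    rng = np.random.default_rng(cfg.seed)
    shape = (cfg.n_rows, cfg.n_cols)
    L = cfg.spatial_correlation_length
    geom = GridGeometry(cfg.n_rows, cfg.n_cols, cfg.cell_size)
    stack = GridStack(geom)

    e = _smooth_field(rng, shape, L)
    elev = np.clip(2500.0 + 900.0 * e, 0.0, 6500.0)
    stack.add("ELEV", elev)

    # temperatures: shared driver = synoptic field + lapse-rate cooling
    s_t = _smooth_field(rng, shape, L)
    driver = 12.0 + 0.8 * s_t - cfg.lapse_rate * (elev - 2500.0) / 1000.0
    sd_d = driver.std()
    targets = cfg.climate_correlation_targets
    for var, offset in _TEMP_OFFSETS.items():
        r = targets.get(("AMT", var))
        if var == "AMT" or r is None:
            sigma = 0.0
        else:
            sigma = sd_d * np.sqrt(1.0 / r**2 - 1.0)
        noise = _smooth_field(rng, shape, L) if sigma > 0 else 0.0
        stack.add(var, offset + driver + sigma * noise)

    # precipitation: wetter where warmer (the anthropogenic conflict: warm,
    # wet lowlands are also where people settle)
    t_std = (driver - driver.mean()) / sd_d
    p_driver = 0.6 * t_std + 0.8 * _smooth_field(rng, shape, L)
    p_driver = (p_driver - p_driver.mean()) / p_driver.std()
    stack.add("PANN", np.clip(1200.0 + 380.0 * p_driver, 30.0, None))
    r = targets.get(("PANN", "PWetQ"), 0.94)
    sig = np.sqrt(1.0 / r**2 - 1.0)
    stack.add(
        "PWetQ",
        np.clip(550.0 + 200.0 * (p_driver + sig * _smooth_field(rng, shape, L)) / np.sqrt(1 + sig**2), 5.0, None),
    )
    d_dry = 0.7 * p_driver + np.sqrt(1 - 0.49) * _smooth_field(rng, shape, L)
    stack.add("PDryQ", np.clip(90.0 + 45.0 * d_dry, 0.0, None))
    r = targets.get(("PDryQ", "PColdQ"), 0.98)
    sig = np.sqrt(1.0 / r**2 - 1.0)
    stack.add(
        "PColdQ",
        np.clip(80.0 + 40.0 * (d_dry + sig * _smooth_field(rng, shape, L)) / np.sqrt(1 + sig**2), 0.0, None),
    )

    # human pressure in the lowlands, forest on the heights
    hii = np.clip(24.0 - 10.0 * e + 6.0 * _smooth_field(rng, shape, L), 0.0, 64.0)
    stack.add("HII", hii)
    stack.add(
        "POPDENS",
        np.clip(np.exp(3.0 - 1.2 * e + 0.8 * _smooth_field(rng, shape, L)), 0.0, 5000.0),
    )
    stack.add(
        "TREECOV",
        np.clip(55.0 + 15.0 * e - 0.45 * hii + 8.0 * _smooth_field(rng, shape, L), 0.0, 100.0),
    )

    # protected areas: random blobs covering roughly a tenth of the region
    pa_field = _smooth_field(rng, shape, L)
    stack.add("PA", (pa_field >= np.quantile(pa_field, 0.9)).astype(float))

    for (a, b), r_target in targets.items():
        if a in stack.layers and b in stack.layers:
            r_emp = _corr(stack[a], stack[b])
            if abs(r_emp - r_target) > 0.05:
                raise ValueError(
                    f"correlation target unattainable for ({a}, {b}): "
                    f"target {r_target:.2f}, achieved {r_emp:.2f}"
                )
    return stack


def true_suitability(cfg: SimulationConfig, stack: GridStack) -> np.ndarray:
    """True suitability in [0, 1]: product of Gaussian responses
    exp(-(v - center)^2 / (2 width^2)) over the configured niche variables."""
    out = np.ones(stack.geometry.shape)
    for v, c in cfg.niche_center.items():
        w = cfg.niche_width[v]
        out = out * np.exp(-((stack[v] - c) ** 2) / (2.0 * w**2))
    return out


def simulate_occurrences(
    cfg: SimulationConfig, stack: GridStack, truth: np.ndarray
) -> OccurrenceSet:
    """Sample current (truncated) and historical (full-niche) occurrences.

    Historical records are drawn from all cells with probability
    proportional to true suitability; current records from the subset with
    ``ELEV >= elev_cutoff`` and ``HII <= hii_cutoff``.  Cells are drawn
    without replacement per period, and records sit at cell centres.
    """
    truth = np.asarray(truth, dtype=float)
    if np.nanmin(truth) < 0 or np.nanmax(truth) > 1:
        raise ValueError("truth must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    xs, ys = stack.geometry.cell_centres()
    flat_truth = np.where(np.isfinite(truth), truth, 0.0).ravel()

    def draw(weights: np.ndarray, n: int, period: str) -> dict:
        total = weights.sum()
        if total <= 0:
            raise ValueError(f"no cells available to sample {period} records")
        n_avail = int(np.sum(weights > 0))
        if n > n_avail:
            raise ValueError(
                f"cannot draw {n} {period} records from {n_avail} candidate cells"
            )
        idx = rng.choice(flat_truth.size, size=n, replace=False, p=weights / total)
        return {
            "species": GENUS,
            "x": xs.ravel()[idx],
            "y": ys.ravel()[idx],
            "period": period,
        }

    trunc_mask = (
        (stack["ELEV"] >= cfg.elev_cutoff) & (stack["HII"] <= cfg.hii_cutoff)
    ).ravel()
    if not trunc_mask.any():
        raise ValueError("truncated region is empty under the configured cutoffs")
    import pandas as pd

    cur = pd.DataFrame(draw(flat_truth * trunc_mask, cfg.n_current, "current"))
    hist = pd.DataFrame(draw(flat_truth, cfg.n_historical, "historical"))
    return OccurrenceSet(pd.concat([cur, hist], ignore_index=True))


def simulate_dataset(
    cfg: SimulationConfig,
) -> tuple[GridStack, np.ndarray, OccurrenceSet]:
    """Landscape, true suitability and occurrences in one seeded call."""
    stack = simulate_landscape(cfg)
    truth = true_suitability(cfg, stack)
    occ = simulate_occurrences(cfg, stack, truth)
    return stack, truth, occ
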