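"""End-to-end orchestration: simulate or load inputs, prepare occurrences,
fit and evaluate the maxent model grid, threshold and intersect the maps,
fit the climate envelopes per temperature adjustment, tally suitable area by
protection and tree cover, and test the current-vs-historical niche shift.

Each stage reads its inputs from and writes its artefacts into one run
directory, so stages can be re-run individually; ``run_pipeline`` executes
them in order.  Every run is deterministic for a fixed seed, and every CSV
artefact carries the configuration hash in a leading comment line.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from configparser import ConfigParser
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import envelope as env
from . import evaluation as ev
from . import maxent as mx
from . import postprocess as pp
from .grids import (CLIMATE_VARIABLES, GridStack, load_stack, write_ascii_grid,
                    write_stack)
from .occurrences import (FilterConfig, OccurrenceSet, adjust_temperatures,
                          apply_occurrence_filters, default_profiles,
                          extract_covariates, load_polygons,
                          polygons_to_cell_centres, thin_occurrences)
from .simulate import SimulationConfig, simulate_dataset

log = logging.getLogger("nichetrunc")

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

#: the four candidate variable subsets, fitted with current-only records
#: (CURR prefix) and with current+historical records (HIST prefix)
DEFAULT_MODEL_SPECS = {
    "1": ["PANN", "PDryQ", "MTCQ", "MTWQ"],
    "2": ["PANN", "PDryQ", "MinTCM", "MTWQ"],
    "3": ["PANN", "PDryQ", "MinTCM"],
    "4": ["PANN", "PDryQ", "MTCQ"],
}


@dataclass
class PipelineConfig:
    """Single plain-text configuration for the whole analysis."""

    # inputs; when manifest is None the synthetic generator provides them
    manifest: str | None = None
    occurrences: str | None = None
    polygons: str | None = None
    # prepare
    apply_filters: bool = False
    treecov_min: float = 50.0
    popdens_max: float = 100.0
    hii_max: float = 20.0
    thin_target_n: int | None = None
    # modelling
    model_specs: dict = field(default_factory=lambda: dict(DEFAULT_MODEL_SPECS))
    reg_multiplier: float = 2.5
    max_iter: int = 5000
    cv_folds: int = 10
    n_hinge_knots: int = 30
    background_size: int = 10_000
    threshold_method: str = "p10"
    deltas: tuple = (0.0, 0.7, 1.5, 2.0)
    seed: int = 0
    # synthetic scenario (used when no manifest is given)
    sim_n_rows: int = 60
    sim_n_cols: int = 60

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if any(d < 0 for d in self.deltas):
            raise ValueError("deltas must be non-negative")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        cp = ConfigParser()
        cp.read(path)
        kw: dict = {}
        g = cp["inputs"] if cp.has_section("inputs") else {}
        for key in ("manifest", "occurrences", "polygons"):
            if key in g:
                kw[key] = g[key]
        g = cp["prepare"] if cp.has_section("prepare") else {}
        if "apply_filters" in g:
            kw["apply_filters"] = g.getboolean("apply_filters")
        for key in ("treecov_min", "popdens_max", "hii_max"):
            if key in g:
                kw[key] = float(g[key])
        if "thin_target_n" in g:
            kw["thin_target_n"] = int(g["thin_target_n"])
        g = cp["model"] if cp.has_section("model") else {}
        for key, cast in (
            ("reg_multiplier", float), ("max_iter", int), ("cv_folds", int),
            ("n_hinge_knots", int), ("background_size", int),
            ("threshold_method", str), ("seed", int),
            ("sim_n_rows", int), ("sim_n_cols", int),
        ):
            if key in g:
                kw[key] = cast(g[key])
        if "deltas" in g:
            kw["deltas"] = tuple(float(x) for x in g["deltas"].split(","))
        if cp.has_section("model_specs"):
            kw["model_specs"] = {
                k: [v.strip() for v in spec.split(",")]
                for k, spec in cp["model_specs"].items()
            }
        return cls(**kw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path, cfg: PipelineConfig) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# config_hash: {cfg.config_hash()}\n")
        df.to_csv(fh, index=False)


def _read_csv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# stages

def stage_prepare(cfg: PipelineConfig, out: Path) -> None:
    """Assemble the stack and the covariate-annotated occurrence set."""
    if cfg.manifest:
        stack = load_stack(cfg.manifest)
        parts = []
        if cfg.polygons:
            polys = load_polygons(cfg.polygons)
            parts.append(polygons_to_cell_centres(polys, stack.geometry).df)
        if cfg.occurrences:
            parts.append(OccurrenceSet.from_csv(cfg.occurrences).df)
        if not parts:
            raise ValueError("no occurrence source configured")
        occ = OccurrenceSet(pd.concat(parts, ignore_index=True))
    else:
        sim = SimulationConfig(
            seed=cfg.seed, n_rows=cfg.sim_n_rows, n_cols=cfg.sim_n_cols
        )
        stack, truth, occ = simulate_dataset(sim)
        write_ascii_grid(out / "truth.asc", truth, stack.geometry)
    write_stack(stack, out / "stack")
    occ = extract_covariates(occ, stack)
    if cfg.apply_filters:
        occ = apply_occurrence_filters(
            occ, stack, default_profiles(),
            FilterConfig(cfg.treecov_min, cfg.popdens_max, cfg.hii_max),
        )
    if cfg.thin_target_n:
        cur = thin_occurrences(
            occ.subset("current"), target_n=cfg.thin_target_n, seed=cfg.seed,
            bandwidth=2 * stack.geometry.cell_size,
        )
        occ = OccurrenceSet(
            pd.concat([cur.df, occ.subset("historical").df], ignore_index=True)
        )
    with open(out / "occurrences_prepared.csv", "w", newline="") as fh:
        fh.write(f"# config_hash: {cfg.config_hash()}\n")
        occ.df.to_csv(fh, index=False)


def _load_prepared(cfg: PipelineConfig, out: Path) -> tuple[GridStack, OccurrenceSet]:
    stack = load_stack(out / "stack" / "manifest.txt")
    occ = OccurrenceSet.from_csv(out / "occurrences_prepared.csv")
    return stack, occ


def _calibrations(cfg: PipelineConfig):
    """(set name, delta) pairs: one current-only set, one per delta with
    historical records included."""
    yield "CURR", 0.0
    for d in cfg.deltas:
        yield "HIST", d


def _set_tag(calib: str, delta: float) -> str:
    return "CURR" if calib == "CURR" else f"HIST_d{delta:g}"


def _presences_for(occ: OccurrenceSet, calib: str, delta: float, variables):
    if calib == "CURR":
        return occ.subset("current").covariates(variables)
    return adjust_temperatures(occ, delta).covariates(variables)


def stage_fit(cfg: PipelineConfig, out: Path) -> None:
    """Fit every model of the grid on full data; save models, logistic maps
    and training thresholds."""
    stack, occ = _load_prepared(cfg, out)
    (out / "models").mkdir(exist_ok=True)
    (out / "maps").mkdir(exist_ok=True)
    all_vars = sorted({v for s in cfg.model_specs.values() for v in s})
    bg, _ = mx.sample_background(stack, all_vars, cfg.background_size, cfg.seed)
    rows = []
    for calib, delta in _calibrations(cfg):
        tag = _set_tag(calib, delta)
        pres = _presences_for(occ, calib, delta, all_vars)
        for num, variables in cfg.model_specs.items():
            model_id = f"{tag}_{num}"
            feats = mx.build_features(bg, variables, n_hinge_knots=cfg.n_hinge_knots)
            model = mx.fit_maxent(
                pres, bg, feats, reg_multiplier=cfg.reg_multiplier,
                max_iter=cfg.max_iter, model_id=model_id,
            )
            model.to_text(out / "models" / f"{model_id}.txt")
            layer = mx.predict(model, stack)
            write_ascii_grid(out / "maps" / f"{model_id}.asc", layer, stack.geometry)
            scores = mx.predict_values(model, pres)
            bg_scores = mx.predict_values(model, bg)
            rows.append(
                {
                    "model_id": model_id, "set": tag, "spec": num,
                    "threshold_method": cfg.threshold_method,
                    "threshold": pp.compute_threshold(
                        scores, cfg.threshold_method, bg_scores
                    ),
                }
            )
    _write_csv(pd.DataFrame(rows), out / "thresholds.csv", cfg)


def stage_evaluate(cfg: PipelineConfig, out: Path) -> None:
    """Cross-validated AUC, TSS, AICc and Akaike weights for every model."""
    stack, occ = _load_prepared(cfg, out)
    thresholds = _read_csv(out / "thresholds.csv")
    all_vars = sorted({v for s in cfg.model_specs.values() for v in s})
    bg, _ = mx.sample_background(stack, all_vars, cfg.background_size, cfg.seed)
    rows = []
    for calib, delta in _calibrations(cfg):
        tag = _set_tag(calib, delta)
        pres = _presences_for(occ, calib, delta, all_vars)
        aiccs = []
        for num, variables in cfg.model_specs.items():
            model_id = f"{tag}_{num}"
            model = mx.MaxentModel.from_text(out / "models" / f"{model_id}.txt")
            feats = model.features
            cv = mx.cross_validate(
                pres, bg, feats, k=cfg.cv_folds, seed=cfg.seed,
                reg_multiplier=cfg.reg_multiplier, max_iter=cfg.max_iter,
            )
            scores = mx.predict_values(model, pres)
            bg_scores = mx.predict_values(model, bg)
            tss, tss_t = ev.compute_tss(scores, bg_scores)
            aicc = ev.compute_aicc(model, pres, bg)
            aiccs.append(aicc)
            thr = thresholds.loc[thresholds.model_id == model_id, "threshold"]
            rows.append(
                {
                    "model_id": model_id, "set": tag, "spec": num,
                    "variables": "+".join(variables),
                    "auc": cv.mean_auc, "tss": tss, "aicc": aicc,
                    "threshold": float(thr.iloc[0]),
                    "k": model.n_nonzero, "n_presences": model.n_presences,
                }
            )
        w = ev.akaike_weights(aiccs)
        for r, wi in zip(rows[-len(aiccs):], w):
            r["akaike_weight"] = wi
    _write_csv(pd.DataFrame(rows), out / "table1.csv", cfg)


def stage_ensemble(cfg: PipelineConfig, out: Path) -> None:
    """Per-set count layers: how many models call each cell suitable."""
    from .grids import read_ascii_grid

    stack, _ = _load_prepared(cfg, out)
    thresholds = _read_csv(out / "thresholds.csv")
    for tag in thresholds["set"].unique():
        sub = thresholds[thresholds["set"] == tag]
        maps, ts = [], []
        for _, row in sub.iterrows():
            layer, _ = read_ascii_grid(out / "maps" / f"{row.model_id}.asc")
            maps.append(layer)
            ts.append(row.threshold)
        count = pp.ensemble_intersection(maps, ts)
        write_ascii_grid(out / f"ensemble_{tag}.asc", count, stack.geometry)


def stage_envelope(cfg: PipelineConfig, out: Path) -> None:
    """Rectilinear envelopes: current-only, and current+historical per delta."""
    stack, occ = _load_prepared(cfg, out)
    cur = occ.subset("current")
    model = env.fit_envelope(cur)
    model.to_csv(out / "envelope_CURR.csv")
    write_ascii_grid(
        out / "envelope_CURR.asc", env.predict_envelope(model, stack), stack.geometry
    )
    for delta in cfg.deltas:
        model = env.fit_envelope(occ, delta=delta)
        tag = _set_tag("HIST", delta)
        model.to_csv(out / f"envelope_{tag}.csv")
        write_ascii_grid(
            out / f"envelope_{tag}.asc", env.predict_envelope(model, stack),
            stack.geometry,
        )


def stage_overlay(cfg: PipelineConfig, out: Path) -> None:
    """Suitable-area accounting by protected-area status and tree cover, for
    the maxent ensembles and the envelopes, plus the historical-vs-current
    percent area change."""
    from .grids import read_ascii_grid

    stack, _ = _load_prepared(cfg, out)
    pa, treecov = stack["PA"], stack["TREECOV"]
    rows = []
    tags = [_set_tag(c, d) for c, d in _calibrations(cfg)]
    n_models = len(cfg.model_specs)
    for tag in tags:
        count, _ = read_ascii_grid(out / f"ensemble_{tag}.asc")
        for label, mask in (
            ("min_one_model", count >= 1),
            ("all_models", count >= n_models),
        ):
            summ = pp.area_summary(
                mask.astype(float), pa, treecov, stack.geometry
            )
            rows.append({"model": f"maxent_{label}", "set": tag, **summ.to_dict()})
        envl, _ = read_ascii_grid(out / f"envelope_{tag}.asc")
        summ = pp.area_summary(np.nan_to_num(envl), pa, treecov, stack.geometry)
        rows.append({"model": "envelope", "set": tag, **summ.to_dict()})
    areas = pd.DataFrame(rows)
    _write_csv(areas, out / "areas.csv", cfg)

    # percent change: current-only vs current+historical, per delta
    changes = []
    for tag in tags:
        if tag == "CURR":
            continue
        for model in areas["model"].unique():
            a_cur = areas.query("model == @model and set == 'CURR'")["total_km2"].iloc[0]
            a_hist = areas.query("model == @model and set == @tag")["total_km2"].iloc[0]
            if a_cur > 0:
                changes.append(
                    {
                        "model": model, "set": tag,
                        "pct_area_change": pp.percent_area_change(a_cur, a_hist),
                    }
                )
    _write_csv(pd.DataFrame(changes), out / "area_changes.csv", cfg)


def stage_nichetest(cfg: PipelineConfig, out: Path) -> None:
    """Current-vs-historical medians and Mann-Whitney tests per variable."""
    stack, occ = _load_prepared(cfg, out)
    variables = [v for v in CLIMATE_VARIABLES if v in occ.df.columns]
    if "ELEV" in occ.df.columns:
        variables.append("ELEV")
    report = pp.niche_shift_report(occ, variables, deltas=cfg.deltas)
    _write_csv(report, out / "niche_shift.csv", cfg)


STAGES = {
    "prepare": stage_prepare,
    "fit": stage_fit,
    "evaluate": stage_evaluate,
    "ensemble": stage_ensemble,
    "envelope": stage_envelope,
    "overlay": stage_overlay,
    "nichetest": stage_nichetest,
}


def run_pipeline(cfg: PipelineConfig, out_dir) -> Path:
    """Run every stage in order; on failure, leave a FAILED marker naming the
    stage and re-raise."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_info.json").write_text(
        json.dumps(
            {"config_hash": cfg.config_hash(), "seed": cfg.seed,
             "config": dataclasses.asdict(cfg)},
            indent=2, default=str,
        )
    )
    failed = out / "FAILED"
    if failed.exists():
        failed.unlink()
    for name, stage in STAGES.items():
        t0 = time.perf_counter()
        try:
            stage(cfg, out)
        except Exception as exc:
            failed.write_text(f"stage: {name}\nerror: {exc!r}\n")
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        log.info("stage %-9s done in %.1fs", name, time.perf_counter() - t0)
    return out
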