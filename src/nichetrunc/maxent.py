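"""Presence-background maximum-entropy distribution model.

The model estimates the distribution q over background cells with maximum
entropy subject to matching feature expectations at the presence records,
which is equivalent to minimising the L1-regularised convex objective

    J(lambda) = -(1/m) sum_i lambda . f(x_i) + log Z(lambda)
                + sum_j beta_j |lambda_j|,

where Z sums exp(lambda . f) over the background, m is the number of
presences, and beta_j is a per-feature penalty (a per-class default scaled
by the global regularisation multiplier and by 1/sqrt(m)).  The objective is
minimised exactly via the split-variable reformulation
``lambda = lambda_plus - lambda_minus`` with non-negativity bounds, which
turns the non-smooth L1 term into a smooth bound-constrained problem solved
by L-BFGS-B.

Feature classes follow the classic maxent SDM vocabulary: linear, quadratic,
product, forward/reverse hinge and threshold, all evaluated on min-max
normalised variables so every feature lies in [0, 1] on the background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .grids import GridStack

__all__ = [
    "Feature",
    "FeatureSet",
    "MaxentModel",
    "build_features",
    "fit_maxent",
    "predict",
    "predict_values",
    "response_curve",
    "jackknife_importance",
    "cross_validate",
    "sample_background",
    "ALL_FEATURE_CLASSES",
]

ALL_FEATURE_CLASSES = ("linear", "quadratic", "product", "hinge", "threshold")

# per-class base penalties, interpolated on presence count (m, beta) and then
# multiplied by the regularisation multiplier and divided by sqrt(m)
_BETA_TABLES = {
    "linear": [(10, 1.0), (30, 0.2), (100, 0.05)],
    "quadratic": [(10, 1.0), (30, 0.2), (100, 0.05)],
    "product": [(10, 1.0), (30, 0.2), (100, 0.05)],
    "hinge": [(10, 0.5), (100, 0.5)],
    "threshold": [(10, 2.0), (100, 1.0)],
}


def _class_beta(kind: str, m: int) -> float:
    table = _BETA_TABLES[kind]
    ms, bs = zip(*table)
    return float(np.interp(m, ms, bs))


@dataclass(frozen=True)
class Feature:
    """One model feature: a transform of one variable (or a product of two)."""

    kind: str  # linear | quadratic | product | hinge | rhinge | threshold
    var: str
    var2: str | None = None
    knot: float | None = None

    @property
    def involved(self) -> tuple[str, ...]:
        return (self.var,) if self.var2 is None else (self.var, self.var2)


@dataclass
class FeatureSet:
    """Feature definitions plus the background min-max normalisation bounds."""

    features: list[Feature]
    bounds: dict[str, tuple[float, float]]

    @property
    def variables(self) -> list[str]:
        seen: dict[str, None] = {}
        for f in self.features:
            for v in f.involved:
                seen.setdefault(v)
        return list(seen)

    def __len__(self) -> int:
        return len(self.features)

    def _z(self, name: str, values: np.ndarray) -> np.ndarray:
        lo, hi = self.bounds[name]
        if hi == lo:
            return np.zeros_like(values, dtype=float)
        return np.clip((values - lo) / (hi - lo), 0.0, 1.0)

    def evaluate(self, data: dict[str, np.ndarray]) -> np.ndarray:
        """Design matrix (n_samples, n_features); every entry in [0, 1].

        Variables are clamped to their background range before the feature
        transform, so extrapolated predictions stay bounded.
        """
        cols = []
        for f in self.features:
            v = np.asarray(data[f.var], dtype=float)
            z = self._z(f.var, v)
            if f.kind == "linear":
                col = z
            elif f.kind == "quadratic":
                col = z**2
            elif f.kind == "product":
                col = z * self._z(f.var2, np.asarray(data[f.var2], dtype=float))
            elif f.kind == "hinge":
                lo, hi = self.bounds[f.var]
                vc = np.clip(v, lo, hi)
                col = np.clip((vc - f.knot) / (hi - f.knot), 0.0, 1.0)
            elif f.kind == "rhinge":
                lo, hi = self.bounds[f.var]
                vc = np.clip(v, lo, hi)
                col = np.clip((f.knot - vc) / (f.knot - lo), 0.0, 1.0)
            elif f.kind == "threshold":
                col = (v > f.knot).astype(float)
            else:  # pragma: no cover
                raise ValueError(f"unknown feature class {f.kind!r}")
            cols.append(col)
        return np.column_stack(cols) if cols else np.empty((len(next(iter(data.values()))), 0))

    def betas(
        self, m: int, reg_multiplier: float, presence_design: np.ndarray | None = None
    ) -> np.ndarray:
        """Final per-feature L1 penalties for m presences.

        Following the standard formulation, the per-class base penalty is
        scaled by the feature's standard deviation over the presence sample
        (floored at a small value so constant features stay penalised) and
        by 1/sqrt(m), then multiplied by the global regularisation
        multiplier.
        """
        kinds = ["hinge" if f.kind == "rhinge" else f.kind for f in self.features]
        base = np.array([_class_beta(k, m) for k in kinds])
        if presence_design is not None and presence_design.size:
            sd = presence_design.std(axis=0)
            base = base * np.maximum(sd, 0.05)
        return reg_multiplier * base / np.sqrt(m)

    def restrict(self, variables) -> "FeatureSet":
        """Features involving only the given variables (products need both)."""
        keep = set(variables)
        feats = [f for f in self.features if set(f.involved) <= keep]
        return FeatureSet(feats, dict(self.bounds))

    def drop(self, variable: str) -> "FeatureSet":
        """Features not involving the given variable."""
        feats = [f for f in self.features if variable not in f.involved]
        return FeatureSet(feats, dict(self.bounds))


def build_features(
    background: dict[str, np.ndarray],
    variables,
    classes=ALL_FEATURE_CLASSES,
    n_hinge_knots: int = 30,
    n_threshold_knots: int = 10,
) -> FeatureSet:
    """Build the feature expansion from the background sample.

    Hinge knots (both forward and reverse) sit at equally spaced background
    quantiles, as do threshold knots.  A variable with zero range on the
    background keeps only a (constant-zero) linear feature; its nonlinear
    features are dropped with a warning.
    """
    if n_hinge_knots < 2:
        raise ValueError("n_hinge_knots must be >= 2")
    variables = list(variables)
    classes = list(classes)
    bounds = {}
    degenerate = set()
    for v in variables:
        vals = np.asarray(background[v], dtype=float)
        vals = vals[np.isfinite(vals)]
        lo, hi = float(vals.min()), float(vals.max())
        bounds[v] = (lo, hi)
        if hi == lo:
            degenerate.add(v)
    if degenerate:
        warnings.warn(
            f"variables {sorted(degenerate)} have zero background range; "
            "keeping only their linear features"
        )
    feats: list[Feature] = []
    for v in variables:
        if "linear" in classes:
            feats.append(Feature("linear", v))
        if v in degenerate:
            continue
        if "quadratic" in classes:
            feats.append(Feature("quadratic", v))
        if "hinge" in classes:
            qs = np.quantile(
                np.asarray(background[v], dtype=float),
                np.linspace(0, 1, n_hinge_knots + 2)[1:-1],
            )
            lo, hi = bounds[v]
            for k in np.unique(qs):
                if k < hi:
                    feats.append(Feature("hinge", v, knot=float(k)))
                if k > lo:
                    feats.append(Feature("rhinge", v, knot=float(k)))
        if "threshold" in classes:
            qs = np.quantile(
                np.asarray(background[v], dtype=float),
                np.linspace(0, 1, n_threshold_knots + 2)[1:-1],
            )
            lo, hi = bounds[v]
            for k in np.unique(qs):
                if lo <= k < hi:
                    feats.append(Feature("threshold", v, knot=float(k)))
    if "product" in classes:
        for i, a in enumerate(variables):
            for b in variables[i + 1 :]:
                if a not in degenerate and b not in degenerate:
                    feats.append(Feature("product", a, b))
    return FeatureSet(feats, bounds)


def sample_background(
    stack: GridStack, variables, max_cells: int = 10_000, seed: int = 0
) -> tuple[dict[str, np.ndarray], tuple[np.ndarray, np.ndarray]]:
    """Background sample: all valid study-area cells, or a seeded uniform
    sample of ``max_cells`` if there are more."""
    variables = list(variables)
    mask = stack.valid_mask(variables)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("no valid background cells")
    if rows.size > max_cells:
        idx = np.random.default_rng(seed).choice(rows.size, max_cells, replace=False)
        idx.sort()
        rows, cols = rows[idx], cols[idx]
    return stack.values_at(rows, cols, variables), (rows, cols)


@dataclass
class MaxentModel:
    """A fitted maximum-entropy model for one variable subset."""

    features: FeatureSet
    lambdas: np.ndarray
    betas: np.ndarray
    reg_multiplier: float
    log_normalizer: float      # log Z over the training background
    entropy: float             # H of the fitted distribution over background
    training_gain: float       # regularised gain over the uniform model
    n_presences: int
    n_background: int
    presence_means: dict[str, float] = field(default_factory=dict)
    model_id: str = ""

    @property
    def variables(self) -> list[str]:
        return self.features.variables

    @property
    def n_nonzero(self) -> int:
        return int(np.sum(np.abs(self.lambdas) > 1e-8))

    # -- plain-text serialization ------------------------------------------
    def to_text(self, path) -> None:
        lines = [
            "# nichetrunc maxent model",
            f"model_id {self.model_id}",
            f"reg_multiplier {self.reg_multiplier!r}",
            f"log_normalizer {self.log_normalizer!r}",
            f"entropy {self.entropy!r}",
            f"training_gain {self.training_gain!r}",
            f"n_presences {self.n_presences}",
            f"n_background {self.n_background}",
        ]
        for v, (lo, hi) in self.features.bounds.items():
            lines.append(f"bounds {v} {lo!r} {hi!r}")
        for v, mu in self.presence_means.items():
            lines.append(f"presence_mean {v} {mu!r}")
        for f, lam, beta in zip(self.features.features, self.lambdas, self.betas):
            lines.append(
                f"feature {f.kind} {f.var} {f.var2 or '-'} "
                f"{'-' if f.knot is None else repr(float(f.knot))} "
                f"{float(lam)!r} {float(beta)!r}"
            )
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_text(cls, path) -> "MaxentModel":
        head: dict[str, str] = {}
        bounds: dict[str, tuple[float, float]] = {}
        means: dict[str, float] = {}
        feats, lams, betas = [], [], []
        for line in Path(path).read_text().splitlines():
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            key = parts[0]
            if key == "bounds":
                bounds[parts[1]] = (float(parts[2]), float(parts[3]))
            elif key == "presence_mean":
                means[parts[1]] = float(parts[2])
            elif key == "feature":
                kind, var, var2, knot, lam, beta = parts[1:7]
                feats.append(
                    Feature(
                        kind,
                        var,
                        None if var2 == "-" else var2,
                        None if knot == "-" else float(knot),
                    )
                )
                lams.append(float(lam))
                betas.append(float(beta))
            else:
                head[key] = parts[1] if len(parts) > 1 else ""
        return cls(
            features=FeatureSet(feats, bounds),
            lambdas=np.array(lams),
            betas=np.array(betas),
            reg_multiplier=float(head["reg_multiplier"]),
            log_normalizer=float(head["log_normalizer"]),
            entropy=float(head["entropy"]),
            training_gain=float(head["training_gain"]),
            n_presences=int(head["n_presences"]),
            n_background=int(head["n_background"]),
            presence_means=means,
            model_id=head.get("model_id", ""),
        )


def _as_covariates(data, variables) -> dict[str, np.ndarray]:
    if isinstance(data, dict):
        return {v: np.asarray(data[v], dtype=float) for v in variables}
    # OccurrenceSet-like
    return data.covariates(variables)


def _objective_factory(f_mean: np.ndarray, F_bg: np.ndarray, beta: np.ndarray):
    p = F_bg.shape[1]

    def obj(w):
        lam = w[:p] - w[p:]
        s = F_bg @ lam
        log_z = logsumexp(s)
        q = np.exp(s - log_z)
        val = -(f_mean @ lam) + log_z + beta @ (w[:p] + w[p:])
        g = -f_mean + q @ F_bg
        return val, np.concatenate([g + beta, -g + beta])

    return obj


def fit_maxent(
    presences,
    background,
    features: FeatureSet,
    reg_multiplier: float = 2.5,
    max_iter: int = 5000,
    tol: float = 1e-5,
    betas: np.ndarray | float | None = None,
    init: np.ndarray | None = None,
    model_id: str = "",
) -> MaxentModel:
    """Fit the L1-regularised maximum-entropy model.

    ``presences`` and ``background`` are either covariate dicts
    (variable -> value array) or objects exposing ``covariates``.  ``betas``
    overrides the per-class default penalties (already final, i.e. not
    rescaled); ``init`` seeds the optimiser with a lambda vector, used by the
    convexity checks — the optimum is independent of it.
    """
    variables = features.variables
    pres = _as_covariates(presences, variables)
    bg = _as_covariates(background, variables)
    m = len(next(iter(pres.values()))) if variables else 0
    if m < 2:
        raise ValueError("need at least 2 presence records")
    F_pr = features.evaluate(pres)
    F_bg = features.evaluate(bg)
    n_bg = F_bg.shape[0]
    p = len(features)
    if betas is None:
        beta = features.betas(m, reg_multiplier, presence_design=F_pr)
    else:
        beta = np.broadcast_to(np.asarray(betas, dtype=float), (p,)).copy()
    f_mean = F_pr.mean(axis=0) if p else np.zeros(0)

    w0 = np.zeros(2 * p)
    if init is not None:
        lam0 = np.asarray(init, dtype=float)
        w0[:p] = np.maximum(lam0, 0)
        w0[p:] = np.maximum(-lam0, 0)
    res = minimize(
        _objective_factory(f_mean, F_bg, beta),
        w0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * (2 * p),
        options={
            # ftol is relative to |f|; scale the user tol down hard so runs
            # from different initialisations agree to ~1e-9 in objective
            "ftol": tol * 1e-9,
            "gtol": 1e-9,
            "maxiter": max_iter,
            "maxfun": 40 * max_iter,
            "maxls": 50,
        },
    )
    lam = res.x[:p] - res.x[p:]
    lam[np.abs(lam) < 1e-10] = 0.0
    s = F_bg @ lam
    log_z = float(logsumexp(s))
    q = np.exp(s - log_z)
    entropy = float(-(q * (s - log_z)).sum())
    gain = float(f_mean @ lam - log_z + np.log(n_bg) - beta @ np.abs(lam))
    return MaxentModel(
        features=features,
        lambdas=lam,
        betas=beta,
        reg_multiplier=reg_multiplier,
        log_normalizer=log_z,
        entropy=entropy,
        training_gain=gain,
        n_presences=m,
        n_background=n_bg,
        presence_means={v: float(np.mean(pres[v])) for v in variables},
        model_id=model_id,
    )


def predict_values(model: MaxentModel, data, output: str = "logistic") -> np.ndarray:
    """Model output at arbitrary covariate samples.

    ``raw`` is exp(lambda . f) normalised by the training-background Z, so it
    sums to 1 over the training background; ``logistic`` is the entropy-based
    transform e^H q / (1 + e^H q), mapping the typical background cell to
    suitability well below 1 and lying strictly inside (0, 1).
    """
    cov = _as_covariates(data, model.variables)
    F = model.features.evaluate(cov)
    raw = np.exp(F @ model.lambdas - model.log_normalizer)
    if output == "raw":
        return raw
    if output == "logistic":
        eh = np.exp(model.entropy) * raw
        return eh / (1.0 + eh)
    raise ValueError("output must be 'raw' or 'logistic'")


def predict(model: MaxentModel, stack: GridStack, output: str = "logistic") -> np.ndarray:
    """Suitability layer over the study grid (nan outside valid cells)."""
    for v in model.variables:
        if v not in stack:
            raise ValueError(f"variable {v!r} missing from the stack")
    mask = stack.valid_mask(model.variables)
    rows, cols = np.nonzero(mask)
    vals = stack.values_at(rows, cols, model.variables)
    out = np.full(stack.geometry.shape, np.nan)
    out[rows, cols] = predict_values(model, vals, output=output)
    return out


def response_curve(
    model: MaxentModel, variable: str, grid_points: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """Logistic output as one variable sweeps its background range while all
    other variables sit at their mean presence values."""
    if variable not in model.variables:
        raise ValueError(f"{variable!r} is not a model variable")
    lo, hi = model.features.bounds[variable]
    sweep = np.linspace(lo, hi, grid_points)
    data = {
        v: np.full(grid_points, model.presence_means[v]) for v in model.variables
    }
    data[variable] = sweep
    return sweep, predict_values(model, data, output="logistic")


def jackknife_importance(
    presences, background, features: FeatureSet, variables=None, **fit_kw
) -> dict[str, dict[str, float]]:
    """Per-variable regularised training gain with the variable alone and
    with the variable left out, plus the full-model gain."""
    variables = list(variables) if variables is not None else features.variables
    if len(variables) < 2:
        raise ValueError("jackknife needs at least 2 variables")
    full = fit_maxent(presences, background, features, **fit_kw)
    out: dict[str, dict[str, float]] = {}
    for v in variables:
        alone = fit_maxent(presences, background, features.restrict([v]), **fit_kw)
        without = fit_maxent(presences, background, features.drop(v), **fit_kw)
        out[v] = {
            "gain_alone": alone.training_gain,
            "gain_without": without.training_gain,
            "gain_full": full.training_gain,
        }
    return out


@dataclass
class CVResult:
    models: list[MaxentModel]
    fold_aucs: list[float]
    mean_auc: float
    mean_map: np.ndarray | None


def cross_validate(
    presences,
    background,
    features: FeatureSet,
    k: int = 10,
    seed: int = 0,
    stack: GridStack | None = None,
    **fit_kw,
) -> CVResult:
    """Seeded k-fold cross-validation over presence records.

    Each replicate is trained on k-1 folds; AUC is evaluated on the held-out
    presences against the background.  The mean map (if a stack is given) is
    the cellwise mean of the replicate logistic maps.
    """
    from .evaluation import compute_auc

    variables = features.variables
    pres = _as_covariates(presences, variables)
    bg = _as_covariates(background, variables)
    m = len(next(iter(pres.values())))
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > m:
        raise ValueError(f"k={k} exceeds the {m} presences")
    perm = np.random.default_rng(seed).permutation(m)
    folds = np.array_split(perm, k)
    models, aucs, maps = [], [], []
    for fold in folds:
        test = np.zeros(m, dtype=bool)
        test[fold] = True
        train = {v: pres[v][~test] for v in variables}
        model = fit_maxent(train, bg, features, **fit_kw)
        models.append(model)
        pr_scores = predict_values(model, {v: pres[v][test] for v in variables})
        bg_scores = predict_values(model, bg)
        aucs.append(compute_auc(pr_scores, bg_scores))
        if stack is not None:
            maps.append(predict(model, stack))
    mean_map = None
    if maps:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-nan cells
            mean_map = np.nanmean(np.stack(maps), axis=0)
    return CVResult(models, aucs, float(np.mean(aucs)), mean_map)
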