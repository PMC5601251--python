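"""Candidate age functions, breakpoint scanning, and AIC model averaging.

The population-level age trajectory of breeding success is chosen among a
null model (no age term), linear and quadratic polynomials, and continuous
piecewise-linear (hinge) models with one or two breakpoints, all fitted as
Bernoulli GLMMs with individual and year intercepts.  Single-threshold
models are scanned over a grid of integer candidate ages; a 95% confidence
interval for the breakpoint is read off the profile deviance (candidates
whose deviance lies within the chi-square(1) 95% quantile, 3.841, of the
minimum).  Models within two AIC units of the best form the top set, whose
predictions are combined with Akaike weights
``w_i = exp(-d_i/2) / sum_j exp(-d_j/2)`` on the response scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .glmm import GlmmFit, SeparationError, fit_glmm, predict_fixed

__all__ = [
    "AgeFunctionSpec",
    "AgeBasis",
    "ThresholdScanResult",
    "ModelSet",
    "make_age_basis",
    "default_threshold_grid",
    "fit_age_model",
    "scan_thresholds",
    "threshold_ci",
    "fit_candidate_models",
    "select_and_average",
    "akaike_weights",
]

_KINDS = ("null", "linear", "quadratic", "threshold1", "threshold2")


@dataclass(frozen=True)
class AgeFunctionSpec:
    """A candidate age-function family: kind plus 0-2 integer breakpoints."""

    kind: str
    thresholds: tuple = ()

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown age-function kind {self.kind!r}")
        need = {"null": 0, "linear": 0, "quadratic": 0, "threshold1": 1, "threshold2": 2}[self.kind]
        th = tuple(int(t) for t in self.thresholds)
        if len(th) != need:
            raise ValueError(f"{self.kind} requires {need} thresholds, got {len(th)}")
        if len(th) == 2 and th[0] >= th[1]:
            raise ValueError("thresholds must be strictly increasing")
        object.__setattr__(self, "thresholds", th)

    @property
    def label(self) -> str:
        if self.thresholds:
            return f"{self.kind}@{','.join(map(str, self.thresholds))}"
        return self.kind


@dataclass
class AgeBasis:
    """Design columns for an age function, with centring constants.

    Columns are built from raw ages (hinge pieces are continuous at the
    breakpoints by construction) and then centred on their fitting-sample
    means; ``transform`` re-applies the same centring to new ages so that
    predictions are exact.
    """

    spec: AgeFunctionSpec
    names: list
    centers: np.ndarray

    def _raw(self, ages):
        ages = np.asarray(ages, dtype=float)
        k = self.spec.kind
        th = self.spec.thresholds
        if k == "null":
            return np.empty((len(ages), 0))
        if k == "linear":
            return ages[:, None]
        if k == "quadratic":
            return np.column_stack([ages, ages**2])
        if k == "threshold1":
            t = th[0]
            return np.column_stack([np.minimum(ages, t), np.maximum(ages - t, 0.0)])
        t1, t2 = th
        return np.column_stack(
            [
                np.minimum(ages, t1),
                np.clip(ages - t1, 0.0, t2 - t1),
                np.maximum(ages - t2, 0.0),
            ]
        )

    def transform(self, ages) -> np.ndarray:
        return self._raw(ages) - self.centers


def make_age_basis(spec: AgeFunctionSpec, ages) -> tuple[np.ndarray, AgeBasis]:
    """Build centred age-design columns for ``spec`` on the fitting ages."""
    ages = np.asarray(ages, dtype=float)
    if spec.thresholds:
        lo, hi = ages.min(), ages.max()
        for t in spec.thresholds:
            if not lo <= t <= hi:
                raise ValueError(f"threshold {t} outside the observed age range [{lo}, {hi}]")
    names = {
        "null": [],
        "linear": ["age"],
        "quadratic": ["age", "age_sq"],
        "threshold1": ["age_before", "age_after"],
        "threshold2": ["age_before", "age_between", "age_after"],
    }[spec.kind]
    basis = AgeBasis(spec=spec, names=names, centers=np.zeros(len(names)))
    raw = basis._raw(ages)
    basis.centers = raw.mean(axis=0) if raw.size else np.zeros(0)
    return raw - basis.centers, basis


@dataclass
class FittedAgeModel:
    spec: AgeFunctionSpec
    basis: AgeBasis
    fit: GlmmFit

    @property
    def aic(self):
        return self.fit.aic

    def predict(self, ages):
        Xa = self.basis.transform(ages)
        X = np.column_stack([np.ones(len(Xa)), Xa])
        return predict_fixed(self.fit, X)


def fit_age_model(df: pd.DataFrame, spec: AgeFunctionSpec, **fit_kw) -> FittedAgeModel:
    """Fit ``outcome ~ intercept + age basis + (1|individual) + (1|year)``."""
    X_age, basis = make_age_basis(spec, df["age"].to_numpy())
    X = np.column_stack([np.ones(len(df)), X_age])
    fit = fit_glmm(
        df["outcome"].to_numpy(dtype=float),
        X,
        df["individual_id"].to_numpy(),
        df["season"].to_numpy(),
        terms=["intercept"] + basis.names,
        **fit_kw,
    )
    return FittedAgeModel(spec=spec, basis=basis, fit=fit)


def default_threshold_grid(ages, min_side: int = 25, margin: int = 2) -> np.ndarray:
    """Integer candidate breakpoints: every age from min+margin to max-margin
    with at least ``min_side`` observations strictly on each side."""
    ages = np.asarray(ages)
    lo, hi = int(ages.min()), int(ages.max())
    grid = []
    for t in range(lo + margin, hi - margin + 1):
        if (ages < t).sum() >= min_side and (ages > t).sum() >= min_side:
            grid.append(t)
    return np.array(grid, dtype=int)


@dataclass
class ThresholdScanResult:
    grid: np.ndarray
    aic_profile: np.ndarray
    loglik_profile: np.ndarray
    best: AgeFunctionSpec
    models: list = field(repr=False, default_factory=list)
    ci_low: int | None = None
    ci_high: int | None = None
    failed: list = field(default_factory=list)  # candidates dropped (separation)

    @property
    def best_model(self) -> FittedAgeModel:
        i = int(np.argmin(self.aic_profile))
        return self.models[i]

    def to_frame(self):
        return pd.DataFrame(
            {"threshold": self.grid, "aic": self.aic_profile, "loglik": self.loglik_profile}
        )


def scan_thresholds(
    df: pd.DataFrame,
    grid=None,
    kind: str = "threshold1",
    min_side: int = 25,
    double_gap: int = 3,
    ci_level: float = 0.95,
) -> ThresholdScanResult:
    """Refit the age GLMM at every candidate breakpoint and profile the AIC.

    For ``kind="threshold2"`` the grid is all ordered pairs ``(t1, t2)`` from
    the single-threshold grid with ``t2 - t1 >= double_gap``.  Variance
    components are warm-started along the grid, which leaves the optimum
    unchanged but speeds the scan up considerably.
    """
    ages = df["age"].to_numpy()
    if grid is None:
        grid = default_threshold_grid(ages, min_side=min_side)
    grid = np.asarray(grid)
    if kind == "threshold2" and grid.ndim == 1:
        grid = np.array(
            [(a, b) for a in grid for b in grid if b - a >= double_gap], dtype=int
        )
    if len(grid) == 0:
        raise ValueError("empty candidate grid after support constraints")

    models, kept, failed = [], [], []
    theta0 = (np.log(0.5), np.log(0.5))
    entries = list(grid) if grid.ndim == 1 else list(range(len(grid)))
    for t in entries:
        th = (int(grid[t][0]), int(grid[t][1])) if grid.ndim == 2 else (int(t),)
        spec = AgeFunctionSpec(kind, th)
        try:
            m = fit_age_model(df, spec, theta0=theta0)
        except (SeparationError, np.linalg.LinAlgError):
            # a hinge segment with (near-)one-sided outcomes makes the
            # candidate unidentifiable; exclude it from the profile
            failed.append(th)
            continue
        s2i = max(m.fit.sigma2_ind, 1e-3)
        s2y = max(m.fit.sigma2_year, 1e-3)
        theta0 = (0.5 * np.log(s2i), 0.5 * np.log(s2y))
        models.append(m)
        kept.append(th)
    if not models:
        raise ValueError("every candidate threshold fit failed (separation)")
    grid = (np.array([t[0] for t in kept], dtype=int) if grid.ndim == 1
            else np.array(kept, dtype=int))
    aics = np.array([m.aic for m in models])
    lls = np.array([m.fit.loglik for m in models])
    i = int(np.argmin(aics))
    res = ThresholdScanResult(
        grid=grid, aic_profile=aics, loglik_profile=lls, best=models[i].spec,
        models=models, failed=failed,
    )
    if grid.ndim == 1:
        res.ci_low, res.ci_high = threshold_ci(res, level=ci_level)
    return res


def threshold_ci(scan: ThresholdScanResult, level: float = 0.95) -> tuple[int, int]:
    """Profile-deviance CI for a single breakpoint.

    The interval is the contiguous run of candidates around the best whose
    deviance (-2 loglik) is within the chi-square(1) quantile at ``level``
    (3.841 at 0.95) of the minimum; endpoints are the extreme grid ages in
    that run.  Based on the Laplace log-likelihood, so itself approximate.
    """
    dev = -2.0 * scan.loglik_profile
    cut = chi2.ppf(level, df=1)
    ok = dev <= dev.min() + cut
    i = int(np.argmin(dev))
    lo = i
    while lo > 0 and ok[lo - 1]:
        lo -= 1
    hi = i
    while hi < len(ok) - 1 and ok[hi + 1]:
        hi += 1
    return int(scan.grid[lo]), int(scan.grid[hi])


def akaike_weights(aics) -> np.ndarray:
    """Akaike weights over a set of AIC values (smaller is better)."""
    aics = np.asarray(aics, dtype=float)
    d = aics - aics.min()
    w = np.exp(-0.5 * d)
    return w / w.sum()


@dataclass
class ModelSet:
    """Top model set (dAIC < 2) with Akaike weights and an averaged curve."""

    members: list  # FittedAgeModel, all models considered
    delta_aic: np.ndarray  # vs best, all models
    top_indices: np.ndarray
    weights: np.ndarray  # over top set only, sums to 1
    prediction_ages: np.ndarray
    averaged: np.ndarray  # response-scale averaged prediction
    best_index: int

    @property
    def best(self) -> FittedAgeModel:
        return self.members[self.best_index]

    def to_frame(self):
        best_p, best_se = self.best.predict(self.prediction_ages)
        return pd.DataFrame(
            {
                "age": self.prediction_ages,
                "fit": best_p,
                "se": best_se,
                "averaged_fit": self.averaged,
            }
        )

    def summary(self):
        rows = []
        w = dict(zip(self.top_indices.tolist(), self.weights))
        for j, m in enumerate(self.members):
            rows.append(
                {
                    "model": m.spec.label,
                    "aic": m.aic,
                    "delta_aic": self.delta_aic[j],
                    "weight": w.get(j, 0.0),
                    "in_top_set": j in w,
                }
            )
        return pd.DataFrame(rows).sort_values("delta_aic").reset_index(drop=True)


def fit_candidate_models(
    df: pd.DataFrame,
    grid=None,
    min_side: int = 25,
    include_double: bool = False,
    double_gap: int = 3,
):
    """Fit the full candidate family: null, linear, quadratic, all single
    thresholds (and optionally all double thresholds).  Returns the list of
    fitted models and the single-threshold scan (for the breakpoint CI)."""
    models = [fit_age_model(df, AgeFunctionSpec(k)) for k in ("null", "linear", "quadratic")]
    scan = scan_thresholds(df, grid=grid, kind="threshold1", min_side=min_side)
    models.extend(scan.models)
    if include_double:
        scan2 = scan_thresholds(
            df, grid=grid, kind="threshold2", min_side=min_side, double_gap=double_gap
        )
        models.extend(scan2.models)
    return models, scan


def select_and_average(models, prediction_ages, delta_cut: float = 2.0) -> ModelSet:
    """Build the top model set (strict dAIC < ``delta_cut``) and the
    Akaike-weight-averaged prediction curve on the response scale.

    Ties for best are broken by fewer parameters, then by earlier (smaller)
    first threshold.
    """
    if not models:
        raise ValueError("empty model list")
    aics = np.array([m.aic for m in models])
    nobs = {m.fit.n_obs for m in models}
    if len(nobs) > 1:
        raise ValueError("candidate models were fitted on different datasets")
    order = sorted(
        range(len(models)),
        key=lambda j: (
            aics[j],
            models[j].fit.k,
            models[j].spec.thresholds[0] if models[j].spec.thresholds else -np.inf,
        ),
    )
    best = order[0]
    delta = aics - aics[best]
    top = np.flatnonzero(delta < delta_cut)
    w = akaike_weights(aics[top])
    prediction_ages = np.asarray(prediction_ages, dtype=float)
    preds = np.stack([models[j].predict(prediction_ages)[0] for j in top])
    averaged = w @ preds
    return ModelSet(
        members=list(models),
        delta_aic=delta,
        top_indices=top,
        weights=w,
        prediction_ages=prediction_ages,
        averaged=averaged,
        best_index=int(best),
    )
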