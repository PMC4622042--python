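"""Nonlinear growth models, per-animal least-squares fitting and selection.

Five classical weight-age models are supported (parameters: asymptotic mature
weight ``A`` in kg, integration constant ``b``, maturity rate ``K`` per age
unit, plus the Richards inflection exponent ``M``):

========  ==============================
brody         w(t) = A (1 - b e^{-Kt})
bertalanffy   w(t) = A (1 - b e^{-Kt})^3
logistic      w(t) = A (1 + b e^{-Kt})^{-1}
gompertz      w(t) = A exp(-b e^{-Kt})
richards      w(t) = A (1 - b e^{-Kt})^M
========  ==============================

Each animal is fitted independently by Gauss-Newton least squares with a
Levenberg-Marquardt damping ladder; convergence is declared when the maximum
relative parameter change drops below ``tol``. The goodness-of-fit battery
(adjusted R^2, MSE, MAD over the early and late curve segments, AIC) feeds a
rank-by-criteria model selection.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import WeightSeries

__all__ = [
    "GrowthModelSpec", "FitDiagnostics", "GrowthFit", "PopulationFitSummary",
    "MODELS", "get_model", "predict_weight", "initial_estimates", "fit_animal",
    "gof_summary", "fit_population", "select_model", "preadjust_fixed_effects",
    "fits_to_frame",
]

_K_GRID = np.round(np.arange(1, 101) * 0.005, 10)  # 0.005 .. 0.5


@dataclass(frozen=True)
class GrowthModelSpec:
    """A growth function, its analytic Jacobian, and parameter bookkeeping."""

    name: str
    param_names: tuple
    predict: callable = field(repr=False)
    jacobian: callable = field(repr=False)
    b_from_first: callable = field(repr=False)  # (w0, t0, A0, K) -> b0

    @property
    def n_params(self) -> int:
        return len(self.param_names)


def _brody(p, t):
    A, b, K = p
    return A * (1.0 - b * np.exp(-K * t))


def _brody_jac(p, t):
    A, b, K = p
    E = np.exp(-K * t)
    return np.column_stack([1.0 - b * E, -A * E, A * b * t * E])


def _bertalanffy(p, t):
    A, b, K = p
    u = 1.0 - b * np.exp(-K * t)
    return A * u ** 3


def _bertalanffy_jac(p, t):
    A, b, K = p
    E = np.exp(-K * t)
    u = 1.0 - b * E
    return np.column_stack([u ** 3, -3 * A * u ** 2 * E, 3 * A * u ** 2 * b * t * E])


def _logistic(p, t):
    A, b, K = p
    v = 1.0 + b * np.exp(-K * t)
    return A / v


def _logistic_jac(p, t):
    A, b, K = p
    E = np.exp(-K * t)
    v = 1.0 + b * E
    return np.column_stack([1.0 / v, -A * E / v ** 2, A * b * t * E / v ** 2])


def _gompertz(p, t):
    A, b, K = p
    return A * np.exp(-b * np.exp(-K * t))


def _gompertz_jac(p, t):
    A, b, K = p
    E = np.exp(-K * t)
    f = A * np.exp(-b * E)
    return np.column_stack([f / A, -f * E, f * b * t * E])


def _richards(p, t):
    A, b, K, M = p
    u = 1.0 - b * np.exp(-K * t)
    if np.any(u <= 0):
        raise ValueError("richards: base 1 - b*exp(-Kt) <= 0 gives a complex value")
    return A * u ** M


def _richards_jac(p, t):
    A, b, K, M = p
    E = np.exp(-K * t)
    u = 1.0 - b * E
    if np.any(u <= 0):
        raise ValueError("richards: base 1 - b*exp(-Kt) <= 0 gives a complex value")
    um1 = u ** (M - 1.0)
    return np.column_stack([
        u ** M, -A * M * um1 * E, A * M * um1 * b * t * E, A * u ** M * np.log(u),
    ])


MODELS: dict[str, GrowthModelSpec] = {
    "brody": GrowthModelSpec(
        "brody", ("A", "b", "K"), _brody, _brody_jac,
        lambda w0, t0, A0, K: (1.0 - w0 / A0) * math.exp(K * t0),
    ),
    "bertalanffy": GrowthModelSpec(
        "bertalanffy", ("A", "b", "K"), _bertalanffy, _bertalanffy_jac,
        lambda w0, t0, A0, K: (1.0 - (w0 / A0) ** (1 / 3)) * math.exp(K * t0),
    ),
    "logistic": GrowthModelSpec(
        "logistic", ("A", "b", "K"), _logistic, _logistic_jac,
        lambda w0, t0, A0, K: (A0 / w0 - 1.0) * math.exp(K * t0),
    ),
    "gompertz": GrowthModelSpec(
        "gompertz", ("A", "b", "K"), _gompertz, _gompertz_jac,
        lambda w0, t0, A0, K: math.log(A0 / w0) * math.exp(K * t0),
    ),
    "richards": GrowthModelSpec(
        "richards", ("A", "b", "K", "M"), _richards, _richards_jac,
        lambda w0, t0, A0, K: (1.0 - w0 / A0) * math.exp(K * t0),
    ),
}


def get_model(name) -> GrowthModelSpec:
    if isinstance(name, GrowthModelSpec):
        return name
    try:
        return MODELS[name]
    except KeyError:
        raise ValueError(f"unknown growth model {name!r}; choose from {sorted(MODELS)}")


def predict_weight(model, params, t):
    """Evaluate the model's weight (kg) at age(s) ``t``."""
    spec = get_model(model)
    params = np.asarray(params, dtype=float)
    if params.shape != (spec.n_params,):
        raise ValueError(f"{spec.name} expects {spec.n_params} parameters")
    return spec.predict(params, np.asarray(t, dtype=float))


@dataclass
class FitDiagnostics:
    """Per-animal goodness of fit. ``mad1``/``mad2`` are mean absolute
    residuals over the early and late halves of the age grid (for the 6-point
    cattle grid: ages 0/6/12 vs 15/18/24 months)."""

    r2_adj: float
    mse: float
    mad1: float
    mad2: float
    aic: float
    residuals: np.ndarray


@dataclass
class GrowthFit:
    animal_id: str
    model: str
    params: np.ndarray
    converged: bool
    diagnostics: FitDiagnostics | None = None
    n_iter: int = 0

    def param(self, name: str) -> float:
        spec = get_model(self.model)
        return float(self.params[spec.param_names.index(name)])


def initial_estimates(series: WeightSeries, model) -> np.ndarray:
    """Starting values: A0 = 1.1 x max weight; b0 solved from the first
    observation given A0; K0 = grid argmin of the SSE over {0.005..0.5}.

    A non-increasing weight series triggers the degenerate fallback
    (A0 = max weight, K0 = smallest grid value) with a warning.
    """
    spec = get_model(model)
    t, w = series.ages, series.weights
    if len(series) < spec.n_params:
        raise ValueError(
            f"{series.animal_id}: need >= {spec.n_params} observations for {spec.name}"
        )
    increasing = w[-1] > w[0]
    if not increasing:
        warnings.warn(
            f"{series.animal_id}: non-increasing weight series, using fallback "
            "starting values",
            stacklevel=2,
        )
        A0 = float(np.max(w))
        K0 = float(_K_GRID[0])
        b0 = _safe_b(spec, w[0], t[0], A0 * (1 + 1e-9), K0)
        p0 = [A0, b0, K0]
    else:
        A0 = 1.1 * float(np.max(w))
        best = (np.inf, _K_GRID[0], 0.1)
        for K in _K_GRID:
            b = _safe_b(spec, w[0], t[0], A0, K)
            p = [A0, b, K] + ([1.0] if spec.name == "richards" else [])
            try:
                resid = w - spec.predict(np.array(p), t)
            except ValueError:
                continue
            sse = float(resid @ resid)
            if np.isfinite(sse) and sse < best[0]:
                best = (sse, K, b)
        _, K0, b0 = best
        p0 = [A0, b0, float(K0)]
    if spec.name == "richards":
        p0.append(1.0)
    return np.asarray(p0, dtype=float)


def _safe_b(spec, w0, t0, A0, K) -> float:
    try:
        b = spec.b_from_first(w0, t0, A0, K)
    except (ValueError, ZeroDivisionError):
        b = 1e-6
    if not np.isfinite(b) or b <= 0:
        b = 1e-6
    return float(b)


def fit_animal(series: WeightSeries, model, max_iter: int = 200,
               tol: float = 1e-8) -> GrowthFit:
    """Gauss-Newton nonlinear least squares with an LM damping ladder.

    Steps are accepted only when they reduce the SSE; each rejection scales
    the damping factor by 10. Convergence requires the maximum relative
    parameter change of an accepted step to fall below ``tol``. Degenerate
    inputs (zero weight variance, singular Jacobian at every damping level)
    yield ``converged=False`` without raising, counting against the
    population convergence rate C%.
    """
    spec = get_model(model)
    t, w = series.ages, series.weights
    if len(series) < spec.n_params:
        raise ValueError(
            f"{series.animal_id}: need >= {spec.n_params} observations for {spec.name}"
        )
    if np.ptp(w) == 0.0:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            theta = initial_estimates(series, spec)
        return GrowthFit(series.animal_id, spec.name, theta, converged=False)

    theta = initial_estimates(series, spec)
    sse = _sse(spec, theta, t, w)
    lam = 1e-3
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            J = spec.jacobian(theta, t)
            r = w - spec.predict(theta, t)
        except ValueError:
            break
        if not np.all(np.isfinite(J)):
            break
        JtJ = J.T @ J
        g = J.T @ r
        accepted = False
        for _ in range(30):  # damping ladder, x10 per rejection
            D = np.diag(np.maximum(np.diag(JtJ), 1e-12))
            try:
                delta = np.linalg.solve(JtJ + lam * D, g)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            cand = theta + delta
            new_sse = _sse(spec, cand, t, w)
            if np.isfinite(new_sse) and new_sse <= sse:
                rel = np.max(np.abs(delta) / np.maximum(np.abs(theta), 1e-12))
                theta, sse = cand, new_sse
                lam = max(lam / 10.0, 1e-12)
                accepted = True
                if rel < tol:
                    converged = True
                break
            lam *= 10.0
        if not accepted or converged:
            break

    A, K = theta[0], theta[2]
    if converged and not (A > 0 and K > 0 and np.all(np.isfinite(theta))):
        converged = False
    fit = GrowthFit(series.animal_id, spec.name, theta, converged, n_iter=it)
    if converged:
        fit.diagnostics = gof_summary(series, fit)
    return fit


def _sse(spec, theta, t, w) -> float:
    try:
        resid = w - spec.predict(theta, t)
    except ValueError:
        return np.inf
    return float(resid @ resid)


def gof_summary(series: WeightSeries, fit: GrowthFit) -> FitDiagnostics:
    """Goodness-of-fit battery for one converged fit.

    mse = SSE/(n-p); r2_adj = 1 - mse / (SST/(n-1));
    aic = n ln(SSE/n) + 2(p+1) with the SSE floored at 1e-12 so a perfect
    fit yields a finite value; MAD1/MAD2 are mean |residual| over the first
    ceil(n/2) ages and the remaining ages.
    """
    spec = get_model(fit.model)
    t, w = series.ages, series.weights
    n, p = len(series), spec.n_params
    if n <= p:
        raise ValueError(f"gof_summary needs n > p (got n={n}, p={p})")
    resid = w - spec.predict(fit.params, t)
    sse = float(resid @ resid)
    sst = float(np.sum((w - w.mean()) ** 2))
    mse = sse / (n - p)
    r2_adj = 1.0 - mse / (sst / (n - 1)) if sst > 0 else np.nan
    k = math.ceil(n / 2)
    mad1 = float(np.mean(np.abs(resid[:k])))
    mad2 = float(np.mean(np.abs(resid[k:])))
    aic = n * math.log(max(sse, 1e-12) / n) + 2 * (p + 1)
    return FitDiagnostics(r2_adj, mse, mad1, mad2, aic, resid)


@dataclass
class PopulationFitSummary:
    """Per-model population summary over the attempted animals.

    C% = 100 x converged/attempted; means and SDs are computed over the
    converged animals only.
    """

    model: str
    n_attempted: int
    n_converged: int
    param_means: dict
    param_sds: dict
    diag_means: dict
    diag_sds: dict

    @property
    def c_pct(self) -> float:
        if self.n_attempted == 0:
            return 0.0
        return 100.0 * self.n_converged / self.n_attempted


_DIAG_KEYS = ("r2_adj", "mse", "mad1", "mad2", "aic")


def fit_population(phenos, model, max_iter: int = 200, tol: float = 1e-8):
    """Fit every complete series; summarise parameters and diagnostics."""
    spec = get_model(model)
    complete = [s for s in phenos if s.complete]
    if not complete:
        raise ValueError("no complete weight series to fit")
    fits = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in complete:
            fits.append(fit_animal(s, spec, max_iter=max_iter, tol=tol))
    conv = [f for f in fits if f.converged]
    if conv:
        P = np.array([f.params for f in conv])
        pm = {nm: float(P[:, j].mean()) for j, nm in enumerate(spec.param_names)}
        ps = {nm: float(P[:, j].std(ddof=1)) if len(conv) > 1 else 0.0
              for j, nm in enumerate(spec.param_names)}
        D = np.array([[getattr(f.diagnostics, k) for k in _DIAG_KEYS] for f in conv])
        dm = {k: float(D[:, j].mean()) for j, k in enumerate(_DIAG_KEYS)}
        ds = {k: float(D[:, j].std(ddof=1)) if len(conv) > 1 else 0.0
              for j, k in enumerate(_DIAG_KEYS)}
    else:
        pm, ps, dm, ds = {}, {}, {}, {}
    summary = PopulationFitSummary(spec.name, len(fits), len(conv), pm, ps, dm, ds)
    return fits, summary


def select_model(summaries, min_c_pct: float = 50.0) -> pd.DataFrame:
    """Rank models by the number of goodness-of-fit criteria won.

    Criteria: higher mean adjusted R^2, lower mean MSE, MAD1, MAD2 and AIC.
    Models with C% below ``min_c_pct`` are excluded first (a model that
    rarely converges is useless whatever its fit). Ties break on lower mean
    AIC; ranking is deterministic.
    """
    if len(summaries) < 1:
        raise ValueError("select_model needs at least one summary")
    kept = [s for s in summaries if s.c_pct >= min_c_pct and s.diag_means]
    if not kept:
        raise ValueError(f"all models excluded by the C% >= {min_c_pct} rule")
    rows = []
    for s in kept:
        rows.append({
            "model": s.model, "c_pct": s.c_pct,
            "r2_adj": s.diag_means["r2_adj"], "mse": s.diag_means["mse"],
            "mad1": s.diag_means["mad1"], "mad2": s.diag_means["mad2"],
            "aic": s.diag_means["aic"],
        })
    df = pd.DataFrame(rows)
    wins = np.zeros(len(df), dtype=int)
    wins[df["r2_adj"].idxmax()] += 1
    for crit in ("mse", "mad1", "mad2", "aic"):
        wins[df[crit].idxmin()] += 1
    df["criteria_won"] = wins
    df = df.sort_values(
        ["criteria_won", "aic", "model"], ascending=[False, True, True],
        kind="stable",
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


# ---------------------------------------------------------------------------
# fixed-effect pre-adjustment
# ---------------------------------------------------------------------------

def preadjust_fixed_effects(phenos, factor_names) -> list[WeightSeries]:
    """Remove categorical fixed effects from the raw weights, age by age.

    For each age an ordinary least-squares model regresses weight on the
    named factors (dummy coding with intercept); the adjusted weight is the
    grand mean at that age plus the OLS residual, so each age's mean is
    preserved exactly. A factor level observed once is fitted exactly and
    contributes a zero residual.
    """
    phenos = list(phenos)
    for s in phenos:
        for f in factor_names:
            if f not in s.factors:
                raise ValueError(f"{s.animal_id}: missing factor {f!r}")
    ages = sorted({a for s in phenos for a in s.ages})
    adjusted = {s.animal_id: dict(zip(s.ages, s.weights)) for s in phenos}
    for age in ages:
        members = [s for s in phenos if age in s.ages]
        if len(members) < 2:
            continue
        y = np.array([dict(zip(s.ages, s.weights))[age] for s in members])
        X = _dummy_design(members, factor_names)
        rank = np.linalg.matrix_rank(X)
        if rank >= len(members):
            raise ValueError(
                f"age {age}: fixed effects perfectly confounded with animal "
                "(zero residual degrees of freedom)"
            )
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        gmean = float(y.mean())
        for s, r in zip(members, resid):
            adjusted[s.animal_id][age] = gmean + r
    out = []
    for s in phenos:
        w = np.array([adjusted[s.animal_id][a] for a in s.ages])
        out.append(WeightSeries(s.animal_id, s.ages.copy(), w, dict(s.factors),
                                complete=s.complete))
    return out


def _dummy_design(members, factor_names) -> np.ndarray:
    cols = [np.ones(len(members))]
    for f in factor_names:
        levels = sorted({s.factors[f] for s in members})
        for lev in levels[1:]:  # drop-first coding
            cols.append(np.array([1.0 if s.factors[f] == lev else 0.0
                                  for s in members]))
    return np.column_stack(cols)


def fits_to_frame(fits) -> pd.DataFrame:
    """Tabulate per-animal fits (TSV-ready)."""
    rows = []
    for f in fits:
        spec = get_model(f.model)
        row = {"animal_id": f.animal_id, "model": f.model}
        for nm in ("A", "b", "K", "M"):
            row[nm] = (f.param(nm) if nm in spec.param_names else np.nan)
        row["converged"] = f.converged
        for k in _DIAG_KEYS:
            row[k] = getattr(f.diagnostics, k) if f.diagnostics else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
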