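"""Kinetic parameter estimation for rehydration curves.

Two estimation layers:

* :func:`fit_single_curve` — nonlinear least squares of one model against one
  rehydration curve, on the RR(t) scale (MR(t) for the Fickian model).
* :func:`fit_global_arrhenius` — the single-step approach: the Arrhenius law
  is substituted for the model's time constant and one joint least-squares
  problem is solved over every observation at every temperature, yielding
  the rate constant (or diffusivity) at the reference temperature and the
  activation energy simultaneously.  :func:`fit_two_step_arrhenius` provides
  the classical per-temperature-then-log-linear alternative for
  cross-checking; both coincide on noiseless data.

Positive parameters are estimated on a log scale (which enforces the bound),
the activation energy on its natural scale; standard errors are asymptotic,
from the Jacobian at the optimum, delta-transformed back to the raw scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .models import (
    GAS_CONSTANT,
    BoundaryMoistures,
    DegenerateRangeError,
    ExponentialParams,
    FickParams,
    FirstOrderParams,
    InvalidInputError,
    PelegParams,
    SeriesConvergenceError,
    WeibullParams,
    exponential_rr,
    fick_mr,
    first_order_rr,
    moisture_db_from_weight,
    peleg_rr,
    weibull_rr,
    weight_from_moisture_db,
)

__all__ = [
    "RehydrationCurve",
    "KineticFit",
    "ArrheniusFit",
    "TwoStepArrhenius",
    "RehydrationTime",
    "FitFailureError",
    "MODEL_NAMES",
    "fit_single_curve",
    "fit_global_arrhenius",
    "fit_two_step_arrhenius",
    "goodness_of_fit",
    "estimate_rehydration_time",
    "compare_models",
]


class FitFailureError(RuntimeError):
    """Optimisation failed to converge after all restarts; carries the best attempt."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------


@dataclass
class RehydrationCurve:
    """Time-indexed weights/moistures of one sample at one water temperature.

    Times are minutes starting at 0; weights grams; moistures %db; the
    temperature is kelvin.  Either ``weights`` or ``moistures`` may be given,
    the other is derived from ``dry_mass``.
    """

    sample_id: str
    drying_method: str
    temperature: float
    times: np.ndarray
    dry_mass: float
    weights: Optional[np.ndarray] = None
    moistures: Optional[np.ndarray] = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size < 2:
            raise InvalidInputError("a curve needs at least two observations")
        if self.times[0] != 0.0:
            raise InvalidInputError("times must start at 0")
        if np.any(np.diff(self.times) <= 0):
            raise InvalidInputError("times must be strictly increasing")
        if self.temperature <= 273.15:
            raise InvalidInputError(
                f"rehydration temperature must exceed 273.15 K, got {self.temperature}"
            )
        if self.dry_mass <= 0:
            raise InvalidInputError("dry_mass must be > 0")
        if self.weights is None and self.moistures is None:
            raise InvalidInputError("provide weights or moistures")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != self.times.shape:
                raise InvalidInputError("weights and times differ in length")
            if np.any(self.weights < self.dry_mass):
                raise InvalidInputError("weight below dry mass")
        if self.moistures is not None:
            self.moistures = np.asarray(self.moistures, dtype=float)
            if self.moistures.shape != self.times.shape:
                raise InvalidInputError("moistures and times differ in length")
            if np.any(self.moistures < 0):
                raise InvalidInputError("negative moisture")
        if self.moistures is None:
            self.moistures = moisture_db_from_weight(self.weights, self.dry_mass)
        if self.weights is None:
            self.weights = weight_from_moisture_db(self.moistures, self.dry_mass)

    def default_bounds(self) -> BoundaryMoistures:
        """M_o = first observed moisture, M_e = last (saturation criterion)."""
        m_o = float(self.moistures[0])
        m_e = float(self.moistures[-1])
        if m_e <= m_o:
            raise DegenerateRangeError(
                f"curve {self.sample_id!r}: final moisture {m_e} not above initial {m_o}"
            )
        return BoundaryMoistures(m_o=m_o, m_e=m_e)


@dataclass
class KineticFit:
    """One model fitted to one curve."""

    model: str
    params: dict
    standard_errors: dict
    r_squared: float
    rmse: float
    chi_squared: float
    residuals: np.ndarray
    predicted: np.ndarray
    observed: np.ndarray
    response_scale: str  # "rr" or "mr"
    converged: bool
    n_restarts_used: int
    curve_id: Optional[str] = None


@dataclass
class ArrheniusFit:
    """Single-step joint fit over all temperatures of one drying method."""

    model: str
    k_ref: float
    k_ref_se: float
    e_a: float  # kJ/mol
    e_a_se: float
    t_ref: float
    extras: dict
    extras_se: dict
    r_squared: float
    rmse: float
    chi_squared: float
    n_obs: int
    temperatures: np.ndarray
    residuals: np.ndarray
    converged: bool

    def rate_at(self, temperature: float) -> float:
        """Implied time constant (k_ref units) at ``temperature`` (K)."""
        sign = -1.0 if _MODELS[self.model].reciprocal_rate else 1.0
        ea_j = self.e_a * 1000.0
        return self.k_ref * math.exp(
            sign * (ea_j / GAS_CONSTANT) * (1.0 / self.t_ref - 1.0 / temperature)
        )


@dataclass
class TwoStepArrhenius:
    """Per-temperature fits followed by log-linear regression on 1/T."""

    model: str
    k_ref: float
    e_a: float
    t_ref: float
    rates: dict  # temperature (K) -> fitted rate (1/time-constant scale)


@dataclass
class RehydrationTime:
    time_min: float
    saturated: bool


# ---------------------------------------------------------------------------
# model registry: parameterisation, initialisation, prediction
# ---------------------------------------------------------------------------

_LOG2 = math.log(2.0)
_LOG10 = math.log(10.0)


@dataclass(frozen=True)
class _ModelDef:
    names: tuple  # single-curve parameter names
    lo: tuple  # bounds in transformed (log) space
    hi: tuple
    rate_param: str  # the temperature-dependent parameter
    reciprocal_rate: bool  # True if rate_param is a time constant (1/rate)
    shared: tuple  # parameters shared across temperatures in the global fit
    response: str  # "rr" or "mr"


_MODELS = {
    "peleg": _ModelDef(("k1", "k2"), (-np.inf,) * 2, (np.inf,) * 2, "k1", True, ("k2",), "rr"),
    "weibull": _ModelDef(
        ("alpha", "beta"), (-np.inf, -np.inf), (np.inf, _LOG2), "alpha", True, ("beta",), "rr"
    ),
    "exponential": _ModelDef(
        ("k", "n"), (-np.inf, -np.inf), (np.inf, _LOG2), "k", False, ("n",), "rr"
    ),
    "first_order": _ModelDef(("h",), (-np.inf,), (np.inf,), "h", False, (), "rr"),
    "fick": _ModelDef(
        ("d_eff", "g"), (-np.inf, 1e-9), (np.inf, _LOG10), "d_eff", False, ("g",), "mr"
    ),
}

MODEL_NAMES = tuple(_MODELS)


def _predict(model: str, t_min, prm: dict, bounds: BoundaryMoistures,
             half_thickness: Optional[float], geometry: str):
    if model == "peleg":
        return peleg_rr(t_min, PelegParams(prm["k1"], prm["k2"]), bounds)
    if model == "weibull":
        return weibull_rr(t_min, WeibullParams(prm["alpha"], prm["beta"]))
    if model == "exponential":
        return exponential_rr(t_min, ExponentialParams(prm["k"], prm["n"]))
    if model == "first_order":
        return first_order_rr(t_min, FirstOrderParams(prm["h"]))
    if model == "fick":
        p = FickParams(
            d_eff=prm["d_eff"], g=prm["g"], half_thickness=half_thickness, geometry=geometry
        )
        return fick_mr(np.asarray(t_min, dtype=float) * 60.0, p)
    raise InvalidInputError(f"unknown model {model!r}; choose from {MODEL_NAMES}")


def _time_to_63(t, rr):
    """Interpolated time at which RR first reaches 1 - 1/e; used as a scale init."""
    target = 1.0 - math.exp(-1.0)
    rr = np.clip(rr, 0.0, None)
    above = np.nonzero(rr >= target)[0]
    if above.size == 0 or above[0] == 0:
        return max(float(t[-1]) / 2.0, float(t[1]))
    j = above[0]
    t0, t1, r0, r1 = t[j - 1], t[j], rr[j - 1], rr[j]
    if r1 == r0:
        return float(t1)
    return float(t0 + (target - r0) * (t1 - t0) / (r1 - r0))


def _initial_params(model: str, t, rr, bounds: BoundaryMoistures,
                    half_thickness: Optional[float]) -> dict:
    t63 = _time_to_63(t, rr)
    if model == "peleg":
        mask = rr > 1e-6
        if mask.sum() >= 2:
            # transform: t / (RR * span) = K1 + K2 t, linear in t
            u = t[mask] / (rr[mask] * bounds.span)
            k2, k1 = np.polyfit(t[mask], u, 1)
            if k1 > 0 and k2 > 0:
                return {"k1": float(k1), "k2": float(k2)}
        return {"k1": t63 / bounds.span, "k2": 1.0 / bounds.span}
    if model == "weibull":
        return {"alpha": t63, "beta": 1.0}
    if model == "exponential":
        return {"k": 1.0 / t63, "n": 1.0}
    if model == "first_order":
        return {"h": 1.0 / t63}
    if model == "fick":
        # late-time slope of log MR gives the leading-mode decay rate
        mr = 1.0 - rr
        mask = (mr > 1e-3) & (mr < 0.7) & (t > 0)
        if mask.sum() >= 2:
            slope = np.polyfit(t[mask] * 60.0, np.log(mr[mask]), 1)[0]
            d0 = max(-slope * half_thickness**2 / math.pi**2, 1e-16)
        else:
            d0 = half_thickness**2 / (math.pi**2 * t63 * 60.0)
        return {"d_eff": float(d0), "g": 8.0}
    raise InvalidInputError(f"unknown model {model!r}")


def _run_least_squares(residual, x0, lo, hi, n_restarts, seed):
    rng = np.random.default_rng(seed)
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    x0 = np.clip(x0, lo + 1e-9, hi - 1e-9)
    best = None
    for attempt in range(n_restarts + 1):
        start = x0 if attempt == 0 else np.clip(
            x0 + rng.normal(0.0, 0.5, size=x0.size), lo + 1e-9, hi - 1e-9
        )
        try:
            res = least_squares(residual, start, bounds=(lo, hi), method="trf",
                                xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
        if res.success and res.cost <= best.cost + 1e-30:
            best = res
    if best is None:
        raise FitFailureError("all optimisation attempts raised")
    if not best.success:
        raise FitFailureError(f"did not converge after {n_restarts + 1} starts", best=best)
    return best


def _asymptotic_ses(res, n_obs, n_params):
    """Delta-method SEs in raw space from a log/raw-space Jacobian."""
    dof = max(n_obs - n_params, 1)
    chi2 = 2.0 * res.cost / dof
    jtj = res.jac.T @ res.jac
    try:
        cov = chi2 * np.linalg.pinv(jtj)
        se_t = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se_t = np.full(n_params, np.nan)
    return se_t


# ---------------------------------------------------------------------------
# goodness of fit
# ---------------------------------------------------------------------------


def goodness_of_fit(observed, predicted, n_params: int):
    """(R^2, RMSE, chi^2) with R^2 = 1 - SSE/SST, RMSE = sqrt(SSE/N) and
    chi^2 = SSE/(N - p), the reduced form customary in drying studies."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise InvalidInputError("observed and predicted differ in length")
    n = observed.size
    if n <= n_params:
        raise InvalidInputError(f"need more than {n_params} observations, got {n}")
    sse = float(np.sum((observed - predicted) ** 2))
    sst = float(np.sum((observed - observed.mean()) ** 2))
    if sst == 0.0:
        raise DegenerateRangeError("observed response has zero variance; R^2 undefined")
    r2 = 1.0 - sse / sst
    rmse = math.sqrt(sse / n)
    chi2 = sse / (n - n_params)
    return r2, rmse, chi2


# ---------------------------------------------------------------------------
# single-curve fitting
# ---------------------------------------------------------------------------


def fit_single_curve(
    curve: RehydrationCurve,
    model: str,
    bounds: Optional[BoundaryMoistures] = None,
    half_thickness: Optional[float] = None,
    geometry: str = "slab",
    n_restarts: int = 5,
    seed: int = 0,
) -> KineticFit:
    """Nonlinear least squares of one kinetic model against one curve.

    The response is RR(t) computed from ``bounds`` (default: M_o and M_e from
    the first/last observed moisture), or MR(t) = 1 - RR for the Fickian
    model, which additionally needs the slab half-thickness / sphere radius
    ``half_thickness`` in metres.
    """
    if model not in _MODELS:
        raise InvalidInputError(f"unknown model {model!r}; choose from {MODEL_NAMES}")
    mdef = _MODELS[model]
    if model == "fick" and half_thickness is None:
        raise InvalidInputError("the Fickian model requires half_thickness (m)")
    if bounds is None:
        bounds = curve.default_bounds()
    t = curve.times
    rr_obs = (curve.moistures - bounds.m_o) / bounds.span
    if t.size < len(mdef.names) + 2:
        raise InvalidInputError(
            f"need at least {len(mdef.names) + 2} observations for {model}"
        )
    observed = 1.0 - rr_obs if mdef.response == "mr" else rr_obs

    init = _initial_params(model, t, rr_obs, bounds, half_thickness)
    x0 = np.log([init[name] for name in mdef.names])

    def residual(theta):
        prm = dict(zip(mdef.names, np.exp(theta)))
        try:
            pred = _predict(model, t, prm, bounds, half_thickness, geometry)
        except SeriesConvergenceError:
            return np.full(t.size, 1e6)
        return pred - observed

    res = _run_least_squares(residual, x0, mdef.lo, mdef.hi, n_restarts, seed)
    raw = np.exp(res.x)
    params = dict(zip(mdef.names, map(float, raw)))
    se_t = _asymptotic_ses(res, t.size, len(mdef.names))
    ses = dict(zip(mdef.names, map(float, raw * se_t)))  # d exp(u) = exp(u) du

    predicted = _predict(model, t, params, bounds, half_thickness, geometry)
    r2, rmse, chi2 = goodness_of_fit(observed, predicted, len(mdef.names))
    return KineticFit(
        model=model,
        params=params,
        standard_errors=ses,
        r_squared=r2,
        rmse=rmse,
        chi_squared=chi2,
        residuals=observed - predicted,
        predicted=predicted,
        observed=observed,
        response_scale=mdef.response,
        converged=True,
        n_restarts_used=0,
        curve_id=curve.sample_id,
    )


# ---------------------------------------------------------------------------
# global (single-step) Arrhenius fitting
# ---------------------------------------------------------------------------


def _rate_param_at(model: str, ref_value: float, e_a_kj: float, t_ref: float,
                   temperature: float) -> float:
    """Temperature-scaled value of the model's rate parameter.

    For time-constant parameters (Peleg K1, Weibull alpha) the Arrhenius law
    applies to their reciprocal, so the parameter itself shrinks with T.
    """
    sign = -1.0 if _MODELS[model].reciprocal_rate else 1.0
    ea_j = e_a_kj * 1000.0
    return ref_value * math.exp(sign * (ea_j / GAS_CONSTANT) * (1.0 / t_ref - 1.0 / temperature))


def fit_global_arrhenius(
    curves: Sequence[RehydrationCurve],
    model: str,
    t_ref: float = 353.15,
    half_thickness: Optional[float] = None,
    geometry: str = "slab",
    bounds: Optional[BoundaryMoistures] = None,
    n_restarts: int = 5,
    seed: int = 0,
) -> ArrheniusFit:
    """Single-step Arrhenius estimation across temperatures.

    The Arrhenius law is substituted for the model's temperature-dependent
    time constant and all observations from every curve are stacked into one
    least-squares problem, estimating simultaneously the constant at the
    reference temperature (``k_ref``; D_eff0 for the Fickian model), the
    activation energy E_a (kJ/mol) and any shared shape parameter
    (Weibull beta, Peleg K2, geometric factor G).
    """
    if model not in _MODELS:
        raise InvalidInputError(f"unknown model {model!r}; choose from {MODEL_NAMES}")
    mdef = _MODELS[model]
    curves = list(curves)
    temps = np.array([c.temperature for c in curves])
    if np.unique(temps).size < 2:
        raise InvalidInputError(
            "global Arrhenius fit needs >= 2 distinct temperatures; "
            "use fit_single_curve for a single curve"
        )
    methods = {c.drying_method for c in curves}
    if len(methods) > 1:
        raise InvalidInputError(f"curves mix drying methods {sorted(methods)}")
    if model == "fick" and half_thickness is None:
        raise InvalidInputError("the Fickian model requires half_thickness (m)")

    per_curve = []
    for c in curves:
        b = bounds if bounds is not None else c.default_bounds()
        rr = (c.moistures - b.m_o) / b.span
        obs = 1.0 - rr if mdef.response == "mr" else rr
        per_curve.append((c, b, rr, obs))

    # initial values: single fit at the temperature closest to t_ref
    c0, b0, rr0, _ = min(per_curve, key=lambda item: abs(item[0].temperature - t_ref))
    init = _initial_params(model, c0.times, rr0, b0, half_thickness)
    shared0 = [init[nm] for nm in mdef.shared]
    # theta = [log k_ref, e_a, log shared...]
    x0 = np.array([math.log(init[mdef.rate_param]), 10.0] + [math.log(v) for v in shared0])
    lo = np.array([-np.inf, -500.0] + [mdef.lo[mdef.names.index(nm)] for nm in mdef.shared])
    hi = np.array([np.inf, 500.0] + [mdef.hi[mdef.names.index(nm)] for nm in mdef.shared])

    def unpack(theta):
        k_ref = math.exp(theta[0])
        e_a = float(theta[1])
        shared = dict(zip(mdef.shared, np.exp(theta[2:])))
        return k_ref, e_a, shared

    def residual(theta):
        k_ref, e_a, shared = unpack(theta)
        out = []
        for c, b, rr, obs in per_curve:
            prm = dict(shared)
            prm[mdef.rate_param] = _rate_param_at(model, k_ref, e_a, t_ref, c.temperature)
            try:
                pred = _predict(model, c.times, prm, b, half_thickness, geometry)
            except SeriesConvergenceError:
                pred = np.full(c.times.size, 1e6)
            out.append(pred - obs)
        return np.concatenate(out)

    res = _run_least_squares(residual, x0, lo, hi, n_restarts, seed)
    k_ref, e_a, shared = unpack(res.x)
    n_obs = sum(c.times.size for c in curves)
    n_params = 2 + len(mdef.shared)
    se_t = _asymptotic_ses(res, n_obs, n_params)
    k_ref_se = k_ref * se_t[0]
    e_a_se = float(se_t[1])
    extras_se = {
        nm: float(shared[nm] * se_t[2 + i]) for i, nm in enumerate(mdef.shared)
    }

    all_obs = np.concatenate([obs for _, _, _, obs in per_curve])
    all_pred = all_obs + res.fun  # residual = pred - obs
    r2, rmse, chi2 = goodness_of_fit(all_obs, all_pred, n_params)
    return ArrheniusFit(
        model=model,
        k_ref=float(k_ref),
        k_ref_se=float(k_ref_se),
        e_a=e_a,
        e_a_se=e_a_se,
        t_ref=t_ref,
        extras={k: float(v) for k, v in shared.items()},
        extras_se=extras_se,
        r_squared=r2,
        rmse=rmse,
        chi_squared=chi2,
        n_obs=n_obs,
        temperatures=np.unique(temps),
        residuals=res.fun,
        converged=True,
    )


def fit_two_step_arrhenius(
    curves: Sequence[RehydrationCurve],
    model: str,
    t_ref: float = 353.15,
    half_thickness: Optional[float] = None,
    geometry: str = "slab",
) -> TwoStepArrhenius:
    """Classical two-step estimate: fit each temperature separately, then
    regress the log rate on (1/T_ref - 1/T).  Reported ``k_ref`` is on the
    same scale as the single-step fit (time constant for Peleg/Weibull)."""
    mdef = _MODELS[model]
    rates = {}
    for c in curves:
        fit = fit_single_curve(c, model, half_thickness=half_thickness, geometry=geometry)
        value = fit.params[mdef.rate_param]
        rate = 1.0 / value if mdef.reciprocal_rate else value
        rates[c.temperature] = rate
    temps = np.array(sorted(rates))
    if temps.size < 2:
        raise InvalidInputError("two-step Arrhenius needs >= 2 temperatures")
    x = 1.0 / t_ref - 1.0 / temps
    y = np.log([rates[T] for T in temps])
    slope, intercept = np.polyfit(x, y, 1)
    e_a = slope * GAS_CONSTANT / 1000.0  # kJ/mol
    k_ref_rate = math.exp(intercept)
    k_ref = 1.0 / k_ref_rate if mdef.reciprocal_rate else k_ref_rate
    return TwoStepArrhenius(model=model, k_ref=float(k_ref), e_a=float(e_a),
                            t_ref=t_ref, rates=rates)


# ---------------------------------------------------------------------------
# saturation time and model comparison
# ---------------------------------------------------------------------------


def estimate_rehydration_time(curve: RehydrationCurve, weight_tol: float = 0.05) -> RehydrationTime:
    """Time at which the weight gain between consecutive readings becomes and
    stays insignificant (<= ``weight_tol`` g).

    If every consecutive difference is already within tolerance the curve is
    saturated from the start (0 min).  Otherwise the saturation time is the
    first reading whose increment from the previous one — and every later
    increment — is within tolerance.  If the last increment still exceeds the
    tolerance, the last time is returned flagged as not saturated.
    """
    diffs = np.abs(np.diff(curve.weights))
    if diffs.size == 0:
        return RehydrationTime(time_min=float(curve.times[0]), saturated=True)
    if np.all(diffs <= weight_tol):
        return RehydrationTime(time_min=float(curve.times[0]), saturated=True)
    if diffs[-1] > weight_tol:
        return RehydrationTime(time_min=float(curve.times[-1]), saturated=False)
    exceed = np.nonzero(diffs > weight_tol)[0]
    k = exceed[-1] + 1  # first diff index after which all diffs are within tol
    return RehydrationTime(time_min=float(curve.times[k + 1]), saturated=True)


def _runs_test(residuals: np.ndarray):
    """Wald-Wolfowitz runs test on residual signs (z, p)."""
    if np.all(np.abs(residuals) < 1e-12):
        return 0.0, 1.0
    from statsmodels.sandbox.stats.runs import runstest_1samp

    z, p = runstest_1samp(residuals, cutoff=0, correction=False)
    if not np.isfinite(z):
        return 0.0, 1.0
    return float(z), float(p)


def compare_models(fits: Sequence[KineticFit]) -> pd.DataFrame:
    """Rank fits of different models to the same data.

    Ranking is by R^2 (descending), then RMSE and chi^2 (ascending); a runs
    test on the residual signs summarises the randomness of the error
    distribution (|z| near 0 means random scatter around the fit).
    """
    fits = list(fits)
    if not fits:
        raise InvalidInputError("no fits to compare")
    canon = [f.observed if f.response_scale == "rr" else 1.0 - f.observed for f in fits]
    for arr in canon[1:]:
        if arr.shape != canon[0].shape or not np.allclose(arr, canon[0]):
            raise InvalidInputError("fits were not computed on identical data")
    rows = []
    for f in fits:
        z, p = _runs_test(f.residuals)
        rows.append(
            {
                "model": f.model,
                "r_squared": f.r_squared,
                "rmse": f.rmse,
                "chi_squared": f.chi_squared,
                "runs_z": z,
                "runs_p": p,
            }
        )
    table = pd.DataFrame(rows)
    order = table.sort_values(
        by=["r_squared", "rmse", "chi_squared"], ascending=[False, True, True], kind="mergesort"
    ).index
    table["rank"] = 0
    table.loc[order, "rank"] = np.arange(1, len(fits) + 1)
    return table.sort_values("rank").reset_index(drop=True)
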