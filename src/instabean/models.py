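"""Rehydration kinetics model equations.

Water uptake by a dried particulate food (here: pre-cooked dried beans) is
tracked as the rehydration ratio

    RR(t) = (M_t - M_o) / (M_e - M_o),        MR(t) = 1 - RR(t),

where ``M_o`` and ``M_e`` are the initial and equilibrium moisture contents
(percent dry basis) and ``M_t`` the moisture at time ``t``.  Four empirical
models (Peleg, Weibull, exponential, first-order) and the series solution of
Fick's second law for an infinite slab or a sphere are provided, together
with the Arrhenius reparameterisation used to pool curves measured at
several water-bath temperatures.

All moistures are percent dry basis (g water / 100 g dry solids),
temperatures are kelvin, times are minutes except for the Fickian model
whose time argument is seconds (diffusivities are m^2/s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "GAS_CONSTANT",
    "InvalidInputError",
    "DegenerateRangeError",
    "SeriesConvergenceError",
    "BoundaryMoistures",
    "PelegParams",
    "WeibullParams",
    "ExponentialParams",
    "FirstOrderParams",
    "FickParams",
    "ArrheniusParams",
    "moisture_db_from_weight",
    "weight_from_moisture_db",
    "db_from_wb",
    "wb_from_db",
    "rehydration_ratio",
    "moisture_ratio",
    "peleg_rr",
    "weibull_rr",
    "exponential_rr",
    "first_order_rr",
    "fick_mr",
    "arrhenius_k",
]

#: Universal gas constant, J mol^-1 K^-1.
GAS_CONSTANT = 8.314


class InvalidInputError(ValueError):
    """A physically impossible input (negative rate, weight below dry mass, ...)."""


class DegenerateRangeError(InvalidInputError):
    """The moisture range M_e - M_o is zero, so ratios are undefined."""


class SeriesConvergenceError(RuntimeError):
    """The Fickian series did not converge within the term budget."""

    def __init__(self, message: str, *, n_terms: int, last_term: float):
        super().__init__(message)
        self.n_terms = n_terms
        self.last_term = last_term


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BoundaryMoistures:
    """Initial (M_o), equilibrium (M_e) and optional cooked-reference (M_c)
    moisture contents, percent dry basis."""

    m_o: float
    m_e: float
    m_c: Optional[float] = None

    def __post_init__(self):
        if not (self.m_e > self.m_o >= 0.0):
            raise InvalidInputError(
                f"require M_e > M_o >= 0, got M_o={self.m_o}, M_e={self.m_e}"
            )

    @property
    def span(self) -> float:
        """M_e - M_o, the saturation moisture gain (%db)."""
        return self.m_e - self.m_o


@dataclass(frozen=True)
class PelegParams:
    """Peleg sorption model.  ``k1`` (min·(%db)^-1) is the rate constant
    (reciprocal of the initial uptake rate); ``k2`` ((%db)^-1) the capacity
    constant, with the saturation gain M_e - M_o = 1/k2."""

    k1: float
    k2: float

    def __post_init__(self):
        if self.k1 <= 0 or self.k2 <= 0:
            raise InvalidInputError(f"Peleg constants must be > 0, got {self}")


@dataclass(frozen=True)
class WeibullParams:
    """Weibull (stretched-exponential) uptake: ``alpha`` (min) is the time to
    63% completion; ``beta`` the dimensionless shape factor."""

    alpha: float
    beta: float

    def __post_init__(self):
        if self.alpha <= 0:
            raise InvalidInputError(f"alpha must be > 0, got {self.alpha}")
        if not (0.0 < self.beta <= 2.0):
            raise InvalidInputError(f"beta must be in (0, 2], got {self.beta}")


@dataclass(frozen=True)
class ExponentialParams:
    """Page-type exponential model RR = 1 - exp(-K t^n)."""

    k: float
    n: float

    def __post_init__(self):
        if self.k <= 0 or self.n <= 0:
            raise InvalidInputError(f"exponential constants must be > 0, got {self}")


@dataclass(frozen=True)
class FirstOrderParams:
    """First-order uptake RR = 1 - exp(-H t), rate constant H (min^-1)."""

    h: float

    def __post_init__(self):
        if self.h <= 0:
            raise InvalidInputError(f"H must be > 0, got {self.h}")


@dataclass(frozen=True)
class FickParams:
    """Series solution of Fick's second law with a free geometric factor.

    ``d_eff``
        effective moisture diffusivity, m^2/s.
    ``g``
        geometric factor replacing the theoretical pre-series constant
        (8 for an infinite slab, 6 for a sphere); estimated freely because a
        bean is neither an infinite slab nor a perfect sphere.
    ``half_thickness``
        slab half-thickness, or sphere radius, in metres.
    """

    d_eff: float
    g: float
    half_thickness: float
    geometry: str = "slab"
    n_terms_max: int = 500
    term_tol: float = 1e-12

    def __post_init__(self):
        if self.d_eff <= 0 or self.g <= 0 or self.half_thickness <= 0:
            raise InvalidInputError(f"D_eff, G and L must be > 0, got {self}")
        if self.geometry not in ("slab", "sphere"):
            raise InvalidInputError(f"geometry must be 'slab' or 'sphere', got {self.geometry!r}")


@dataclass(frozen=True)
class ArrheniusParams:
    """Arrhenius temperature dependence about a reference temperature.

    ``k_ref`` carries the units of the wrapped rate constant; ``e_a`` is in
    kJ/mol (converted to J/mol internally); ``t_ref`` defaults to 353.15 K
    (80 degC, the middle of the 70-100 degC rehydration range).
    """

    k_ref: float
    e_a: float
    t_ref: float = 353.15

    def __post_init__(self):
        if self.k_ref <= 0:
            raise InvalidInputError(f"k_ref must be > 0, got {self.k_ref}")
        if self.t_ref <= 0:
            raise InvalidInputError(f"T_ref must be > 0 K, got {self.t_ref}")


# ---------------------------------------------------------------------------
# moisture bookkeeping
# ---------------------------------------------------------------------------


def moisture_db_from_weight(weight, dry_mass):
    """Moisture content (%db) from sample weight and dry mass, both grams."""
    weight = np.asarray(weight, dtype=float)
    if dry_mass <= 0:
        raise InvalidInputError(f"dry_mass must be > 0, got {dry_mass}")
    if np.any(weight < dry_mass):
        raise InvalidInputError("weight below dry mass is not physical")
    out = 100.0 * (weight - dry_mass) / dry_mass
    return out if out.ndim else float(out)


def weight_from_moisture_db(moisture_db, dry_mass):
    """Inverse of :func:`moisture_db_from_weight`."""
    moisture_db = np.asarray(moisture_db, dtype=float)
    if dry_mass <= 0:
        raise InvalidInputError(f"dry_mass must be > 0, got {dry_mass}")
    if np.any(moisture_db < 0):
        raise InvalidInputError("negative moisture content")
    out = dry_mass * (1.0 + moisture_db / 100.0)
    return out if out.ndim else float(out)


def db_from_wb(wb):
    """Wet-basis (%) to dry-basis (%) moisture: db = 100 wb / (100 - wb)."""
    wb = np.asarray(wb, dtype=float)
    if np.any((wb < 0) | (wb >= 100)):
        raise InvalidInputError("wet-basis moisture must lie in [0, 100)")
    out = 100.0 * wb / (100.0 - wb)
    return out if out.ndim else float(out)


def wb_from_db(db):
    """Dry-basis (%) to wet-basis (%) moisture: wb = 100 db / (100 + db)."""
    db = np.asarray(db, dtype=float)
    if np.any(db < 0):
        raise InvalidInputError("dry-basis moisture must be >= 0")
    out = 100.0 * db / (100.0 + db)
    return out if out.ndim else float(out)


def rehydration_ratio(m_t, bounds: BoundaryMoistures, as_printed: bool = False):
    """Normalised rehydration progress RR = (M_t - M_o)/(M_e - M_o).

    ``as_printed=True`` returns (M_t - M_e)/(M_e - M_o) instead — an audit
    variant of the ratio as it is sometimes typeset, which equals RR - 1 and
    gives RR(0) = -1; the default orientation is the one consistent with the
    kinetic models (RR(0) = 0, RR -> 1 at saturation).
    """
    m_t = np.asarray(m_t, dtype=float)
    span = bounds.span
    if span == 0:  # unreachable through BoundaryMoistures, kept for raw use
        raise DegenerateRangeError("M_e equals M_o")
    ref = bounds.m_e if as_printed else bounds.m_o
    out = (m_t - ref) / span
    return out if out.ndim else float(out)


def moisture_ratio(m_t, bounds: BoundaryMoistures):
    """MR = 1 - RR."""
    return 1.0 - rehydration_ratio(m_t, bounds)


# ---------------------------------------------------------------------------
# empirical models
# ---------------------------------------------------------------------------


def peleg_rr(t, p: PelegParams, bounds: BoundaryMoistures):
    """Peleg model RR(t) = (1/(M_e - M_o)) * t / (K1 + K2 t).

    Saturates at 1/(K2 (M_e - M_o)); when M_e - M_o = 1/K2 the asymptote is
    exactly 1.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidInputError("negative time")
    with np.errstate(invalid="ignore"):
        out = np.where(t > 0, t / (p.k1 + p.k2 * t), 0.0) / bounds.span
    return out if out.ndim else float(out)


def weibull_rr(t, p: WeibullParams):
    """Weibull model RR(t) = 1 - exp(-(t/alpha)^beta); RR(alpha) = 1 - 1/e."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidInputError("negative time")
    out = -np.expm1(-((t / p.alpha) ** p.beta))
    return out if out.ndim else float(out)


def exponential_rr(t, p: ExponentialParams):
    """Exponential (Page) model RR(t) = 1 - exp(-K t^n)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidInputError("negative time")
    out = -np.expm1(-p.k * t**p.n)
    return out if out.ndim else float(out)


def first_order_rr(t, p: FirstOrderParams):
    """First-order model RR(t) = 1 - exp(-H t) (exponential model with n=1)."""
    return exponential_rr(t, ExponentialParams(k=p.h, n=1.0))


# ---------------------------------------------------------------------------
# Fickian diffusion
# ---------------------------------------------------------------------------

_SLAB_SERIES_SUM = math.pi**2 / 8.0  # sum (2i-1)^-2
_SPHERE_SERIES_SUM = math.pi**2 / 6.0  # sum n^-2


def fick_mr(t, p: FickParams):
    """Moisture ratio from the series solution of Fick's second law.

    slab:   MR = (G/pi^2) sum_{i>=1} (2i-1)^-2 exp(-(2i-1)^2 pi^2 Fo)
    sphere: MR = (G/pi^2) sum_{n>=1} n^-2      exp(-n^2 pi^2 Fo)

    with Fourier number Fo = D_eff t / L^2 and ``t`` in seconds.  At t = 0
    the closed-form partial sums (pi^2/8 and pi^2/6) are used, so MR(0) = G/8
    for a slab and G/6 for a sphere — hence MR(0) = 1 exactly at the
    theoretical geometric constants.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidInputError("negative time")
    fo = p.d_eff * t / p.half_thickness**2
    scalar = fo.ndim == 0
    fo = np.atleast_1d(fo)
    out = np.empty_like(fo)

    zero = fo == 0.0
    base = _SLAB_SERIES_SUM if p.geometry == "slab" else _SPHERE_SERIES_SUM
    out[zero] = (p.g / math.pi**2) * base

    pos = ~zero
    if np.any(pos):
        fo_pos = fo[pos]
        acc = np.zeros_like(fo_pos)
        converged = False
        last_max = np.inf
        for i in range(1, p.n_terms_max + 1):
            m = 2 * i - 1 if p.geometry == "slab" else i
            term = np.exp(-(m**2) * math.pi**2 * fo_pos) / m**2
            acc += term
            last_max = float(term.max())
            if last_max < p.term_tol:
                converged = True
                break
        if not converged:
            raise SeriesConvergenceError(
                f"Fickian series not converged after {p.n_terms_max} terms "
                f"(largest last term {last_max:.3e} >= tol {p.term_tol:.1e}); "
                "increase n_terms_max or term_tol",
                n_terms=p.n_terms_max,
                last_term=last_max,
            )
        out[pos] = (p.g / math.pi**2) * acc

    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# Arrhenius reparameterisation
# ---------------------------------------------------------------------------


def arrhenius_k(temperature, a: ArrheniusParams):
    """Rate constant at ``temperature`` (K):

        k(T) = k_ref * exp((E_a/R) (1/T_ref - 1/T)),

    with E_a supplied in kJ/mol.  k(T_ref) = k_ref and log k is linear in
    1/T with slope -E_a/R.
    """
    temperature = np.asarray(temperature, dtype=float)
    if np.any(temperature <= 0):
        raise InvalidInputError("temperature must be > 0 K")
    ea_j = a.e_a * 1000.0
    out = a.k_ref * np.exp((ea_j / GAS_CONSTANT) * (1.0 / a.t_ref - 1.0 / temperature))
    return out if out.ndim else float(out)
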