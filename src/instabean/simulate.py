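"""Synthetic data with the statistical structure the analysis assumes.

Three generators:

* :func:`gen_rehydration_dataset` — saturating monotone rehydration curves
  from a chosen kinetic model, one per water temperature, with Arrhenius
  temperature dependence of the time constant and additive Gaussian balance
  noise on the moisture content (truncated so weights never drop below the
  dry mass);
* :func:`gen_replicates` — Gaussian replicate draws around group means, used
  for colour, DSC and hardness tables;
* :func:`gen_peak_table` — log-normal GC-MS peak areas with class-specific
  log-mean shifts planted on designated discriminant variables.

Every generator is driven by a single integer seed; sub-streams are spawned
deterministically from it, so equal seeds give byte-identical output.

The module also carries the default study conditions (drying methods AD/VD/
FD vs a freshly cooked control; rehydration at 70-100 degC; reference
temperature 80 degC; six GC-MS repetitions per treatment) and the reported
group means used to parameterise quality-table simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .fitting import RehydrationCurve
from .models import (
    ArrheniusParams,
    BoundaryMoistures,
    ExponentialParams,
    FickParams,
    FirstOrderParams,
    InvalidInputError,
    PelegParams,
    WeibullParams,
    arrhenius_k,
    exponential_rr,
    fick_mr,
    first_order_rr,
    peleg_rr,
    weibull_rr,
    weight_from_moisture_db,
)

__all__ = [
    "RehydrationSimSpec",
    "PeakTableSimSpec",
    "gen_rehydration_dataset",
    "gen_replicates",
    "gen_peak_table",
    "STUDY_TEMPERATURES_K",
    "T_REF_K",
    "COLOR_MEANS",
    "COLOR_SDS",
    "DELTA_E_REFERENCE_CLASS",
    "THERMAL_MEANS",
    "THERMAL_SDS",
    "HARDNESS_MEANS",
    "HARDNESS_SDS",
    "KINETIC_TRUTHS",
]

# --------------------------------------------------------------------------
# default study conditions
# --------------------------------------------------------------------------

#: Rehydration water-bath temperatures, 70/80/90/100 degC in kelvin.
STUDY_TEMPERATURES_K = (343.15, 353.15, 363.15, 373.15)

#: Arrhenius reference temperature (80 degC).
T_REF_K = 353.15

#: CIELAB group means for freshly cooked (control) and dried beans.
COLOR_MEANS = {
    "cooked": {"l": 24.42, "a": 18.31, "b": 8.65},
    "AD": {"l": 20.72, "a": 8.76, "b": 2.73},
    "VD": {"l": 19.24, "a": 9.10, "b": 2.70},
    "FD": {"l": 31.32, "a": 12.0, "b": 4.50},
}
COLOR_SDS = {
    "cooked": {"l": 0.89, "a": 0.53, "b": 0.74},
    "AD": {"l": 0.93, "a": 0.45, "b": 0.24},
    "VD": {"l": 0.58, "a": 0.13, "b": 0.02},
    "FD": {"l": 1.55, "a": 0.83, "b": 0.47},
}
DELTA_E_REFERENCE_CLASS = "cooked"

#: DSC peak temperature (degC) and enthalpy pairs; DR% follows from the
#: enthalpy ratio (native gelatinisation enthalpy taken as 3.0 J/g).
THERMAL_MEANS = {
    "cooked": {"t_p": 79.74, "dh_g": 3.0, "dh_r": 0.0},
    "AD": {"t_p": 57.57, "dh_g": 3.0, "dh_r": 1.344},
    "VD": {"t_p": 64.76, "dh_g": 3.0, "dh_r": 0.867},
    "FD": {"t_p": 58.33, "dh_g": 3.0, "dh_r": 0.811},
}
THERMAL_SDS = {
    "cooked": {"t_p": 0.06, "dh_g": 0.1, "dh_r": 0.0},
    "AD": {"t_p": 0.71, "dh_g": 0.1, "dh_r": 0.05},
    "VD": {"t_p": 0.74, "dh_g": 0.1, "dh_r": 0.04},
    "FD": {"t_p": 0.54, "dh_g": 0.1, "dh_r": 0.02},
}

#: Hardness (maximum compression force, N).
HARDNESS_MEANS = {"cooked": 64.82, "AD": 62.90, "VD": 70.50, "FD": 48.21}
HARDNESS_SDS = {"cooked": 11.40, "AD": 12.86, "VD": 13.50, "FD": 9.74}

#: Generative kinetic truths per drying method (Weibull parameterisation):
#: alpha at 80 degC in minutes, shape beta (the study's range is 0.487-0.724)
#: and activation energy kJ/mol.  FD beans rehydrate roughly ten times
#: faster than AD/VD and show the weakest temperature dependence.
#: Equilibrium moistures (m_e, %db) follow from the rehydration yields
#: Y = W_e/W_0 of 2.28-2.56 at an initial moisture of 11 %db:
#: m_e = 100 (Y (1 + m_o/100) - 1).
KINETIC_TRUTHS = {
    "VD": {"alpha_ref": 4.52, "beta": 0.62, "e_a": 14.37, "m_e": 153.1},
    "AD": {"alpha_ref": 4.77, "beta": 0.60, "e_a": 6.90, "m_e": 155.3},
    "FD": {"alpha_ref": 0.61, "beta": 0.65, "e_a": 2.86, "m_e": 184.2},
}


# --------------------------------------------------------------------------
# rehydration curves
# --------------------------------------------------------------------------

_MODEL_PARAM_KEYS = {
    "peleg": ("k1_ref", "k2"),
    "weibull": ("alpha_ref", "beta"),
    "exponential": ("k_ref", "n"),
    "first_order": ("h_ref",),
    "fick_slab": ("d_ref", "g", "half_thickness"),
    "fick_sphere": ("d_ref", "g", "half_thickness"),
}

#: models whose Arrhenius-scaled parameter is a time constant (reciprocal rate)
_RECIPROCAL = {"peleg", "weibull"}


@dataclass(frozen=True)
class RehydrationSimSpec:
    """Generative recipe for one drying method's rehydration curves.

    ``true_params`` holds the model's parameters with the rate/time-constant
    given at ``t_ref``; ``e_a`` (kJ/mol) scales it to each temperature.
    ``noise_sd`` is the additive balance noise on moisture, %db.
    """

    model_name: str
    true_params: dict
    e_a: float
    temperatures: Tuple[float, ...] = STUDY_TEMPERATURES_K
    t_ref: float = T_REF_K
    # weight readings clustered early (where uptake is fast) then sparser,
    # resolving time constants from fractions of a minute up to hours
    time_grid: Tuple[float, ...] = (0.0,) + tuple(
        float(x) for x in np.geomspace(0.25, 360.0, 40)
    )
    m_o: float = 11.0
    m_e: float = 150.0
    noise_sd: float = 1.0
    drying_method: str = "VD"
    dry_mass: float = 9.0
    seed: int = 0

    def __post_init__(self):
        if self.model_name not in _MODEL_PARAM_KEYS:
            raise InvalidInputError(
                f"unknown model {self.model_name!r}; choose from {sorted(_MODEL_PARAM_KEYS)}"
            )
        missing = [k for k in _MODEL_PARAM_KEYS[self.model_name] if k not in self.true_params]
        if missing:
            raise InvalidInputError(f"{self.model_name} needs parameters {missing}")
        if any(v <= 0 for v in self.true_params.values()):
            raise InvalidInputError("non-physical (non-positive) model parameter")
        if any(T <= 273.15 for T in self.temperatures):
            raise InvalidInputError("temperatures must exceed 273.15 K")
        t = np.asarray(self.time_grid, dtype=float)
        if t[0] != 0.0 or np.any(np.diff(t) <= 0):
            raise InvalidInputError("time_grid must strictly increase from 0")
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be >= 0")
        if not self.m_e > self.m_o:
            raise InvalidInputError("M_e must exceed M_o")


def _true_rr(spec: RehydrationSimSpec, t: np.ndarray, temperature: float) -> np.ndarray:
    p = spec.true_params
    name = spec.model_name
    base = _MODEL_PARAM_KEYS[name][0]
    scaled = arrhenius_k(
        temperature,
        ArrheniusParams(k_ref=p[base], e_a=-spec.e_a if name in _RECIPROCAL else spec.e_a,
                        t_ref=spec.t_ref),
    )
    bounds = BoundaryMoistures(m_o=spec.m_o, m_e=spec.m_e)
    if name == "peleg":
        return peleg_rr(t, PelegParams(k1=scaled, k2=p["k2"]), bounds)
    if name == "weibull":
        return weibull_rr(t, WeibullParams(alpha=scaled, beta=p["beta"]))
    if name == "exponential":
        return exponential_rr(t, ExponentialParams(k=scaled, n=p["n"]))
    if name == "first_order":
        return first_order_rr(t, FirstOrderParams(h=scaled))
    geometry = "slab" if name == "fick_slab" else "sphere"
    fick = FickParams(d_eff=scaled, g=p["g"], half_thickness=p["half_thickness"],
                      geometry=geometry)
    return 1.0 - fick_mr(t * 60.0, fick)


def gen_rehydration_dataset(spec: RehydrationSimSpec) -> list:
    """One :class:`RehydrationCurve` per temperature in ``spec``.

    With ``noise_sd = 0`` the curves reproduce the generative model exactly;
    otherwise i.i.d. Gaussian noise (sd ``noise_sd`` %db) is added to the
    moisture, truncated at zero so weights never fall below the dry mass.
    """
    t = np.asarray(spec.time_grid, dtype=float)
    root = np.random.default_rng(spec.seed)
    streams = root.spawn(len(spec.temperatures))
    curves = []
    for temperature, rng in zip(spec.temperatures, streams):
        rr = _true_rr(spec, t, temperature)
        moisture = spec.m_o + rr * (spec.m_e - spec.m_o)
        if spec.noise_sd > 0:
            moisture = moisture + rng.normal(0.0, spec.noise_sd, size=t.size)
            moisture = np.clip(moisture, 0.0, None)
        curves.append(
            RehydrationCurve(
                sample_id=f"{spec.drying_method}_{temperature - 273.15:.0f}C",
                drying_method=spec.drying_method,
                temperature=float(temperature),
                times=t.copy(),
                dry_mass=spec.dry_mass,
                moistures=moisture,
            )
        )
    return curves


# --------------------------------------------------------------------------
# replicate tables (colour / DSC / hardness)
# --------------------------------------------------------------------------


def gen_replicates(
    means: Dict[str, Dict[str, float]],
    sds: Dict[str, Dict[str, float]],
    n: int,
    seed: int = 0,
    clip_nonnegative: Sequence[str] = (),
) -> pd.DataFrame:
    """Gaussian replicate draws around per-group metric means.

    ``means[group][metric]`` / ``sds[group][metric]``; returns a tidy frame
    with columns ``group``, ``replicate`` and one column per metric.
    Metrics listed in ``clip_nonnegative`` are truncated at zero.
    """
    if n < 2:
        raise InvalidInputError("need n >= 2 replicates (downstream tests need variance)")
    root = np.random.default_rng(seed)
    rows = []
    for group, stream in zip(means, root.spawn(len(means))):
        metric_means = means[group]
        metric_sds = sds[group]
        if any(metric_sds[m] < 0 for m in metric_means):
            raise InvalidInputError("sds must be >= 0")
        draws = {
            m: metric_means[m] + stream.normal(0.0, metric_sds[m], size=n)
            for m in metric_means
        }
        for m in clip_nonnegative:
            if m in draws:
                draws[m] = np.clip(draws[m], 0.0, None)
        for i in range(n):
            rows.append({"group": group, "replicate": i + 1,
                         **{m: float(draws[m][i]) for m in metric_means}})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# peak tables
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PeakTableSimSpec:
    """Generative recipe for an aligned GC-MS peak table.

    ``discriminant_sets[class]`` lists the variable indices whose log-mean is
    shifted upward by ``effect_size`` log-noise standard deviations in that
    class.  Areas are log-normal (multiplicative noise, coefficient of
    variation ``noise_cv``).
    """

    # discriminant compounds in dried-vs-cooked fingerprints are often formed
    # or lost outright, i.e. very large fold-changes; 6 log-sd reproduces the
    # near-unity VID magnitudes such compounds show
    n_classes: int = 4
    n_samples_per_class: int = 6
    n_variables: int = 60
    discriminant_sets: Optional[Dict[str, Tuple[int, ...]]] = None
    effect_size: float = 6.0
    noise_cv: float = 0.3
    class_names: Optional[Tuple[str, ...]] = None
    rt_span: Tuple[float, float] = (6.0, 40.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise InvalidInputError("need >= 2 classes")
        if self.n_samples_per_class < 3:
            raise InvalidInputError("need >= 3 samples per class")
        if self.effect_size < 0:
            raise InvalidInputError("effect_size must be >= 0")
        if not 0 < self.noise_cv < 2:
            raise InvalidInputError("noise_cv must lie in (0, 2)")
        if self.class_names is not None and len(self.class_names) != self.n_classes:
            raise InvalidInputError("class_names length mismatch")
        if self.discriminant_sets is not None:
            for cls, idx in self.discriminant_sets.items():
                if any(not 0 <= i < self.n_variables for i in idx):
                    raise InvalidInputError(
                        f"discriminant indices for {cls!r} outside [0, {self.n_variables})"
                    )

    def resolved_classes(self) -> Tuple[str, ...]:
        if self.class_names is not None:
            return self.class_names
        base = ("cooked", "AD", "VD", "FD")
        if self.n_classes <= 4:
            return base[: self.n_classes]
        return base + tuple(f"class{i}" for i in range(4, self.n_classes))

    def default_discriminants(self) -> Dict[str, Tuple[int, ...]]:
        """Disjoint blocks of 5 variables per class, from the front."""
        classes = self.resolved_classes()
        block = min(5, self.n_variables // self.n_classes)
        return {
            cls: tuple(range(i * block, (i + 1) * block))
            for i, cls in enumerate(classes)
        }


def gen_peak_table(spec: PeakTableSimSpec, internal_standard: bool = False):
    """Log-normal peak table with planted class-specific discriminants.

    Per-variable baseline log-areas are drawn once; samples of class c get
    ``effect_size * sigma_log`` added to the log-mean of c's discriminant
    variables, where sigma_log is the log-scale noise sd implied by
    ``noise_cv``.  With ``internal_standard=True`` an IS column of constant
    area is appended (for exercising normalisation).
    Returns a :class:`~instabean.chemometrics.PeakTable`.
    """
    from .chemometrics import PeakTable

    rng = np.random.default_rng(spec.seed)
    classes = spec.resolved_classes()
    disc = spec.discriminant_sets
    if disc is None:
        disc = spec.default_discriminants()
    sigma_log = float(np.sqrt(np.log1p(spec.noise_cv**2)))

    base_log = rng.normal(np.log(1e6), 1.0, size=spec.n_variables)
    n_total = spec.n_classes * spec.n_samples_per_class
    log_areas = np.empty((n_total, spec.n_variables))
    labels = []
    sample_ids = []
    row = 0
    for cls in classes:
        shift = np.zeros(spec.n_variables)
        for i in disc.get(cls, ()):
            shift[i] = spec.effect_size * sigma_log
        for rep in range(spec.n_samples_per_class):
            noise = rng.normal(0.0, sigma_log, size=spec.n_variables)
            log_areas[row] = base_log + shift + noise
            labels.append(cls)
            sample_ids.append(f"{cls}_{rep + 1}")
            row += 1

    var_ids = [f"V{i + 1:03d}" for i in range(spec.n_variables)]
    areas = pd.DataFrame(np.exp(log_areas), index=sample_ids, columns=var_ids)
    rts = dict(
        zip(var_ids, np.sort(rng.uniform(spec.rt_span[0], spec.rt_span[1], spec.n_variables)))
    )
    is_col = None
    if internal_standard:
        is_col = "IS_2-heptanone"
        areas[is_col] = np.exp(rng.normal(np.log(5e6), 0.02, size=n_total))
        rts[is_col] = sum(spec.rt_span) / 2.0
    return PeakTable(
        areas=areas,
        classes=pd.Series(labels, index=sample_ids),
        retention_times=rts,
        internal_standard=is_col,
    )
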