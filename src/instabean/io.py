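"""CSV schemas, pipeline configuration and the pipeline driver.

File conventions: tidy long-format CSV everywhere; temperatures in degC and
thicknesses in mm only at this boundary (kelvin / metres internally); times
in minutes; diffusivities reported in m^2/s.

:func:`run_pipeline` ties the stages together — simulate (or read)
rehydration curves, fit the kinetic models globally across temperatures,
derive the quality table, run the volatile chemometrics — and writes three
report tables, a JSON summary and a log.  Outputs regenerate bit-identically
from (inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import chemometrics, fitting, quality, simulate
from .chemometrics import AlkaneLadder, PeakTable
from .fitting import RehydrationCurve
from .models import InvalidInputError

__all__ = [
    "PipelineConfig",
    "read_rehydration_csv",
    "write_rehydration_csv",
    "read_peak_table_csv",
    "write_peak_table_csv",
    "run_pipeline",
    "simulate_default_curves",
    "DEFAULT_ALKANE_LADDER",
]

logger = logging.getLogger("instabean")

REHYDRATION_COLUMNS = ("sample_id", "method", "temperature_C", "time_min",
                       "weight_g", "dry_mass_g")

#: C8-C22 n-alkane ladder with evenly spread retention times (min) spanning
#: a typical temperature-programmed polar-column run.
DEFAULT_ALKANE_LADDER = AlkaneLadder(
    carbon_numbers=tuple(range(8, 23)),
    retention_times=tuple(float(x) for x in np.linspace(5.0, 41.0, 15)),
)


@dataclass
class PipelineConfig:
    """Everything the pipeline needs; °C/mm at this boundary only."""

    seed: int = 0
    output_dir: str = "instabean_out"
    models: Tuple[str, ...] = ("peleg", "weibull", "first_order", "fick")
    temperatures_c: Tuple[float, ...] = (70.0, 80.0, 90.0, 100.0)
    t_ref_c: float = 80.0
    weight_tol_g: float = 0.05
    vid_threshold: float = 0.8
    n_lv: Optional[int] = 3
    noise_sd: float = 1.0
    n_replicates: int = 6
    m_c: float = 161.8  # cooked-reference moisture, %db
    half_thickness_mm: float = 5.0
    geometry: str = "slab"
    rehydration_csv: Optional[str] = None
    peak_table_csv: Optional[str] = None

    def __post_init__(self):
        if self.weight_tol_g <= 0 or self.vid_threshold <= 0:
            raise InvalidInputError("thresholds must be positive")
        for path in (self.rehydration_csv, self.peak_table_csv):
            if path is not None and not Path(path).exists():
                raise InvalidInputError(f"input file not found: {path}")

    @property
    def t_ref_k(self) -> float:
        return self.t_ref_c + 273.15

    @property
    def temperatures_k(self) -> Tuple[float, ...]:
        return tuple(t + 273.15 for t in self.temperatures_c)

    @property
    def half_thickness_m(self) -> float:
        return self.half_thickness_mm / 1000.0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InvalidInputError(f"unknown config keys: {sorted(unknown)}")
        for key in ("models", "temperatures_c"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


# ---------------------------------------------------------------------------
# CSV readers/writers
# ---------------------------------------------------------------------------


def read_rehydration_csv(path) -> list:
    """Read rehydration curves from tidy CSV.

    Required columns: sample_id, method, temperature_C, time_min, weight_g,
    dry_mass_g (moisture_pct_db optional).  Validation failures name the CSV
    row (header = line 1).
    """
    df = pd.read_csv(path)
    missing = [c for c in REHYDRATION_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"{path}: missing columns {missing}")
    curves = []
    for sample_id, grp in df.groupby("sample_id", sort=True):
        grp = grp.copy()
        rows = grp.index.to_numpy() + 2  # CSV line numbers
        times = grp["time_min"].to_numpy(dtype=float)
        dup = pd.Series(times).duplicated()
        if dup.any():
            raise InvalidInputError(
                f"{path}: duplicate (sample, time) at row {rows[dup.to_numpy()][0]}"
            )
        bad = np.nonzero(np.diff(times) < 0)[0]
        if bad.size:
            raise InvalidInputError(
                f"{path}: time decreasing for sample {sample_id!r} at row {rows[bad[0] + 1]}"
            )
        weights = grp["weight_g"].to_numpy(dtype=float)
        dry_mass = float(grp["dry_mass_g"].iloc[0])
        low = np.nonzero(weights < dry_mass)[0]
        if low.size:
            raise InvalidInputError(
                f"{path}: weight below dry mass at row {rows[low[0]]}"
            )
        curves.append(
            RehydrationCurve(
                sample_id=str(sample_id),
                drying_method=str(grp["method"].iloc[0]),
                temperature=float(grp["temperature_C"].iloc[0]) + 273.15,
                times=times,
                dry_mass=dry_mass,
                weights=weights,
                moistures=(
                    grp["moisture_pct_db"].to_numpy(dtype=float)
                    if "moisture_pct_db" in grp.columns
                    else None
                ),
            )
        )
    return curves


def write_rehydration_csv(curves: Sequence[RehydrationCurve], path) -> None:
    frames = []
    for c in curves:
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": c.sample_id,
                    "method": c.drying_method,
                    "temperature_C": c.temperature - 273.15,
                    "time_min": c.times,
                    "weight_g": c.weights,
                    "dry_mass_g": c.dry_mass,
                    "moisture_pct_db": c.moistures,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(path, index=False, float_format="%.10g")


def read_peak_table_csv(path, class_column: str = "class") -> PeakTable:
    """Samples x variables CSV with a class column; first column = sample id."""
    df = pd.read_csv(path, index_col=0)
    if class_column not in df.columns:
        raise InvalidInputError(f"{path}: missing {class_column!r} column")
    classes = df[class_column]
    areas = df.drop(columns=[class_column])
    return PeakTable(areas=areas, classes=classes)


def write_peak_table_csv(table: PeakTable, path, class_column: str = "class") -> None:
    out = table.areas.copy()
    out.insert(0, class_column, table.classes)
    out.to_csv(path, index_label="sample_id", float_format="%.10g")


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------


def simulate_default_curves(config: PipelineConfig) -> list:
    """Default synthetic rehydration curves: Weibull truths per drying method."""
    curves = []
    for offset, (method, truth) in enumerate(sorted(simulate.KINETIC_TRUTHS.items())):
        spec = simulate.RehydrationSimSpec(
            model_name="weibull",
            true_params={"alpha_ref": truth["alpha_ref"], "beta": truth["beta"]},
            e_a=truth["e_a"],
            temperatures=config.temperatures_k,
            t_ref=config.t_ref_k,
            m_e=truth["m_e"],
            noise_sd=config.noise_sd,
            drying_method=method,
            seed=config.seed + offset,
        )
        curves.extend(simulate.gen_rehydration_dataset(spec))
    return curves


def _stage_kinetics(config: PipelineConfig, curves: Sequence[RehydrationCurve]):
    by_method = {}
    for c in curves:
        by_method.setdefault(c.drying_method, []).append(c)
    rows = []
    residual_rows = []
    for method in sorted(by_method):
        for model in config.models:
            fit = fitting.fit_global_arrhenius(
                by_method[method],
                model,
                t_ref=config.t_ref_k,
                half_thickness=config.half_thickness_m,
                geometry=config.geometry,
            )
            logger.info(
                "kinetics: %s/%s k_ref=%.6g E_a=%.4g kJ/mol R2=%.5f",
                method, model, fit.k_ref, fit.e_a, fit.r_squared,
            )
            row = {
                "method": method,
                "model": model,
                "k_ref": fit.k_ref,
                "k_ref_se": fit.k_ref_se,
                "e_a_kj_mol": fit.e_a,
                "e_a_se": fit.e_a_se,
                "r_squared": fit.r_squared,
                "rmse": fit.rmse,
                "chi_squared": fit.chi_squared,
            }
            for name, value in fit.extras.items():
                row[name] = value
                row[f"{name}_se"] = fit.extras_se[name]
            rows.append(row)
            obs = np.concatenate(
                [np.full(c.times.size, c.temperature) for c in by_method[method]]
            )
            residual_rows.append(
                pd.DataFrame(
                    {
                        "method": method,
                        "model": model,
                        "temperature_K": obs,
                        "residual": fit.residuals,
                    }
                )
            )
    sat_rows = [
        {
            "sample_id": c.sample_id,
            "method": c.drying_method,
            "temperature_C": c.temperature - 273.15,
            "rehydration_time_min": (rt := fitting.estimate_rehydration_time(
                c, config.weight_tol_g)).time_min,
            "saturated": rt.saturated,
        }
        for c in curves
    ]
    return pd.DataFrame(rows), pd.concat(residual_rows, ignore_index=True), pd.DataFrame(sat_rows)


def _stage_quality(config: PipelineConfig, curves: Sequence[RehydrationCurve]):
    colors = simulate.gen_replicates(
        simulate.COLOR_MEANS, simulate.COLOR_SDS, config.n_replicates, seed=config.seed + 100
    )
    thermal = simulate.gen_replicates(
        simulate.THERMAL_MEANS, simulate.THERMAL_SDS, config.n_replicates,
        seed=config.seed + 200, clip_nonnegative=("dh_r",),
    )
    hardness = simulate.gen_replicates(
        {g: {"hardness": m} for g, m in simulate.HARDNESS_MEANS.items()},
        {g: {"hardness": s} for g, s in simulate.HARDNESS_SDS.items()},
        config.n_replicates, seed=config.seed + 300,
    )

    ref = simulate.DELTA_E_REFERENCE_CLASS
    ref_mean = quality.ColorMeasurement(**simulate.COLOR_MEANS[ref])
    ref_reps = colors[colors["group"] == ref][["l", "a", "b"]].to_numpy()

    rows = {}
    for group in simulate.COLOR_MEANS:
        sub = colors[colors["group"] == group]
        mean_color = quality.ColorMeasurement(
            l=float(np.clip(sub["l"].mean(), 0, 100)),
            a=float(sub["a"].mean()),
            b=float(sub["b"].mean()),
        )
        rows[group] = {
            "delta_e_of_means": (
                np.nan if group == ref else quality.delta_e(mean_color, ref_mean)
            ),
            "mean_delta_e": (
                np.nan
                if group == ref
                else quality.mean_delta_e(sub[["l", "a", "b"]].to_numpy(), ref_reps)
            ),
        }
        th = thermal[thermal["group"] == group]
        rows[group]["dr_pct"] = float(
            np.mean(
                [
                    quality.degree_retrogradation(
                        quality.ThermalRecord(t_p=r.t_p, dh_g=r.dh_g, dh_r=r.dh_r)
                    )
                    for r in th.itertuples()
                ]
            )
        )

    # Y and RRM from the rehydration curves at the hottest bath
    t_max = max(c.temperature for c in curves)
    for c in curves:
        if c.temperature == t_max:
            rows.setdefault(c.drying_method, {})
            rows[c.drying_method]["yield_y"] = quality.rehydration_yield(
                float(c.weights[-1]), float(c.weights[0])
            )
            rows[c.drying_method]["rrm"] = quality.relative_rehydration_moisture(
                float(c.moistures[-1]), config.m_c
            )

    comparisons = {}
    for metric, frame, col in (
        ("L_star", colors, "l"),
        ("a_star", colors, "a"),
        ("b_star", colors, "b"),
        ("T_p", thermal, "t_p"),
        ("hardness_N", hardness, "hardness"),
    ):
        groups = {g: frame[frame["group"] == g][col].to_numpy() for g in frame["group"].unique()}
        cmp_res = quality.group_compare(groups)
        comparisons[metric] = cmp_res
        logger.info("quality: %s ANOVA F=%.3f p=%.3g letters=%s",
                    metric, cmp_res.anova_f, cmp_res.anova_p, cmp_res.letters)

    table2_rows = []
    for group in rows:
        entry = {"treatment": group, **rows[group]}
        for metric, cmp_res in comparisons.items():
            if group in cmp_res.means:
                entry[metric] = quality.format_group_summary(cmp_res)[group]
        table2_rows.append(entry)
    return pd.DataFrame(table2_rows).set_index("treatment").sort_index(), comparisons


def _stage_volatiles(config: PipelineConfig, table: Optional[PeakTable]):
    if table is None:
        spec = simulate.PeakTableSimSpec(seed=config.seed + 400)
        table = simulate.gen_peak_table(spec, internal_standard=True)
    if table.internal_standard is not None:
        table = chemometrics.normalize_peaks(table)
    totals, total_cmp = chemometrics.total_peak_area(table)
    logger.info("volatiles: total-area letters=%s",
                total_cmp.letters if total_cmp else None)
    model = chemometrics.plsda_fit(table, n_lv=config.n_lv)
    vid = chemometrics.vid_coefficients(model, table)
    table3 = chemometrics.select_discriminants(
        vid, threshold=config.vid_threshold,
        retention_times=table.retention_times, ladder=DEFAULT_ALKANE_LADDER,
    )
    biplot = chemometrics.biplot_coordinates(model, table)
    logger.info(
        "volatiles: %d LVs, %d discriminants, X-var %.1f%%/%.1f%%",
        model.n_lv, len(table3),
        100 * biplot["explained_x"][0], 100 * biplot["explained_x"][1],
    )
    return table, table3, model, vid, totals, total_cmp, biplot


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------


def _round_floats(obj, ndigits=10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and write the report bundle into ``config.output_dir``.

    Returns a dict of output paths.  Raises on any stage failure, with the
    stage named in the log.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("config: %s", {f.name: getattr(config, f.name)
                                   for f in dataclasses.fields(config)})
        logger.info("stage: rehydration curves")
        if config.rehydration_csv is not None:
            curves = read_rehydration_csv(config.rehydration_csv)
        else:
            curves = simulate_default_curves(config)
        write_rehydration_csv(curves, outdir / "rehydration_curves.csv")

        logger.info("stage: kinetic fitting")
        table1, residuals, sat = _stage_kinetics(config, curves)

        logger.info("stage: quality metrics")
        table2, _ = _stage_quality(config, curves)

        logger.info("stage: volatile chemometrics")
        peak_table = (
            read_peak_table_csv(config.peak_table_csv)
            if config.peak_table_csv is not None
            else None
        )
        table, table3, model, vid, totals, total_cmp, biplot = _stage_volatiles(
            config, peak_table
        )

        table1.to_csv(outdir / "table1_kinetics.csv", index=False, float_format="%.6g")
        residuals.to_csv(outdir / "residuals.csv", index=False, float_format="%.6g")
        sat.to_csv(outdir / "rehydration_times.csv", index=False, float_format="%.6g")
        table2.to_csv(outdir / "table2_quality.csv", float_format="%.6g")
        table3.to_csv(outdir / "table3_discriminants.csv", index=False, float_format="%.6g")
        vid.to_csv(outdir / "vid_coefficients.csv", float_format="%.6g")
        write_peak_table_csv(table, outdir / "peak_table_normalized.csv")

        summary = {
            "seed": config.seed,
            "kinetics": {
                f"{r['method']}/{r['model']}": {
                    "k_ref": r["k_ref"],
                    "e_a_kj_mol": r["e_a_kj_mol"],
                    "r_squared": r["r_squared"],
                }
                for r in table1.to_dict("records")
            },
            "rehydration_time_min": {
                r["sample_id"]: r["rehydration_time_min"] for r in sat.to_dict("records")
            },
            "quality": {
                t: {
                    k: v
                    for k, v in row.items()
                    if isinstance(v, float) and np.isfinite(v)
                }
                for t, row in table2.to_dict("index").items()
            },
            "volatiles": {
                "n_latent_variables": model.n_lv,
                "n_discriminants": int(len(table3)),
                "total_area_letters": total_cmp.letters if total_cmp else {},
                "explained_x_pct": [100 * float(v) for v in model.explained_x],
                "explained_y_pct": [100 * float(v) for v in model.explained_y],
            },
        }
        summary_path = outdir / "summary.json"
        with open(summary_path, "w") as fh:
            json.dump(_round_floats(summary), fh, indent=2, sort_keys=True)
            fh.write("\n")
        logger.info("pipeline complete: %s", summary_path)
    except Exception:
        logger.exception("pipeline failed")
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
    return {
        "summary": str(summary_path),
        "table1": str(outdir / "table1_kinetics.csv"),
        "table2": str(outdir / "table2_quality.csv"),
        "table3": str(outdir / "table3_discriminants.csv"),
        "log": str(log_path),
    }
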