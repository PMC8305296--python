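# instabean

Rehydration kinetics, quality metrics and volatile-fingerprint
chemometrics for pre-cooked ("instant") dried beans.

Fresh common beans need hours of soaking and cooking; soaking, cooking and
then drying them (by air, vacuum or freeze drying) yields a shelf-stable
product that rehydrates in minutes to hours.  Judging such a product takes
three kinds of quantitative evidence, and this package implements all
three as a tested, reusable pipeline for food-process scientists:

1. **Rehydration kinetics.** Water uptake curves M(t) at several bath
   temperatures, normalised to the rehydration ratio
   RR = (M_t − M_o)/(M_e − M_o), are fitted with the Peleg
   (RR = t/((K1 + K2·t)(M_e − M_o))), Weibull (RR = 1 − e^−(t/α)^β),
   exponential (1 − e^−Ktⁿ) and first-order (1 − e^−Ht) models, and with
   the series solution of Fick's second law
   MR = (G/π²) Σ (2i−1)⁻² exp(−(2i−1)²π² D_eff t/L²) in which the
   geometric factor G is estimated rather than fixed at the slab value 8
   (or 6 for a sphere).  Temperature dependence is handled by substituting
   the Arrhenius law k(T) = k_ref·exp((E_a/R)(1/T_ref − 1/T)) into the
   model and fitting all temperatures jointly, which returns the time
   constant at the reference temperature (80 °C) and the activation energy
   E_a in one step, with asymptotic standard errors, R²/RMSE/χ² and a
   residual runs test.
2. **Quality metrics.** Rehydration yield Y = W_e/W_0 and relative
   rehydration moisture RRM = M_e/M_c; CIELAB total colour difference
   ΔE* = √(ΔL*² + Δa*² + Δb*²); degree of starch retrogradation
   DR% = 100·ΔH_R/ΔH_G from DSC enthalpies; and treatment comparison by
   one-way ANOVA with pairwise t-tests rendered as the usual
   compact-letter superscripts.
3. **Volatile chemometrics.** Aligned HS-SPME-GC-MS peak tables are
   normalised to an internal standard, compared on total peak area, and
   modelled with PLS-DA against one-vs-rest class dummies.  Discriminant
   compounds are picked by variable identification (VID) coefficients —
   the correlation between each variable and the model-reconstructed class
   membership — at |VID| > 0.8, reported per class with linear retention
   indices against a C8–C22 alkane ladder, plus bi-plot coordinates with
   the 70 %/100 % correlation circles.

A seeded synthetic-data module generates every input the pipeline consumes
(rehydration curves with Arrhenius structure and balance noise, replicate
tables for colour/DSC/hardness, log-normal peak tables with planted
discriminants), so the entire analysis is exercisable and testable without
instrument data.  See `docs/methods.md` for models, conventions and design
decisions.

## Worked example

Fit the Weibull model jointly across 70–100 °C on a synthetic vacuum-dried
study (α = 4.52 min at 80 °C, β = 0.62, E_a = 14.37 kJ/mol, 1 %db balance
noise):

```python
from instabean import simulate, fit_global_arrhenius
from instabean.models import BoundaryMoistures

spec = simulate.RehydrationSimSpec(
    model_name="weibull",
    true_params={"alpha_ref": 4.52, "beta": 0.62},
    e_a=14.37,
    noise_sd=1.0,
    seed=1,
)
curves = simulate.gen_rehydration_dataset(spec)
fit = fit_global_arrhenius(curves, "weibull",
                           bounds=BoundaryMoistures(m_o=11.0, m_e=150.0))
print(f"alpha(80 C) = {fit.k_ref:.3f} +/- {fit.k_ref_se:.3f} min")
print(f"E_a         = {fit.e_a:.2f} +/- {fit.e_a_se:.2f} kJ/mol")
print(f"beta        = {fit.extras['beta']:.3f} +/- {fit.extras_se['beta']:.3f}")
print(f"R2 = {fit.r_squared:.4f}, RMSE = {fit.rmse:.4f}")
```

prints

```
alpha(80 C) = 4.537 +/- 0.021 min
E_a         = 14.70 +/- 0.40 kJ/mol
beta        = 0.620 +/- 0.002
R2 = 0.9995, RMSE = 0.0074
```

i.e. the time constant at the reference temperature and the activation
energy are recovered within their standard errors from noisy curves.
Ranking competing models on one curve:

```python
from instabean import fit_single_curve, compare_models
bounds = BoundaryMoistures(m_o=11.0, m_e=150.0)
fits = [fit_single_curve(curves[0], m, bounds=bounds)
        for m in ("weibull", "peleg", "first_order")]
print(compare_models(fits)[["model", "r_squared", "rmse", "runs_z", "rank"]])
```

```
      model  r_squared     rmse    runs_z  rank
    weibull   0.999478 0.007433  2.640415     1
      peleg   0.992472 0.028226 -3.917396     2
first_order   0.952773 0.070698 -3.917396     3
```

The Weibull model fits best (highest R², lowest RMSE, least-patterned
residuals), with the first-order model clearly inadequate for β < 1
uptake.

The same stages are available from a shell:

```sh
instabean run --seed 1 --out results_demo   # full pipeline
instabean simulate --seed 1 --out sim       # synthetic input CSVs
instabean fit --input sim/rehydration.csv --model weibull
instabean volatiles --input sim/peak_table.csv --n-lv 3
```

`run` writes a kinetics table (per drying method × model: k_ref, E_a, G
with standard errors), a quality table (ΔE*, DR%, hardness, Y, RRM with
significance letters), a discriminant-volatiles table (class, VID,
retention index), a JSON summary and a log; identical seeds regenerate all
of them byte-for-byte.

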