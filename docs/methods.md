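# Methods

`instabean` implements the quantitative analysis pipeline for pre-cooked
("instant") dried beans: rehydration kinetics at several water-bath
temperatures, derived quality indices with treatment comparison, and
untargeted volatile-fingerprint chemometrics on aligned GC-MS peak tables.
This note records the models, the conventions and the genuinely open design
choices.

## Rehydration kinetics

Moisture is tracked on the dry basis, M = 100·(W − W_dry)/W_dry (%db), and
progress is normalised between the initial and equilibrium moistures of the
dried product,

    RR(t) = (M_t − M_o)/(M_e − M_o),    MR(t) = 1 − RR(t).

This orientation gives RR(0) = 0 and RR → 1 at saturation and is the form
every kinetic model below assumes.  The alternative typeset orientation
(M_t − M_e)/(M_e − M_o), which equals RR − 1, is available behind an
`as_printed=True` audit flag but is not used anywhere in the pipeline.

Four empirical models:

* Peleg: RR = (1/(M_e − M_o)) · t/(K1 + K2·t).  K1 (min·(%db)⁻¹, read as
  min per %db from dimensional analysis of the model) is the reciprocal of
  the initial uptake rate; K2 ((%db)⁻¹) the capacity constant, with
  M_e = M_o + 1/K2 at exact saturation.
* Weibull: RR = 1 − exp(−(t/α)^β); α (min) is the time to 63 % (1 − 1/e)
  completion, β ∈ (0, 2] the shape factor.
* Exponential (Page): RR = 1 − exp(−K·tⁿ); identical to the Weibull curve
  under n = β, K = (1/α)^β.
* First-order: RR = 1 − exp(−H·t), the exponential model with n = 1.

The mechanistic alternative is the series solution of Fick's second law
with an estimated geometric factor G in place of the theoretical pre-series
constant:

    slab:   MR = (G/π²) Σ_{i≥1} (2i−1)⁻² exp(−(2i−1)² π² D_eff t / L²)
    sphere: MR = (G/π²) Σ_{n≥1} n⁻²      exp(−n² π² D_eff t / L²)

At the theoretical constants (8 for the slab, 6 for the sphere, from
Σ(2i−1)⁻² = π²/8 and Σn⁻² = π²/6) MR(0) = 1 exactly; a freely estimated G
absorbs the fact that a bean is neither an infinite slab nor a perfect
sphere.  **Length convention:** the exponent carries no factor 4, so L is
the distance between the two exchange surfaces (both faces instantly
equilibrated); the tests validate this against a Crank–Nicolson solution of
the 1-D diffusion equation on exactly that geometry.  `fick_mr` takes time
in seconds (D_eff is m²/s); the fitting layer converts from minutes.

Series evaluation truncates when a term falls below `term_tol = 1e-12` or
after `n_terms_max = 500` terms (an explicit convergence error beyond
that); at t = 0 the closed-form partial sums are used, avoiding the slowly
converging limit.

### Temperature dependence and single-step estimation

The time constants follow the Arrhenius law about a reference temperature
(default T_ref = 353.15 K = 80 °C, the middle of the 70–100 °C range):

    k(T) = k_ref · exp((E_a/R)(1/T_ref − 1/T)),   E_a in kJ/mol.

For parameters that are time constants rather than rates (Peleg K1,
Weibull α) the law is applied to their reciprocal, so the reported k_ref
stays in the parameter's own units (e.g. α at 80 °C in minutes) and E_a is
positive when uptake accelerates with temperature.

`fit_global_arrhenius` substitutes this law into the chosen model and
solves one joint least-squares problem over every observation at every
temperature ("single-step"), estimating simultaneously k_ref, E_a and any
shared shape parameter (β for Weibull, K2 for Peleg, n for the exponential
model, G for the diffusion model).  The classical two-step route
(per-temperature fits, then log-linear regression on 1/T) is provided as an
independent cross-check and coincides with the single-step fit on noiseless
data.

### Numerical choices in fitting

* Loss: unweighted least squares on RR (MR for the diffusion model); all
  temperatures weighted equally in the global fit.
* Positive parameters are estimated as their logarithms (positivity by
  construction); β and n are bounded above by 2 and G lies in (1, 10) via
  bounds on the transformed variables; E_a is estimated on its natural
  scale and may legitimately be zero or negative.
* Initialisation: Weibull α from the interpolated time to RR = 0.632 with
  β = 1; Peleg from the linear regression of t/(RR·(M_e−M_o)) on t; the
  diffusivity from the late-time slope of log MR with G started at the
  theoretical constant.  Up to 5 jittered restarts (seeded) before a fit
  failure is declared, which carries the best attempt.
* Standard errors are asymptotic, from the Jacobian at the optimum with
  χ² = SSE/(N − p) as the variance estimate, delta-transformed back to the
  raw scale.  χ² uses the residual-degrees-of-freedom form common in the
  drying literature (the weighted form is not used).
* M_e defaults to the last observed moisture (the saturation criterion) and
  M_o to the first; both can be overridden with independently measured
  values.  Overriding matters for the diffusion model: the geometric factor
  is identified by the non-zero intercept MR(0) = G/8, which renormalising
  against the observed endpoints absorbs.  The simulation studies in the
  tests therefore pass the generative bounds explicitly.
* Degenerate inputs (constant moisture, a single temperature, mixed drying
  methods in one global fit) raise typed errors early.

Model comparison ranks fits on identical data by R² (descending), then
RMSE and χ² (ascending), and reports a Wald–Wolfowitz runs test on the
residual signs as the randomness-of-errors summary (via statsmodels).

### Saturation time

The rehydration time is the first reading whose weight increment from the
previous reading — and every later increment — is at most `weight_tol`
(default 0.05 g).  A curve whose increments are all within tolerance is
saturated from the start (time 0); one whose final increment still exceeds
the tolerance is returned flagged `not saturated` at the last time.

## Quality metrics

* Rehydration yield Y = W_e/W_0 and relative rehydration moisture
  RRM = M_e/M_c (M_c, the freshly cooked moisture, must be supplied — it is
  not derivable from the dried product).
* Colour difference ΔE* = ‖(L*, a*, b*) − (L₀*, a₀*, b₀*)‖₂ against the
  control (fresh beans for dried samples, cooked beans for rehydrated
  ones).  Whether a tabulated ΔE* is the ΔE* of group means or the mean of
  per-replicate ΔE* is ambiguous in common reporting; both are computed and
  reported side by side.
* Degree of starch retrogradation DR% = 100·ΔH_R/ΔH_G from DSC enthalpies;
  curve integration is out of scope — enthalpies are inputs.
* Group comparison: one-way ANOVA plus all pairwise t-tests (Welch by
  default; pooled optional) at α = 0.05 with no multiplicity correction by
  default (a Holm option exists, off to mirror plain t-test comparison of
  means).  Letters come from the insert-and-absorb compact-letter-display
  algorithm: start from one column holding all groups, split any column
  containing a significantly different pair, absorb columns that become
  subsets, and assign letters to columns ordered by their best-ranked
  member (groups ranked by descending mean).  The display is deterministic
  given the p-value matrix.

## Volatile chemometrics

Inputs are aligned peak tables (samples × variables, positive areas, class
labels); deconvolution, alignment and library identification are upstream
and out of scope.

* Retention indices are linear (temperature-programmed) against an
  n-alkane ladder: RI = 100·(n + (rt − t_n)/(t_{n+1} − t_n)); extrapolation
  beyond the ladder is an explicit opt-in.
* Internal-standard normalisation divides each sample by its IS area and
  drops the IS column.
* PLS-DA regresses preprocessed areas on one-vs-rest class dummies
  (NIPALS extraction via scikit-learn's `PLSRegression`).  Preprocessing is
  a log transform followed by column autoscaling: areas are positive,
  right-skewed and carry multiplicative noise, and on the raw scale single
  heavy-tailed draws dominate a column's variance and mask genuine class
  structure.  `log_transform=False` gives plain autoscaling of raw areas.
  Explained X- and Y-variance per latent variable are reported (the bi-plot
  axis annotations).
* Model complexity: the smallest number of LVs whose leave-one-out class
  assignment is perfect, falling back to the accuracy maximum; the pipeline
  default is 3 LVs for the four-class design.
* VID coefficients: the literature defines VID only by citation, so the
  implementation is a documented reconstruction — the Pearson correlation
  between each preprocessed variable and the model-reconstructed (fitted)
  membership column of each class, clipped to [−1, 1].  A positive VID
  means the compound is more abundant in that class; variables with
  |VID| > 0.8 (strict) are reported per class in decreasing VID, negative
  VIDs (depleted compounds) included.  One-vs-rest coding is assumed
  throughout; class-pairwise VIDs are not computed.
* Bi-plot coordinates: sample scores on a chosen LV pair, correlation
  loadings of variables and of class dummies with those scores, and the
  0.7/1.0 correlation circles.

## Synthetic data

The generators reproduce the statistical structure the analysis assumes,
so the full pipeline is testable without the original measurements:

* Rehydration curves: a chosen kinetic model with Arrhenius temperature
  dependence, evaluated on a log-spaced reading grid (0, then 0.25–360 min,
  41 readings — dense early where uptake is fast), with additive Gaussian
  balance noise on moisture (default sd 1 %db, truncated so weights never
  fall below the dry mass).  The default study conditions are four bath
  temperatures (70/80/90/100 °C), T_ref = 80 °C, M_o = 11 %db, and
  per-method Weibull truths (α at 80 °C of 4.52/4.77/0.61 min for VD/AD/FD
  with β ≈ 0.6 and E_a of 14.37/6.90/2.86 kJ/mol); equilibrium moistures
  follow from the rehydration yields (Y 2.28–2.56 ⇒ M_e 153–184 %db).
* Quality replicates: Gaussian draws around per-treatment means (CIELAB,
  DSC peak temperature and enthalpies, hardness) with the reported
  standard deviations, n = 6 by default.
* Peak tables: per-variable log-normal areas (noise CV 0.3); each class's
  designated discriminant variables get a log-mean shift of
  `effect_size` log-noise standard deviations (default 6 — discriminant
  volatiles are typically formed or lost outright, which is what near-unity
  VID magnitudes imply).  Four classes × 6 samples × 60 variables by
  default, with optional internal-standard column and synthetic retention
  times.

One integer seed drives each generator; sub-streams are spawned
deterministically, so equal seeds give byte-identical outputs.

What the generators do **not** emulate: solid leaching during rehydration,
moisture-dependent diffusivity or shrinkage, chromatographic peak-shape
artefacts, correlated (batch) structure between volatiles, and
non-Gaussian replicate error.  Passing tests therefore demonstrate
correctness of the estimators under the stated assumptions, not robustness
to those real-data complications.

## Calibration notes

* With response noise of sd 0.01 on the RR scale (moisture sd
  0.01·(M_e−M_o)), the single-step E_a estimate over four temperatures has
  |median bias| well under 2 % and its 95 % asymptotic confidence interval
  covers the truth ~96 % of the time over 50 simulation seeds.
* VID selection at |VID| > 0.8 with n = 6 per class: the population
  one-vs-rest point-biserial correlation of a shift of e log-sd is
  √(3/16)·e/√(1 + (3/16)e²) for four classes, which is ≈ 0.79 at e = 3 —
  *below* the threshold — and ≈ 0.95 at e = 6.  Full recovery of planted
  discriminants is therefore only a meaningful expectation for strong
  effects; the calibration tests plant 6 log-sd.  Under the null
  (no effect), some variable exceeds 0.8 in ≤ 5 % of tables.
* Problem sizes throughout the test-suite simulations (50 seeds for
  coverage/bias, 100 null tables, 40 Fourier numbers for the PDE
  comparison, 2·10⁶ series terms for the geometric constants) were chosen
  so every study resolves its target quantity comfortably while the whole
  suite stays quick on a single CPU.

## Known limitations

* No shrinkage-coupled or moving-boundary diffusion, no surface
  mass-transfer (Biot) term: external resistance is assumed negligible.
* No Bayesian estimation, model averaging, or moisture-dependent D_eff.
* RRM on real data needs the cooked-reference moisture as user input.
* The VID definition is a reconstruction (see above); other software may
  scale it differently even though the sign interpretation matches.
* The compact letter display is greedy insert-and-absorb; for pathological
  p-value patterns other valid letterings exist, but the output is
  deterministic for a given matrix.
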