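# Methods

## Model and estimation

Daily yield at `t` days in milk (DIM) is modelled by Wood's
incomplete-gamma curve `y(t) = a·t^b·e^(−ct)`, with `a` a g/day scale,
`b` the unitless rise rate and `c` the per-day decline rate. The curve
has an interior peak at `t = b/c` when `b, c > 0`; persistency is
reported as Wood's classical index `c^−(b+1)`.

Fitting is nonlinear least squares on the raw scale (Levenberg–
Marquardt with an analytic Jacobian; relative tolerances 1e−10, at most
500 function evaluations — a cheap 3-parameter objective), initialized
from the exact log-linearization `ln y = ln a + b·ln t − c·t` solved by
OLS. Raw-scale NLS is used because the goodness-of-fit statistic of
interest, `R² = 1 − SSE/SST`, is defined on the raw scale and computed
over exactly the points entering that fit — so fits on reduced
schedules carry their own SST. A `log_linear_only` mode scores the
initialization itself. Non-convergence does not raise: the fit is
returned flagged and downstream totals treat it as a failure, counted
and excluded from statistics (exclusion counts change the ANOVA, so
they are always logged).

Two estimator properties worth knowing, both measured by the test
suite:

* on noiseless Wood data any ≥3 informative points recover the
  generating parameters to machine precision (the model is exactly
  identified), so protocols A, B and C agree exactly in that limit;
* on a single animal's 14 noisy points the estimate of `a` is
  median-unbiased but **mean-biased upward** (~6% at test-day noise
  CV 0.10) because its sampling distribution is right-skewed; `b` and
  `c` are mean-unbiased. The bias decays as 1/n when fitting group-mean
  test-day values, which is how the breed-level analysis uses the
  model; the parameter-recovery acceptance test therefore works at the
  herd-mean level (500 herds × 76 animals) and checks
  median-unbiasedness at the single-animal level.

## Totals

The 210-day total from a fitted curve is the closed-form integral
`(a/c^(b+1))·[γ(b+1, c·t₁) − γ(b+1, c·t₀)]` (lower incomplete gamma;
verified against adaptive quadrature to <1e−8 relative). A fit with
`c ≤ 0` — possible on noisy 4-point schedules — integrates the finite
interval numerically instead; `b ≤ −1` with `t₀ = 0` is a divergent
integral and a counted failure. An alternative `daily_sum` mode totals
the predicted daily yields over days 1…210; every output table records
which mode produced it. The horizon defaults to 210 days (the last
scheduled test day) and is configurable.

The ICAR test-interval total credits each interval between consecutive
controls with `(Pₙ+Pₙ₋₁)/2 · d` (a trapezoid rule, exact for linear
production). The guidelines also credit the periods outside the
controls; the default therefore adds `P_first·(dim₁ − 3)` and
`P_last·(210 − dim_last)` — day 3 being the first milking day after
parturition — while a `between_only` mode restricts to the interior
intervals, since recording practice varies on this point. The monthly
control series is DIM 30, 60, …, 210.

Fat-corrected milk uses the 3.5%-fat standardization
`FCM = DMY·(0.634 + 0.1046·fat%)`. Note FCM is a *linear combination*
of two Wood curves (0.634·milk + 10.46·fat yield), hence not exactly
Wood-shaped; its A/B/C totals agree only to ~1e−4 relative even on
noiseless data, where the pure-trait totals agree to 1e−6.

## Recording protocols

A = all 14 fortnightly test days (DIM 15…210); B = monthly records of
months 1–4; C = months 1, 2, 4, 6. The month→DIM mapping is `30·m`,
matching the ~30-day official recording interval and placing every
monthly record on the 15-day grid, so B and C are exact subsets of A;
the mapping is configurable for sensitivity analysis. Subsampling is
strict by default (synthetic data are complete); a tolerant mode
substitutes the nearest record within ±7 days for real-world files.

## Statistics

Per breed × trait, per-animal totals are analysed by a one-way
fixed-effects GLM with calculation method (A, ICAR, B, C) as the sole
effect; LSMeans are the group means (the design is balanced) and the
SEM is the pooled `sqrt(MSE/n)` (harmonic-mean n if unbalanced). ICAR
enters the same GLM as a fourth method level. Dunnett's test compares
ICAR, B and C against reference A two-sided; the three contrasts share
the control, so adjusted p-values come from the equicorrelated
multivariate-t distribution (correlation 1/2 under balance; scipy's
implementation, seeded). A single contrast reduces exactly to the
pooled two-sample t-test and is computed in closed form; adjusted p is
floored at the unadjusted p, which it can never undercut in theory.
Significance classes: `*` p<0.05, `**` p<0.01, `n.s.` otherwise.

A Shapiro–Wilk screen of every breed × test-day × trait cell is
reported descriptively; nothing is transformed or excluded on its
account. No multiplicity control is applied across breeds or traits —
each breed × trait family is its own Dunnett family, mirroring how such
tables are conventionally reported.

The multi-herd headline analysis pools breeds (the GLM model statement
has no breed term) and asks, per simulated herd, whether C is
distinguishable from A; the per-breed analysis remains the reporting
mode for the wide table. Pooling is the literal reading of the model;
it is also conservative for detecting small protocol biases, since
between-breed spread inflates the error term — the per-animal median
absolute deviations |B−A| and |C−A| are therefore reported alongside
the tests as effect-size summaries.

## Synthetic herds

The generator emulates the recording design the analysis assumes: six
breed groups of 78/81/76/77/76/77 animals (465 total; one high-yield
breed near 2.7 kg/day, five between ~0.9 and 1.3 kg/day; 210-day
mean-curve totals 200/190/255/260/210/570 kg), each animal recorded on
all 14 grid days, giving 6510 records. Per animal: a shared lognormal
scale factor (mean 1, CV 0.20) multiplies `a` for all three traits —
so composition percentages stay realistic — while `b` and `c` get
independent normal perturbations (SD 0.05 and 0.001/day) per trait;
every recorded value carries i.i.d. multiplicative lognormal noise
(mean 1, CV 0.10). Fat and protein are generated as daily-yield curves
whose shapes differ slightly from milk (offsets −0.03/−0.0003 and
−0.02/−0.0002 on b/c), giving a mild ~2% mid-lactation composition
dip; recorded percentages are clamped into (0, 10)% fat and (0, 8)%
protein with clamps counted (~2% of records at default settings, caused
by the ratio of two noisy values). Dispersion defaults were sized so
that full-schedule fits land in the R² range typical of well-behaved
goat lactations (roughly 0.8–0.97 per animal).

What the generator does **not** emulate: parity, season and litter-size
effects (constants in a single-kidding design), pedigree structure,
drying-off and missing visits, trait-specific animal correlations
beyond the shared scale, and measurement error in composition analysis
separate from yield noise. Passing tests therefore show that the
*pipeline* behaves correctly under the assumed generative structure —
not that any particular real breed's totals are reproduced, which would
require the original herd data.

## Problem sizes and determinism

Simulation-based checks use: 500 replicates for parameter recovery,
2000 for the Shapiro–Wilk/ANOVA null-calibration and Dunnett
family-wise error simulations, 200 herds for the protocol-robustness
test (60 in the acceptance script, 50 in the analysis driver — enough
for the fractions reported to be stable to a few percent). All
randomness flows from explicit seeds through `numpy.random.SeedSequence`
spawning, so every output file is byte-reproducible from config + seed.

## Known limitations

* The Dunnett adjusted p-values inherit scipy's randomized
  multivariate-t quadrature error (~1e−4); tests compare them at that
  tolerance.
* ICAR totals depend on the edge-period convention; both conventions
  are implemented and stamped into outputs, but results in the wide
  report use the inclusive default.
* Totals from non-converged or divergent fits are excluded rather than
  imputed, slightly unbalancing the GLM in noisy reduced protocols
  (~0.1% of fits at default noise).
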