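# woodlact

Estimating a dairy goat's total lactation yield usually takes a dense
schedule of official test-day recordings. `woodlact` asks how much of
that schedule is really needed: it fits Wood's incomplete-gamma
lactation curve to test-day records under dense and reduced recording
protocols, integrates the fitted curves into 210-day totals, computes
the official ICAR test-interval totals, and tests statistically whether
the reduced protocols change the answer. It is written for animal
scientists and milk-recording organizations weighing cheaper recording
schemes, and for anyone who needs a clean, tested implementation of the
Wood curve, fat-corrected milk, or the test-interval method.

## The model

Daily yield at `t` days in milk (DIM) follows Wood's curve

    y(t) = a · t^b · e^(−c·t)

with scale `a` (g/day), rise rate `b` and decline rate `c` (per day);
the peak sits at `t = b/c` and persistency is `c^−(b+1)`. The 210-day
total follows in closed form from the lower incomplete gamma function:

    ∫₀ᵀ a t^b e^(−ct) dt = (a / c^(b+1)) · γ(b+1, cT)

Fat-corrected milk standardizes to 3.5% fat: `FCM = DMY · (0.634 +
0.1046 · fat%)`. The ICAR test-interval total credits each interval
between controls with `(Pₙ + Pₙ₋₁)/2 · d` plus constant-extrapolated
edge periods. Three recording protocols are built in: **A** — all 14
fortnightly test days (DIM 15…210); **B** — monthly records of months
1–4 (DIM 30, 60, 90, 120); **C** — months 1, 2, 4, 6 (DIM 30, 60, 120,
180). Per-animal totals are compared across calculation methods with a
one-way GLM and Dunnett's many-to-one test against reference A.

Because no public test-day dataset accompanies this design, the package
ships a synthetic herd generator (`woodlact.simulate`): six breed
groups (78/81/76/77/76/77 goats, one high-yield breed), Wood-shaped
mean curves for milk/fat/protein, lognormal between-animal scale
variability, normal shape variability, and multiplicative test-day
noise.

## Worked example

```python
import numpy as np
from woodlact import WoodParameters, fit_wood, curve_features, total_yield_wood, wood_predict

t = np.arange(15, 211, 15)                      # the 14 test days
true = WoodParameters(a=1000, b=0.2, c=0.005)   # g/day scale
rng = np.random.default_rng(0)
y = wood_predict(true, t) * rng.lognormal(-0.005, 0.0998, size=t.size)

fit = fit_wood(t, y)
print(f"a={fit.params.a:.1f} b={fit.params.b:.3f} c={fit.params.c:.5f} R2={fit.r2:.3f}")
f = curve_features(fit.params)
print(f"peak {f.peak_yield:.0f} g/day at DIM {f.peak_time:.0f}; total {total_yield_wood(fit.params, 0, 210):.1f} kg")
```

prints

```
a=790.5 b=0.289 c=0.00665 R2=0.892
peak 1763 g/day at DIM 44; total 296.7 kg
```

— the fitted curve peaks at ~1.8 kg/day around day 44 and integrates to
a 296.7 kg lactation; R² ≈ 0.9 is typical for a single noisy animal,
and the spread of the individual parameter estimates around the truth
(a = 1000, b = 0.2, c = 0.005) is exactly why totals, not raw
parameters, are the quantity compared across protocols.

The full study chain runs from the shell:

```
woodlact full-study --seed 1 --out results/
```

or step by step via the numbered drivers in `analysis/` (simulate herd,
fit breed curves, per-animal totals, protocol comparison, multi-herd
robustness). On simulated herds the well-spread protocol C is
statistically indistinguishable from the dense reference A (per-animal
median |C−A| ≈ 8 kg of milk, Dunnett n.s.), while the front-loaded
protocol B — which extrapolates the last 90 days — deviates about
2.6× more (median |B−A| ≈ 22 kg).

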