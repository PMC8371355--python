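# Methods

## Model

One well-mixed compartment (total body water) holds the body's creatinine.
Creatinine enters at a constant generation rate `Gen` (muscle mass is
assumed stable over the few days an acute episode spans) and leaves by
glomerular filtration at rate `GFR_K · [Cr]_t`. The volume of distribution
drifts linearly, `V_t = V0 + (ΔV/Δt)·t`, standing in for the net of fluid
inputs and outputs over the interval. The mass balance

    d/dt([Cr]_t · V_t) = Gen − GFR_K · [Cr]_t

is a first-order linear ODE with the closed-form solution

    [Cr]_t = Cr0 + [1 − (V0/V_t)^(1 + GFR_K/(ΔV/Δt))] · (Gen/(GFR_K + ΔV/Δt) − Cr0).

Assumptions worth keeping in mind: a single compartment (no slow
re-equilibration between plasma and tissue), purely filtration-based
elimination (no tubular secretion term), constant `Gen`, and piecewise
constant `GFR_K` and `ΔV/Δt` within each clinical interval. The time
origin `t = 0` restarts at every interval, with `Cr0` the creatinine
measured there.

## Canonical units

Internally everything is L, h, mg/dL; clearances in L/h; `Gen` in
mg/dL·L/h. Clinical inputs (GFR and Gen quoted per mL/min) are converted
once at the boundary with 1 mL/min = 0.06 L/h. This keeps every formula
free of unit factors and makes the worked numbers reproduce exactly;
sensitivities with respect to GFR are converted back to the clinical
mg/dL per mL/min for reporting (multiply the internal per-L/h slope
by 0.06).

## Parameter validity (rules A–E)

The model is only meaningful for: positive creatinine (A), positive
volume (B), non-negative GFR (C), positive generation rate (D), and a
fluid-loss rate that does not deplete the volume within the horizon,
`ΔV/Δt > −V0/t` (E). Validation reports all violated rules as data
rather than raising, so a caller can show every problem at once. Rule C
exists in two modes: `strict-clinical` enforces it; `extended-math`
skips it, because the formulas remain smooth for negative GFR and
evaluating there is useful for visualising the curve's behaviour. A
positive `ΔV/Δt` has no mathematical upper bound; above a configurable
sanity bound (default 10 L/h) a warning is attached, never an error.

## Sensitivities and their limit branches

`∂[Cr]_t/∂GFR_K` follows from the product rule on the closed form. The
written expression is 0/0 at three parameter loci, each with a
closed-form limit:

* `ΔV/Δt = 0` (the common fixed-volume case):
  `e^(−g·t/V0)·(t/V0)·(Gen/g − Cr0) − (1 − e^(−g·t/V0))·Gen/g²`;
* `GFR_K = −ΔV/Δt` (zero total clearance):
  `−(1/Δ)·ln(V0/V_t)·(Gen/(2Δ)·ln(V0/V_t) − Cr0)`;
* both zero: `−(t/V0)·(Gen·t/(2V0) + Cr0)`.

All three limit forms were cross-checked symbolically (sympy) against the
limit of the general expression before implementation, as were the two
worked tangent slopes and the volume-rate derivative. Dispatch uses a
rate threshold of 1e−8 L/h: below it the matching limit branch is
evaluated. Continuity across the threshold is part of the test suite
(general form at 1e−9 offsets vs. limit form, agreement better than 1e−6
relative).

`∂[Cr]_t/∂(ΔV/Δt)` is implemented on the general branch only; near its
singular loci the function refuses with an explicit error instead of
evaluating limits that have no verified closed form. Its sign is
genuinely unconstrained.

## Numerical choices

* **Log-space powers.** The evolution factor's exponent
  `1 + GFR_K/(ΔV/Δt)` routinely exceeds 20; the power is computed as
  `exp(e·ln(V0/V_t))` to avoid overflow.
* **Cancellation-safe forms.** Near the singular loci the two
  product-rule terms individually blow up like `1/(GFR_K + ΔV/Δt)` and
  cancel to an O(1) result. Three standard precautions keep the general
  formula accurate to ~1e−7 relative even at 1e−9 offsets:
  `ln(V0/V_t) = −log1p((ΔV/Δt)·t/V0)`, `1 − power = −expm1(·)`, and the
  exponent computed as `(g+Δ)/Δ` (the sum `g+Δ` is exact in floating
  point when `g ≈ −Δ`).
* **ODE oracle.** The closed form is verified against direct integration
  of the mass balance with DOP853 at rtol 1e−12 / atol 1e−14. The tight
  tolerances matter because values at requested times come from the
  integrator's dense-output interpolant, which is less accurate than its
  steps; at the looser 1e−10 the interpolant alone contributes ~1e−6
  relative error and would mask real disagreements.
* **Finite-difference oracle.** Central differences (default step 1e−4
  L/h, O(h²)) cross-check both analytic derivatives; the step shrinks
  once by 100× if a perturbed parameter set is invalid.
* **Inversion.** `[Cr]_dt(GFR_K)` is strictly decreasing, so Brent's
  method on the bracket [0, 300] mL/min (physiologic ceiling with wide
  margin) finds the unique root, to 1e−8 mL/min. An observation outside
  the attainable band `[[Cr]_dt(G_max), [Cr]_dt(0)]` returns a flagged,
  non-converged estimate with the distance to the nearest attainable
  value, so model misfit is visible rather than clamped away.
* **Series inversion.** Each consecutive measurement pair is inverted
  independently; the interval's `ΔV/Δt` is its recorded net fluid
  balance divided by its length (zero if absent), and the next
  interval's `V0` is the previous interval's end volume. The model
  restarts its clock each interval but is silent on volume carry-over;
  carrying the end volume forward is this package's choice, since
  discarding known fluid history would contradict the volume model.

## Sign scan

The negativity of `∂[Cr]_t/∂GFR_K` on the valid region is a theorem of
the model; this package verifies it numerically rather than reproving it
symbolically. The scan draws parameters uniformly from clinically
plausible ranges (Cr0 ∈ [0.2, 15] mg/dL, Gen ∈ [20, 150] mg/dL·mL/min,
GFR_K ∈ [0, 120] mL/min, V0 ∈ [20, 60] L, t ∈ (0, 72] h, with ΔV/Δt
drawn between just above the rule-E depletion bound −V0/t and +0.5 L/h),
evaluates the dispatched derivative for each draw, and counts
non-negative values; the default acceptance run uses 100,000 seeded
draws and expects a count of zero. The worst case (largest derivative)
is reported for inspection. A scan is evidence over the sampled ranges,
not a proof: it cannot rule out sign changes outside them or on
measure-zero sets, but the theorem says none exist.

## Synthetic data

The generator emulates the bedside situation the model describes: a
piecewise-constant `GFR_K` and fluid-rate trajectory (e.g. "GFR drops to
10 mL/min and stays there"), sampled every few hours, with multiplicative
lognormal measurement noise — observation = truth × exp(N(0, σ²)) with
σ = ln(1 + CV) — because creatinine assay error scales with the level.
The default CV of 0.05 matches routine laboratory performance. Creatinine
and volume are carried across segment joins, so the truth trajectory is
continuous. What the generator does **not** emulate: drifting `Gen`
(sepsis, ICU wasting), non-linear fluid schedules, tubular secretion,
assay-specific bias, or irregular real-world sampling jitter. Round-trip
tests on this synthetic data therefore demonstrate correctness of the
mathematics and the solver, not robustness of kinetic GFR estimation to
model misspecification in real patients.

## Problem sizes

The verification suites use 1000 random scenarios for the closed-form vs.
ODE comparison, 300 for the analytic vs. finite-difference comparison,
100,000 draws for the sign scan, and 1000 noiseless round-trip
inversions; together they complete in a few seconds, and all were chosen
as comfortably exhaustive for one-dimensional kinetics with five
parameters.

## Known limitations

* `Gen` is constant; a linearly falling generation rate has a closed
  form in principle but is not implemented.
* Only the GFR and volume-rate sensitivities are provided; derivatives
  with respect to Cr0, Gen, V0 and t exist but are out of scope.
* The volume-rate sensitivity has no limit branches, by design.
* Per-interval inversion treats each creatinine pair as exact; there is
  no smoothing or uncertainty propagation across a noisy series.
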