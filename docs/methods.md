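# Methods

## Model

Body mass is decomposed into three concurrent first-order processes. The
old compartment V decays as `dV/dt = −k_v V` from `V(0) = M_i`; the new
compartment N grows as `dN/dt = −k_n N + Q` from `N(0) = 0` with constant
intake `Q = k_n M_f`, so its plateau is `M_f`; and during the transition
the two compartments exchange mass while eliminating it,

```
dV/dt = −k_v V + k_nv N
dN/dt = −k_n N + k_vn V
```

with `k_v = k_vn + k_e`, `k_n = k_nv + k_e` and a common elimination
constant `k_e > 0`. The characteristic quadratic
`(s + k_v)(s + k_n) − k_nv k_vn` then factors exactly as
`(s + k_e)(s + K)` with `K = k_v + k_nv = k_n + k_vn`, so the two
biexponential roots are `α = k_e` (slow) and `β = K` (fast), and the
compartment total obeys `dM/dt = −k_e M`, i.e.
`V(t) + N(t) = (V_x + N_x) e^(−k_e t)`. Both the exact partial-fraction
solution and the approximate transient
`(M_i + M_f)(e^(−α t) − e^(−β t))` are implemented; the approximation is
what enters the composite solving equation. Note the two are not the same
function: under the exact roots `K − β = 0`, so the exact total is a pure
exponential while the approximate term is a genuine bump with amplitude
`(M_i + M_f)`. The composite equation treats `(k_mi, k_mf, α, β)` as four
independent positive parameters; the redistributive consistency constraint
is *not* imposed on fitted curves, matching how the composite is used — a
descriptive solving equation, not a mechanistic reduction.

All rates are h⁻¹ and masses kg. Time is hours internally; files use days
since the first visit (24 h/day; a generated month is 30 days). This keeps
the printed metabolic-constant formula `k_m = −(1/24) ln[(M_c − M_a)/M_c]`
literal in code. `k_m` is 0 at zero food mass and grows without bound as
the daily food mass approaches the body mass; its exact algebraic inverse
`M_a = M_c (1 − e^(−24 k_m))` is used by the simulator. Because zero food
mass is a legitimate input, `k_mi` and `k_mf` are allowed to be zero in a
parameter set, while the distributive roots must be strictly positive with
`α ≤ β` (the ordering makes the transient non-negative; the quadratic is
solved with the stable Vieta form for the small root).

Degenerate roots: when `β − α < 1e−12 h⁻¹` the approximate transient
returns its analytic limit `(M_i + M_f) t (β − α) e^(−α t)` (which tends
to 0), while the exact partial-fraction state raises an error, since the
printed coefficients divide by `β − α`. Rate sets must satisfy
`|(k_v − k_vn) − (k_n − k_nv)| ≤ 1e−9 h⁻¹`; the constraint is exact in the
model, the tolerance only absorbs floating-point input.

## Estimation

Each patient contributes at least four (time, mass) pairs — a curvilinear
trend cannot be checked with fewer. In the default *paper* mode the
endpoint quantities are measured rather than fitted: `M_i` is the first
observed mass and `k_mi`, `k_mf` come from the `k_m` formula applied at
the first and last control visit. The remaining parameters are estimated
by bounded nonlinear least squares (SciPy `least_squares`) on
log-parameterised rates, with the ordering constraint built into the
parameterisation `(log α, log(β − α))`. Rate bounds are
`[1e−8, 1] h⁻¹` — from "no change within a decade" to "equilibrates within
hours", generously bracketing physiology. A deterministic multistart grid
(default 12 starts: four α values spanning `0.1/T` to `10/T` for a series
of span `T`, three β/α ratios 1.5/3/6) guards against the bimodal
bump-placement problem; among equal-deviance candidates the smallest α,
then smallest β, wins, making the fit deterministic. *Free* mode also
estimates `k_mi` and `k_mf`.

`M_f` is by default a **free parameter** (the asymptotic diet-target
mass) rather than the last observed mass. The two readings are both
plausible a priori; the package uses the free parameter because under this
model the redistributive transient is generally still live at the final
control, so the last observation is a biased estimate of the asymptote —
pinning `M_f` to it leaves a systematic residual that inflates the mean
cohort variance several-fold above the noise floor and past the 1 kg²
validity threshold. Pinning remains available
(`FitConfig(m_f_source="last_observation")`).

Fit quality: `Dev = Σ (obs − exp)²`, `Var = Dev/DF`. The default DF
convention counts the observed–expected *pairs* (this is the convention
under which 60 patients with 4 controls give 240 DF); the standard
`pairs − fitted parameters` alternative is available. An optional
diagnostic reports the per-visit `k_m` sequence; it does not enter the
composite evaluation, which uses only the endpoint constants.

## Validation

Per-patient variances are pooled per pathophysiology group as an
unweighted mean (the DF-weighted pooled `Dev_total/DF_total` is also
reported). A group is *valid* when its mean variance is below 1 kg² with
at least 240 pooled DF, *invalid* above the threshold, and
*indeterminate* below 240 DF — small groups cannot support a verdict
either way. Both constants are overridable. No between-group significance
testing is attempted: the question is whether the model can interpret each
group's data, not whether groups are equal.

## Synthetic cohorts

The generator emulates the study design on which the method is used:
374 patients of both sexes aged 7–73, 4–8 monthly controls (30-day
interval), masses quantised to the 0.1 kg resolution of a clinical
balance, and groups healthy/anorexia/tumors/other with weights
0.70/0.025/0.03/0.245 — the two clinical groups deliberately small enough
that their pooled DF lands near the congruity boundary. Heights come from
sex-specific adult normals (1.75 ± 0.07 m male, 1.62 ± 0.065 m female)
with a linear growth proxy between ages 7 and 18; initial BMI is sampled
per group (anorexia 13–17.5, healthy 18.5–30, tumors 16–28, other 17–32
kg/m²) and the target mass is pulled toward the normal BMI interval,
mimicking the assigned balanced diet. Metabolic constants derive from
plausible daily food masses (1–3 kg/day) through the `k_m` formula;
distributive constants are sampled with `α` log-uniform in
`[5e−4, 5e−3] h⁻¹` and `β/α` uniform in `[1.5, 5]`, producing visible
transients on a months-long horizon.

Measurement noise is Gaussian with sd 0.25 kg, then quantised; the sd is
a choice (the instrument resolution is known, biological variation is
not) that puts the per-patient variance floor (~0.06 kg²) safely inside
the validity regime. Per-visit food mass is derived from the noise-free
trajectory — the first visit through `k_mi` (habitual intake), later
visits through `k_mf` (the assigned diet) — so the endpoint constants
recomputed from a noiseless record equal the ground truth exactly and a
noiseless fit can recover the generating parameters to machine precision.
What the generator does **not** emulate: dietary composition and energy,
dropout and irregular visit schedules, within-subject drift of the rate
constants, and any real biological deviation from the composite curve
itself. Tests that pass on these cohorts therefore certify the machinery
(equations, optimiser, pooling) under the model's own assumptions — they
say nothing about whether real weight trajectories follow the model.

## Numerical cross-checks

Every closed form is validated against an independent adaptive
Runge–Kutta integration (rtol 1e−12, atol 1e−13) of the defining ODEs; the
agreement threshold is 1e−6 kg, about four orders above the integrator's
observed error. The root identities (`α = k_e`, `β = K`, Vieta relations)
are asserted to 1e−12 relative tolerance on randomized consistent rate
sets, and `metabolic_constant`/`food_mass_from_constant` round-trip to
1e−10.

## Problem sizes

The shipped test suite and the reproduction script fit the full default
cohort (374 patients, ~2,250 pairs) end to end; unit-level recovery and
Monte-Carlo checks use 20–100 simulated patients, sizes at which the
sampling error of the checked statistics is already far from the asserted
bounds.

## Known limitations

- The approximate redistributive amplitude `(M_i + M_f)` can produce
  transients of tens of kg for adult masses — visually striking and
  clinically implausible, but it is the composite equation's literal
  form; users who need a conservative transient should fit and inspect
  `α`, `β` and consider the exact two-compartment solution.
- Paper-mode endpoint constants inherit measurement noise from the first
  and last visits; no uncertainty is propagated (no standard errors or
  confidence intervals are produced, by design).
- The pairs DF convention makes `Var` a biased (low) estimate of the
  residual noise variance when series are short, since fitted parameters
  absorb part of the noise.
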