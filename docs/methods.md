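# Methods

`reospread` models the spread of an oncolytic reovirus over a cancer-cell
monolayer with a hierarchy of three reaction–diffusion models, estimates
every kinetic parameter from small printed assay tables (or synthetic
equivalents), and connects the models to observable plaque phenotypes:
invasion speed, front steepness, and plaque area. The motivating system is
the wild-type reovirus T3DPL (T3wt) versus its large-plaque mutant SV5,
which binds cells *less* efficiently yet spreads farther — the analysis
quantifies why, and predicts the binding rate that maximizes spread.

## Models

**Short-time model (first ~16 h).** Free virus only: diffusion plus
first-order removal by binding,

    V_t = D_V ΔV − γ_b V,    V(x, y, 0) = V0 δ0.

The substitution φ = V e^{γ_b t} reduces this to the heat equation, so V is
the damped 2-D heat kernel. The detectable spread radius (where V falls to
a threshold V_min) is

    r(t) = sqrt( 4 D_V t [ ln( (V0/V_min) / (4π D_V t) ) − γ_b t ] ),

which vanishes at the critical binding rate
γ_b* = ln((V0/V_min)/(4π D_V t))/t; at t = 1 h, D_V = 0.01 mm²/h,
V0/V_min = 1000 this is 8.98 ≈ 9.0 per hour. Internally nothing is rounded;
printed output uses one decimal.

**Invasion model (days).** Constant susceptible monolayer, infected cells I
and virus V:

    I_t = γ_b ν V − α I
    V_t = D_V V_xx + α b̃ I − γ_b V.

The viral replication number R_V = b̃ν (progeny infections per infected
cell) controls growth; invasion needs R_V > 1. The leading-edge ansatz
(I, V) ∝ e^{−λ(x−ct)} with ϱ = cλ gives the dispersion relation

    c² = χ(ϱ) = D_V ϱ² (α + ϱ) / ( ϱ² + (α+γ_b)ϱ − αγ_b(R_V − 1) ),

defined right of the pole ϱ_v (positive root of the denominator). The
linear-spreading speed is c* = sqrt(min χ) and the front decay rate
λ* = ϱ*/c*. The minimum is unique: critical points of χ solve a cubic P₃
with exactly one positive root (Descartes' rule), which the implementation
cross-checks against the numerical minimizer. Since c*(γ_b) → 0 both as
γ_b → 0 (no replication) and γ_b → ∞ (virions trapped instantly), the speed
has an interior maximum in the binding rate — the central result. For burst
size 514 the optimum is γ_b = 0.29/h (c* = 0.04858 mm/h); the observed T3wt
rate 0.96/h is far above it, while SV5's 0.28/h sits near its optimum.

**Plaque model.** Adds an explicit susceptible-cell density C (normalized
to 1):

    C_t = −γ_b ν C V,   I_t = γ_b ν C V − α I,
    V_t = D_V ΔV + α b̃ I − γ_b V,

on a 30 × 30 mm square (the domain size is read in mm, consistent with
D_V in mm²/h) with no-flux boundaries and a central inoculum. The plaque is
the region where C < 1% of its initial value, mirroring the cleared area
scored by crystal-violet staining; areas are counted as grid nodes × dx².

## Parameter estimation

All estimators work in canonical units (mm, hours, virions).

- **Binding rate** (per hour): from k replicate 1-hour bound fractions y_i,
  γ̂_b = −ln( mean(1 − y_i) )/t — the ML pooling under the exponential
  binding law. Fractions of exactly 0 or 1 are rejected (log-degenerate).
  Interval: delta method on the replicate scatter. Defaults reproduce
  0.96/h (T3wt) and 0.28/h (SV5) from the shipped table.
- **Diffusion coefficient**: least squares of the 1-D free-space Gaussian
  against percent-per-fraction column data, with the Gaussian integrated
  *exactly* (erf) over each 5.5 mm fraction — the fractions are ~3.5× the
  diffusion length sqrt(2 D t) ≈ 1.55 mm at 120 h, so a midpoint-density
  approximation would misfit the first fraction badly. Moment-based initial
  guess (E[x²] = 2Dt), 3 deterministic starts. Independently,
  Stokes–Einstein D = k_B T/(6πηr) with r = 35 nm, η = 10⁻³ Pa·s,
  T = 294.15 K gives 0.022 mm²/h, close to the fitted 0.01 mm²/h.
- **Death rate** (per hour): fit of D_I(t) = 1 − e^{−α·max(t−onset,0)}.
  The onset delay (default 15 h, the first assay time point) models the
  eclipse phase before lysis; a plain no-delay fit underestimates α and
  fits the 15–36 h assay data poorly. The per-strain fit on the shipped
  table gives α = 0.064 (T3wt, R² = 0.745) and 0.053 (SV5); a pooled fit
  gives 0.058. The model presets use the shared rounded value 0.057.
- **Burst size** (virions/cell): carrying capacity K of a logistic fit to
  per-cell virion production. The fit minimizes squared error of the *log*
  counts — the ML choice when scatter is multiplicative, and the reason
  the estimator stays stable: in level space ~12% of noisy draws admit a
  runaway "still rising" fit with K unbounded. K is additionally bounded
  to [max/10, 20·max] since a never-saturating series cannot identify a
  carrying capacity. Zero (pre-release) counts are excluded.
- **ν** (infections per bound virion) is not estimable from these assays;
  the presets use 0.01, inside the literature range [10⁻³, 10⁻²].

Confidence intervals throughout are asymptotic-normal on the fitted scale
and are reported but never used as model inputs; the point estimates are
authoritative.

## Numerics

**PDE discretization.** Method of lines, 2nd-order central differences,
mirror ghost cells for the no-flux boundaries, forward-Euler stepping with
dt = 0.4·dx²/(2 d D_V) by default (d = dimension), capped by 0.2/(α+γ_b).
The kinetic rates (≤ ~1/h) are far below the diffusion stability limit at
the grids used, so explicit stepping is cheap and positivity-preserving in
practice (asserted in tests). User-supplied dt beyond the stability bound
is rejected before stepping.

**Front-speed measurement.** The invasion model is linear, so the solution
grows exponentially (rate ≈ 0.19/h for T3wt) behind the front while the
front itself translates at the linear-spreading speed. A tracking level
proportional to the running maximum therefore follows a ray *behind* the
front (the level-set of relative amplitude drifts toward the bulk by the
large-deviation rate function) and does not measure c*; the tracker instead
follows a **fixed absolute titre level** (default: the inoculum amplitude),
whose crossing ray converges to c* with an O(1/t) transient. The front
position per snapshot is the outermost crossing, linearly interpolated
between nodes; the speed is the OLS slope over the central [40%, 80%] time
window. Reference run conditions: 20–25 mm domain, 300 h, dx = 0.02 mm
(the domain keeps the front ≥ 10/λ* from the far boundary). Measured
speeds sit ~0.9% below the analytic c* for both strains — the residual is
the slow temporal transient, not spatial error: halving dx moves the speed
by < 0.2%.

**Plaque simulations.** The inoculum magnitude is not identifiable from
the data, so it is calibrated once: a central Gaussian of fixed physical
width σ = 0.05 mm (deliberately *not* tied to the grid spacing, so the
continuum problem is resolution-independent) and total mass V0 = 1.75
chosen so the T3wt 120-h plaque area lands at ≈ 15.1 mm² at dx = 0.1. The
scientifically meaningful output, the SV5/T3wt area ratio, is insensitive
to this calibration: at the defaults it is 3.58, moving to 3.64 under dx
halving and 3.48 under doubling the inoculum width at fixed mass, and it
barely shifts when the inoculum mass doubles. Absolute areas at small burst
sizes (plaques of ~1 mm radius) carry several-percent grid sensitivity at
dx = 0.1.

**Binding-rate optimization.** c*(γ_b) is maximized by a deterministic
coarse-to-fine search (200 log-spaced points, then bounded refinement).
The search bounds are part of the question: unconstrained, the b̃ = 1000
optimum is γ_b = 0.57 (c* = 0.0716); capped at γ_b ≤ 0.5 — the range used
in the published sweep this package reproduces — the optimum sits at the
cap with c* = 0.07154. Both are available through `gamma_bounds`.

**Dispersion minimization.** The bracket starts at ϱ_v(1+10⁻⁶), where χ
diverges, and the upper bound doubles until χ is increasing; bounded
scalar minimization refines to xatol 10⁻¹³. The minimizer is verified
against the positive P₃ root to 10⁻⁶ and the 2×2 leading-edge determinant
to 10⁻⁸ in tests.

## Synthetic data

Each generator is the exact forward model of its paired estimator plus a
noise model respecting the variable's support:

- bound fractions: logit-normal, with the logit location mean-corrected by
  Gauss–Hermite quadrature so replicates average to the forward-law
  fraction (an uncorrected logit-normal biases the mean by ~8% at logit-sd
  0.5 near a fraction of 0.24, which would contaminate recovery studies);
- column fractions and virion counts: multiplicative lognormal;
- death fractions: additive Gaussian truncated to [0, 1];
- fluorescence: additive Gaussian on the normalized intensity, clipped
  at 0.

Default designs mirror the real assays: 3 binding replicates at 1 h; 8
column fractions of 5.5 mm at 120 h; death sampling at 15, 18, 24 (×3),
30 (×2), 36 (×2) h; burst sampling at 10 points over 0–36 h; 445
pixels/mm front profiles. Every generator is byte-deterministic given its
seed.

What passing recovery tests show — and what they do not: the estimators
are consistent and approximately unbiased *under these noise models and
designs*. Real assay noise need not be logit-normal or lognormal;
western-blot quantification and image segmentation introduce systematic
components none of the generators emulate. The fixture-backed checks
(binding rates, death rate, the closed-form quantities) are the only ones
anchored to real measured numbers; burst sizes, the fitted D_V and the
per-pixel front decay rates are validated by synthetic recovery because
the underlying series exist only as figures.

## Front-decay validation

The invasion front predicts fluorescence ∝ e^{−λ(x−s)} ahead of the plaque
edge. Intensities are max-normalized before fitting (so arbitrary
fluorescence units fit the unit-amplitude model) and the reported shift is
back-converted to raw units (s = s_norm + ln f_max/λ). Per-pixel rates are
converted to per-mm with the imaging scale (445 px/mm). The measured mean
rates, 9.8/mm (T3wt) and 4.9/mm (SV5), sit 42% above and 9% below the
analytic λ* of 6.9 and 5.4 — consistent in magnitude and, importantly, in
ordering: the weaker-binding strain has the shallower front, i.e. it seeds
infection farther ahead.

## Known limitations

- The invasion model is linear (no susceptible depletion), so its 1-D
  solutions grow without bound; simulations are kept to a few hundred
  hours to stay inside double precision, and the measured "front" is only
  meaningful at a fixed absolute level.
- Absolute plaque areas depend on the calibrated inoculum and, for small
  plaques, on the grid; only the area *ratio* is treated as a robust
  output.
- Interval estimates are asymptotic and not validated against any
  reference; the underlying assays' interval procedure is not modelled.
- The cell compartment ignores cell division and death from causes other
  than infection over the 5-day window.
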