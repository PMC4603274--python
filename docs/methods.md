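# Methods

This note records the model conventions, numerical choices and limitations
of sasmodelfit, in the order data flows through the package.

## Data model and import

A curve is three columns (q, I, σ).  The package is unit agnostic: all
computations happen in the units supplied, and the only place units enter
explicitly is the concentration conversion (below).  The reader treats any
line whose tokens all parse as floating point as data and skips everything
else (counting skipped lines in the curve log), which makes PDH-style
files with textual headers readable without a dedicated dialect parser.
Points with q ≤ 0 are rejected with a warning.  Every curve carries an
immutable copy of its as-read data (`original`); windowing, reduction and
masking produce new working views and never touch it.

**Uncertainty estimation.**  When σ is absent (or nonpositive, which the
weighted fit cannot use) it is estimated from the smoothness of the curve:
a quadratic is fitted over a moving 11-point window (clipped at the
boundaries) and σ of the centre point is the rms residual about the local
fit, with the residual degrees of freedom (window − 3) divided out.  When
all q, I > 0 the quadratic is fitted in (log q, log I) and residuals are
taken in linear intensity, so pure power laws — the generic local shape of
scattering curves — leave zero residual; otherwise linear coordinates are
used.  Curves shorter than the window fall back to one global fit and are
flagged; exactly constant curves receive a small positive floor
(10⁻¹² × max |I|).  The window length and polynomial order are
reproducible conventions, not fitted quantities.

**Merging.**  Per-curve q windows are applied before concatenation; the
merged curve is sorted by (q, I, σ) so the result is independent of input
order; duplicate q values are kept as distinct points (the weighted fit
handles them, and adaptive averaging will merge them naturally).

## Point reduction

Three methods, all operating on the working view only:

1. *Ratio*: with points numbered i = 1..n, point i is kept iff
   ⌊i·f⌋ > ⌊(i−1)·f⌋ — a uniform decimation keeping ≈ f·n points.
2. *Distance*: greedy forward scan keeping a point iff its Euclidean
   distance from the last kept point is ≥ d_min, computed in linear or
   log₁₀ (q, I) coordinates.  Log coordinates require q, I > 0 and the
   offending point is named otherwise.
3. *Adaptive averaging* (recommended): the curve is partitioned left to
   right into maximal intervals; a point n joins the interval opened at
   point j iff |I_n − I_j| ≤ ε_I (σ_n + σ_j)/2 and (q_n − q_j) ≤ ε_q q_j.
   Both conditions reference the interval's first point — a deterministic
   single-pass convention chosen because the alternative (a running mean
   reference) is order-sensitive within the interval and changes nothing
   for ε → 0.  Each interval is replaced by the inverse-variance weighted
   mean of I with the σ of the weighted mean, q averaged with the same
   weights — the estimator consistent with the χ² weighting of the fit.
   Singleton intervals pass through bit-exact, so ε_I = ε_q = 0 is the
   identity.  For ε_q > 0 the output spacing is narrow at low q and wide
   at high q.

## Size distributions

The set of distributions is fixed (monodisperse, Gaussian, lognormal,
Schulz–Zimm) because robust adaptive integration ranges cannot be
guaranteed for arbitrary user densities.  All are number weighted and
integrate to the scale N, which is therefore the "number of scatterers" in
fitted units.  Conventions:

- Gaussian: location X0, width s, both in length units.  The density is
  **not** renormalized after truncation at x ≥ 0 and closed-form
  (untruncated) moments are used throughout; this is the convention under
  which the concentration → mass-fraction chain reproduces its reference
  values, and it is adequate for the narrow (s/X0 ≲ 20%) distributions the
  number-weighted approach is meant for.
- lognormal: median X0 (length), log-standard-deviation s (dimensionless).
- Schulz–Zimm: mean X0 (length), relative width s (dimensionless), i.e. a
  gamma distribution with shape k = 1/s².
- s = 0 of any kind collapses to the monodisperse delta at X0.

Moments 1–6 are closed form (cross-checked against quadrature in the
tests); a moment that overflows to non-finite is reported as `None`
("undefined") rather than a number.  The mean sphere volume is
⟨V⟩ = (4π/3) E[x³] in the distribution's own length unit.

**Integration.**  Distribution integrals use composite Simpson on a linear
subdivision of an adaptively chosen range: ±8 widths around the location
(quantile-based for Schulz–Zimm), clipped at x ≥ 0, leaving < 10⁻⁶ of the
mass outside (checked against the closed-form CDF before clipping).  The
subdivision count is 12 per (range/sd), bounded to [50, 5000] and forced
even; a zero-clipped lower edge is nudged to 10⁻¹²·x_hi so form factors
with open x > 0 domains stay evaluable.  `distribution_quadrature`
verifies convergence by doubling the count and warns above 10⁻⁴ relative
change.

## Form factors and the registry

The sphere exposes amplitude and intensity:
F(q) = η (4π/3) R³ · 3[sin(qR) − qR cos(qR)]/(qR)³, with the series
1 − x²/10 + x⁴/280 below qR = 10⁻³ (no special-cased constants).  The
branched-polymer model (mass-fractal minimum path, excluded-volume
parameter v, scaling factor c, radius of gyration Rg) exposes intensity
only — deliberately, to exercise the error path of amplitude-requiring
structure-factor approximations.  Its closed form uses lower incomplete
gamma functions of arguments c/2v and (c+1)/2v with
u = q²Rg²(2v+1)(2v+2)/6, normalized so P(0) = 1; validity requires
Rg, v, c > 0 and q ≥ 0 (q < 0 raises an error naming q).

The registry mirrors a plug-in system in-language: models register under a
namespace, must declare at least one parameter and every parameter must
carry a range check; duplicates are refused; fresh templates evaluate to
zero until an evaluation contract is attached; a model may declare other
registered models as imports and call them.

## Structure factors

Hard-sphere fluid in the Percus–Yevick closure (the standard analytic
choice; the closure is a convention of this package, selected for the
"hard sphere" interaction named in the analysis it supports), parameters
R_HS > 0 and volume fraction 0 ≤ fp < 0.74.  Below A = 2qR_HS = 0.05 the
trigonometric form cancels catastrophically in double precision and the
O(A⁴) series of each term is used instead; the two branches agree to
~10⁻⁵ at the crossover and the series is exact in the forward limit
S(0) = (1−fp)⁴/(1+2fp)².

Combining approximations for disperse contributions (⟨·⟩ = number average
over the distribution):

- monodisperse: ⟨F²⟩ S(q);
- local monodisperse: ⟨F² S(q; R_HS x/X0)⟩ — the repulsion radius scales
  proportionally with the particle size, anchored so the user's R_HS
  applies at the location parameter X0 (a documented convention; the
  coupling is not otherwise constrained);
- decoupling: N[⟨F²⟩₁ + ⟨F⟩₁²(S−1)] with ⟨·⟩₁ the normalized average —
  requires the scattering amplitude and raises a clear error otherwise.
  Note that for S < 1 the decoupling intensity is ≥ the monodisperse-
  approximation intensity: by Cauchy–Schwarz ⟨F⟩₁² ≤ ⟨F²⟩₁, so the
  suppression (1−S)⟨F⟩₁² is the weaker one.

The "partial structure factor" and its scaling approximation are not
implemented and raise `NotImplementedError`.

## Model assembly

Contributions are summed with sign −1 when marked subtracted (the model
may then go negative — fine for display, and the fit simply sees the
residuals); disabled contributions are equivalent to removed ones; "fixed"
is purely a fitting flag.  A constant background term (default 0) is
included because absolute-scaled experimental curves commonly need one.
Model configurations serialize to plain-text key = value project files.

## Fitting

χ² = Σ[(I_exp − I_model)/σ]² is minimized by Levenberg–Marquardt
(MINPACK via scipy), tolerances: relative step 10⁻⁸, relative χ² decrease
10⁻¹⁰, ≤ 500 iterations per parameter — fixed conventions of this package.
Derivatives for the covariance report are central differences with
relative step 10⁻⁶ (purely relative: parameter magnitudes span ~30 orders
between the scale N and a radius), since registered models are black
boxes.

Two bound modes: the default *interrupt* mode stops with an error naming
the parameter the moment any active parameter leaves its range (including
a start outside it); the opt-in *bounded* mode maps two-sided finite
ranges through p = lo + (hi−lo)(sin t + 1)/2 and optimizes in t, so bounds
cannot be violated.

**Reports.**  χ²_red = χ²/(N−M); Q factor = Q((N−M)/2, χ²/2), the
regularized upper incomplete gamma — the probability that random data of
this size would give a χ² at least as large (N−M degrees of freedom,
consistent with the χ²_red denominator); R = Σ|I_exp − I_model|/Σ|I_exp|
and wR = √(Σw ΔI²/Σw I_exp²) with w = 1/σ².  The covariance C is the
inverse of the Gauss–Newton Hessian JᵀJ of the weighted residuals;
stderr_i = √C_ii; cc_ij = C_ij/√(C_ii C_jj); pairs with |cc| > 0.95 are
flagged.  Degeneracy is judged on the correlation-normalized Hessian (raw
eigenvalues are meaningless across 10⁶⁰ scale disparity): a relative
eigenvalue below 10⁻¹² marks the parameters spanning the null direction,
their stderr is reported undefined (NaN), and the correlation matrix is
computed from a minimally ridged Hessian so the |cc| → 1 entries remain
visible.  Every report repeats the caveat that standard errors assume
independent, normally distributed errors and uncorrelated parameters.

**Stepwise workflow.**  `three_step_workflow` expresses the recommended
procedure as data: (1) scale N on the first fifth of the points (low q),
(2) X0 on the central 30–70%, (3) N and X0 over the first two-thirds,
then X0 with the width s on the central part, and a concluding joint
(N, X0, s) refinement over the full window — the "repeat until good
overlap" cycle collapsed into one final step, which also makes the
reported uncertainties include the N–X0–s correlations.  Windows are
chosen by point index on the (log-spaced) grid.  The workflow runs in
bounded mode by default with generous auto-bounds around the current
values.

## Physics layer

X-ray SLD = r_e (ρ N_A/M) Σ n_i f1_i(E) with f1 = Z + f′(E).  A compact
table of real dispersion corrections f′ at the Cu Kα energy (8.042 keV,
matched within 0.15 keV) is embedded for H, C, N, O, F, Na, Mg, Al, Si, P,
S, Cl, K, Ca, Ti, Fe, Cu, Zn and Au — standard published single-energy
values.  At other energies the calculation falls back to f1 = Z with a
warning; at 8.042 keV the correction moves the SiO₂ SLD by ≈ +1.1%, so it
is applied by default.  A large |f′|/Z triggers a near-edge warning, since
single-energy tabulations are unreliable there.  Neutron SLDs are out of
scope.

The fitted scale converts to a number concentration by dimensional
analysis of I = N(ΔρV)²: with intensity in units 10^a cm⁻¹, SLD in
10^b cm⁻², and lengths carried in the q unit (10^l cm), the factor to
particles cm⁻³ is exactly 10^(a − 2b − 6l) — e.g. 10⁴² for
(cm⁻¹, nm⁻¹, cm⁻²) and 10⁴⁸ for the Å or SI triples.  From there:
molar concentration = N·10³/N_A; volume fraction = N⟨V⟩ (⟨V⟩ converted to
cm³ from the distribution's length unit); mass fraction = volume fraction
× ρ_particle/ρ_solvent, with the solvent density defaulting to 1 g cm⁻³
(aqueous).

## Synthetic data

The generator emulates absolute-scaled SAXS of dilute nanoparticle
dispersions: model intensity on a log-spaced grid of 500 points in
q ∈ [0.057, 3.0] nm⁻¹ (the measured range of the reference data sets) with
heteroscedastic Gaussian noise σ(q) = max(floor·I, counting·√I), default
floor 2% relative and no counting term.  Gaussian — not Poisson — noise
matches the normality assumption behind the χ² weighting and the
standard-error interpretation.  The gold-like default truth is
N = 7.68×10⁻³⁰ (fitted units), X0 = 4.48 nm, s = 0.44 nm,
η = 1.13×10¹² cm⁻².  What the generator does *not* emulate: instrument
resolution smearing, slit geometry, detector artefacts, non-Gaussian
count statistics at high q, and background mis-subtraction — so passing
recovery tests demonstrate the estimator and its uncertainty model, not
robustness to instrumental systematics.

With this matched noise the fit statistics are exactly calibrated: χ²_red
concentrates around 1 (sd √(2/(N−M))) and the Q factor is uniform on
(0, 1), so over replicates its median sits at 0.5 by construction — a
useful property to keep in mind when reading Q-factor expectations stated
for real (never perfectly matched) data.

## Batch processing and export

Batch jobs glob a directory, sort matches (results independent of
filesystem enumeration), fit every file with the same starting model, and
record per-file failures without aborting; the output table carries the
seed, package version and an input digest per file for traceability.  The
parameter export is semicolon-separated with three columns for the size
distribution, three for the form-factor settings and three reserved for
the structure factor (empty when none is configured), followed by a block
with the distribution moments.  Values are written at full shortest-repr
precision so a re-import reproduces them bit for bit.

## Known limitations

- Single data set per fit; no simultaneous multi-curve (contrast
  variation) fitting.
- No resolution smearing/desmearing; curves are assumed pre-scaled to
  absolute intensity.
- The form-factor catalogue is the representative set (sphere, branched
  polymer, templates), not a comprehensive library.
- The f′ table covers one energy well; elsewhere the Z-only fallback is
  ~1% low for light-element materials.
- The untruncated-Gaussian moment convention becomes questionable for
  broad distributions (s/X0 ≳ 30%), as does the number-weighted approach
  itself.
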