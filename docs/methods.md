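# Methods

## Scope and data model

The package operates on species-level trait records: body length B and
width W [µm], swimming speed U [µm s⁻¹], appendage count N, flagellum
length L, wavelength λ, amplitude/helix radius h, wave count n_w, beat or
rotation frequency f [cycles s⁻¹], cilium length ℓ, spacing d and areal
density κ. Printed cells are parsed into a `Quantity` holding a point
value, an optional standard deviation, an optional range and an
upper-bound flag, exactly as printed; nothing is converted at parse time.

Internal units are µm, s, kg m⁻³ for density and mPa·s for viscosity.
These combine so that ρUB/η × 10⁻⁹ is the dimensionless Reynolds number,
η·U·ξ² [mPa·s · µm/s · µm²] is directly a torque in pN·nm, and
mPa·µm² = 10⁻³ pN; the three conversion constants are module-level and
exercised by the printed-value tests.

**Collapse policy.** Models need one number per trait. The default
precedence is: reported mean, then midpoint of the printed range, then the
upper bound (only when nothing else exists). The source tables do not state
how ranges were collapsed for their derived figures, so the midpoint rule
is this package's own convention; every estimate records which rule fired
so outputs stay auditable. Frequencies are stored as cycles s⁻¹ and
converted to angular rates by an explicit 2π inside the models.

## Fluid and body geometry

The default medium is water at 25 °C, ρ = 997 kg m⁻³ and η = 0.89 mPa·s —
the standard handbook values at that temperature, which also reproduce the
published Reynolds table and torque bounds to printed precision (asserted
in the constants test). Bodies are prolate spheroids with eccentricity
e = √(1−(W/B)²). The translational drag correction

C_FB = (8/3)e³·[−2e+(1+e²)ln((1+e)/(1−e))]⁻¹

is 0/0 at e = 0; below e = 10⁻⁴ a Taylor series
C_FB = 1/(1+⅖e²+(9/35)e⁴) is used, and e is clipped at 1−10⁻¹² against the
logarithmic divergence. The surface area S and the tangential moment
I_t = 2π∫(r²sin²θ − r r′ sinθ cosθ)dθ use the closed form and adaptive
quadrature (absolute and relative tolerance 10⁻¹⁰) respectively; both are
cross-checked in the tests against independent surface-metric quadrature
at 10⁻⁸ relative tolerance.

## Bacterial resistive-force theory

The filament resistance coefficients follow the classical slender-body
forms; the full 2×2 force/torque balance is solved linearly and returns
the signed solution (driving a right-handed helix at ω > 0 gives U < 0,
Ω < 0 and T_m > 0 in the chosen frame; magnitudes are exposed alongside).
The body's rotational drag about its long axis, b22, is not needed by any
published-facing output (U/T_m is provably independent of it); a standard
prolate-spheroid closed form is supplied as the default so the full system
can be solved and its balance residuals verified.

The per-species torque estimator uses the simplified morphological
relation with the pitch angle fixed at π/4 and filament radius b = 0.01 µm
(2b = 0.02 µm for the effective bundled filament; the dependence is only
logarithmic). The ln(L/b)+½ form follows from substituting c∥ ≈ c⊥/2; the
derivational variant through c∥ directly (ln−½) is exposed as
`morphological_factor_variant` for sensitivity analysis but is not used by
the reference estimates. Records missing any of B, W, L, h, U are skipped
with a structured reason rather than imputed — the torque analysis is
restricted to fully characterised morphologies.

## Planar-wave propulsion

The thrust element of a beating flagellum, derived from the anisotropic
local drag balance, carries a 1/√(1+A²) weight (A the local slope): the
two slope projections contribute 1/(1+A²) and the arc element
δs = √(1+A²)δx one factor back. The period-averaged integrals are
therefore

Λ = ⟨√(1+A²)⟩, I1 = ⟨A²/√(1+A²)⟩, I2 = ⟨(1+2A²)/√(1+A²)⟩ = I1 + Λ,

evaluated by adaptive quadrature and cross-checked against the complete
elliptic integrals (Λ = (2/π)√(1+a²)E(m), I1 = Λ−(2/π)K(m)/√(1+a²),
m = a²/(1+a²)). The cos 2α-neglect approximations Λ ≈ √(1+a²/2),
I1 ≈ (a²/2)/√(1+a²/2), I2 ≈ (1+a²)/√(1+a²/2) preserve I2 = I1+Λ and stay
within 13% of exact for all h/λ < 1 (worst case ≈12.6%, I1 near a ≈ 3.6)
— both facts are asserted in the acceptance tests. Note that resolving the
integrals with a first-power denominator instead would both violate the
13% bound (20.7% near a ≈ 2.2) and fail to reproduce the explicit speed
formula, which is why the √ form is the one implemented.

Speed prediction offers two modes: `exact` solves the thrust balance with
quadrature integrals and is the reference; `approx` is the explicit
closed-form formula (the two agree within the propagated 13% budget; for
the reference geometry in `analysis/03` they differ by 5.4%). Imputation
rules: missing W is filled from the group-average aspect ratio (0.60 for
flagellates, 0.47 for sperm); one missing wave parameter among {λ, h, n_w}
is recovered by bracketed root-finding on the wave-count relation
n_w = L/(λΛ(2πh/λ)) — unique on the physical branch because Λ is strictly
increasing — with structured failure when no admissible value exists;
sperm force N = 1; filament radii default to b = 0.2 µm (both groups, the
sperm value being quoted as thickness 2b = 0.4 µm). Steepness beyond
a = 2π is allowed but flagged, since the accuracy statement does not cover
it. Hydrodynamic interactions between flagella are neglected (thrust is
additive in N).

## Ciliary models

Cilia are assumed uniformly distributed over the body surface (no bald
spots), acting along the polar tangent with no tilt. Model A (constant
stress τ) and model B (constant per-cilium force F) are algebraically
identical under τ = FN/S and are implemented independently, with the
identity asserted. The cilia count resolves as: explicit N, else κ·S, else
S/d² (nearest-neighbour spacing rule); when both N and κ are present a
consistency warning fires if they disagree by more than 50%, and a
wide-uncertainty flag is attached when a collapsed κ range spans more than
threefold. Model C fixes the sign convention so that rearward tangential
surface flow yields positive (forward) swimming; the reciprocal-theorem
quadrature and the closed-form eccentricity factor agree to 10⁻⁸, and the
classical sphere-squirmer limit U = (2/3)·first-mode amplitude is
recovered at e → 0.

The inverse estimators divide the observed collapsed speed by the
model-specific geometric factor. A genuinely zero observed speed returns a
zero estimate with a warning rather than a skip.

## Synthetic cohorts

The generator emulates the comparative-database structure: log-normal body
lengths and swimming speeds parameterised by moment inversion from the
published per-group mean ± s.d. (e.g. ciliates 194.87 ± 207.45 µm,
1147.57 ± 1375.64 µm s⁻¹), truncated-normal aspect ratios on (0, 1], and
appendage geometry scaled to the body (flagella ≈2× body length, sperm
≈5×, cilia ≈8% of body length, wavelength ≈0.45L, amplitude ≈0.12λ — the
scales seen across the respective groups). Log-normal marginals match the
strong right skew of the real histograms; what the generator does **not**
emulate is phylogenetic correlation between species, trait–trait
correlations beyond the body-scaling above, or measurement error structure
of individual studies — so recovery tests validate the estimators'
algebra and robustness to multiplicative noise, not database-wide
inference. All draws derive from a single integer seed through per-field
child streams; identical seeds give identical cohorts.

`forward_observe` fills speeds from a chosen forward model at known
ground truth (shared value or per-record log-uniform range) with optional
multiplicative log-normal noise of specified coefficient of variation,
mean-one by construction. At zero noise every estimator inverts its
forward model to 10⁻¹⁰ relative; at 20% noise and n = 500 the cohort
median recovers the truth within 5% (both asserted).

## Pipeline conventions

Cohort envelopes (min/max with arg-species) are computed over non-skipped
estimates only and are order-invariant; group summaries use the arithmetic
mean and the n−1 sample standard deviation (the sources do not state their
estimator; n−1 is the standard choice and is documented here). Problem
sizes in the shipped analyses — 10-record fixture cohorts, 200–500-record
synthetic cohorts, 1000–2000-point steepness grids — were chosen as the
smallest sizes at which the asserted statistics are stable.

## Known limitations

Spirochaete and Spiroplasma body-wave mechanics, helical (3D) eukaryotic
beats, mastigoneme-bearing flagella, metachronal-wave phase dynamics and
cilium stroke-cycle structure are outside all three model families.
Per-species reproduction of derived quantities that depend on the source
tables' unstated range-collapse choices is possible only where the printed
traits are unambiguous (several per-cilium forces reproduce at printed
precision; others land within tens of percent). The five-organism Reynolds
fixture stores the unrounded trait-table values, since the printed summary
table rounds its own input column.
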