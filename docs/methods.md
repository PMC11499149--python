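# Methods

## Scope and model

`genpol` implements a general compact-polarimetric (CP) SAR formalism
and the delta-alpha/alpha target decomposition, together with the
downstream machinery needed to exercise them end to end: speckle
filtering, a synthetic multi-temporal scene generator with known
scattering mechanisms, separability-based feature selection, SVM
classification and transmit-ellipse sweep / phenology-curve analyses.
Everything operates on simulated quad-pol data; ingestion of real vendor
products (radiometric/geometric correction, orthorectification) is out
of scope.

### General compact polarimetry

A fully polarized transmit state is a polarization ellipse with
orientation θ ∈ [−π/2, π/2] and ellipticity χ ∈ [−π/4, π/4], with Jones
amplitudes

    a = cosθ cosχ − j sinθ sinχ,
    b = sinθ cosχ + j cosθ sinχ,      |a|² + |b|² = 1.

Backscatter off a pixel with Sinclair matrix S gives the received wave
(aS_HH + bS_HV, bS_VV + aS_VH). For a ≠ 0 and b ≠ 0 the per-channel
normalized vector

    E1 = S_HH + (b/a) S_HV,   E2 = S_VV + (a/b) S_VH

retains the co-polar backscattering characteristics. The classic π/4
mode (45° linear transmit) and CTLR mode (right-circular transmit,
linear receive) are the special cases (π/4, 0) and (0, −π/4): their
textbook scattering vectors equal the received wave at those angles, so
the general path reproduces them exactly after per-channel normalization
by (1/a, 1/b). Pure-H and pure-V transmits (b = 0 or a = 0) are rejected
explicitly — the normalization is singular there, and the guard is
|a|, |b| > 1e−8.

Second-order statistics are ensemble averages of vector outer products:
the 3×3 Pauli coherency T3 for quad-pol data and, for CP data, the 2×2
covariance C2 = ⟨k₁k₁*ᵀ⟩ with k₁ = (E1, E2) and coherency
T2 = ⟨k₂k₂*ᵀ⟩ with k₂ = (E1+E2, E1−E2)/√2. C2 and T2 share their trace
exactly. The ensemble average ⟨·⟩ is a sliding boxcar of odd side
(default 7, the same scale as the Lee preprocessing filter) with
reflective edge padding, or a global mean (`window=None`) when a single
large-sample estimate is wanted.

### The decomposition

For quad-pol data the mechanism angle is the rotation-invariant

    alpha_B = arctan((T22 + T33) / T11) ∈ [0°, 90°],

0° for odd-bounce (surface), ≈45–65° for volume mixtures, 90° for
even-bounce scattering. The randomness parameter is the gap to the
"ideal" angle implied by the co-polar ratio alone:

    rho_r = sqrt(⟨|S_VV|²⟩/⟨|S_HH|²⟩) · exp(j·arg⟨S_VV S_HH*⟩),
    alpha_0 = arctan(|rho − 1|² / |rho + 1|²),
    delta_alpha_B = alpha_B − alpha_0.

The CP analogue uses alpha_BCP = arctan(⟨|E1−E2|²⟩/⟨|E1+E2|²⟩) and the
channel statistics rho_cp, r_cp, phi_cp of (E1, E2). Coherent
single-mechanism ensembles give delta = 0; mixtures whose co-polar phase
sits near π (even bounce) give delta < 0, near 0 (surface/volume
mixtures) delta > 0.

Numerical conventions: the ratio angles are computed with `arctan2`, so
x/0 with x > 0 maps to 90° and 0/0 is masked invalid (NaN + validity
mask — never silently 0°, which is a physical surface answer). |ρ| is an
amplitude ratio (square root of the power ratio), and the mean co-polar
phase is the circular mean arg⟨S_VV S_HH*⟩, which is wrap-robust, rather
than an arithmetic mean of wrapped per-pixel phases. Angles are reported
in degrees; internal math is in radians.

The closed-form expansion of alpha_BCP in (rho_cp, r_cp, phi_cp) is
provided as a diagnostic (`expansion_consistency`), not a compute path.
Its damping factor admits two typeset readings; with (1 − |r_cp|) the
expansion is algebraically identical to the direct T2 form (both reduce
to (1 + |ρ|² ∓ 2|r||ρ|cosφ) after normalizing by ⟨|E1|²⟩), so the
reported deviation is floating-point noise, while the alternative
(1 − |ρ_cp|) reading genuinely deviates and is reported alongside. The
direct T2 form is authoritative throughout.

## Speckle filtering

`boxcar` is the plain sliding mean (it also realizes ⟨·⟩). `lee_filter`
is the classic local-statistics MMSE filter for intensity-like rasters:
with local mean m, local variance v and L equivalent looks,
k = max(0, v − m²/L)/v and y = m + k(x − m). Two wrappers cover the two
places a practitioner applies it: `lee_filter_scattering` filters
per-channel intensities and rescales the complex amplitudes (phase
preserved — smoothing the zero-mean complex channels directly would
annihilate the signal, not despeckle it), and `lee_filter_field` filters
Hermitian matrix entries with a single span-derived gain per pixel so
diagonal and off-diagonal entries share one smoothing decision and the
matrices stay PSD. Both the filter-then-form-matrices and the
boxcar-after-formation orders are therefore available; the default
pipeline filters first. `estimate_enl` is mean²/variance over a
homogeneous region (≈1 for single-look, ≈L after L-look averaging).

## Synthetic scenes

Pixels are fully developed speckle: i.i.d. zero-mean circular complex
Gaussian lexicographic vectors (S_HH, √2·S_HV, S_VV) with a prescribed
3×3 covariance C3 (so window averages follow Wishart statistics), with
S_VH = S_HV exactly. Rank-deficient covariances (coherent targets) are
handled by an eigendecomposition square root. The generator is
deterministic given an integer seed (numpy PCG64).

Class covariances are scattering-mechanism mixtures: power fractions
(f_surface, f_double, f_volume) summing to 1, a co-polar power ratio g,
and a co-polar coherence c. Surface and double-bounce parts are co-polar
blocks with coherence +c and −c respectively (the ±π phase signature of
an even bounce count); the volume part is the azimuthally symmetric
random-volume matrix with decorrelated equal-power co-polar channels and
one third of the power in cross-pol. Note an exact consequence of that
volume model: the HV term leaks coherently into both E1 and E2, so
pure-volume alpha_BCP is wave-dependent (26.6° at π/4 linear, 63.4° at
circular) — mid-range, but exactly 45° only for fully decorrelated
channels without cross-pol (C3 = diag(1, 0, 1)/2), which is the
construction used for the volume-limit benchmark.

The default study area mimics a six-date field campaign over five
classes — water, urban, shoal naked land (SNL), transplanted hybrid rice
(T-H) and direct-sown japonica rice (D-J) — with 8/8/8/28/14 parcels per
class on a 178×200 grid. Labeled parcels are 12×12 cores of larger
same-class fields (4-pixel margins): survey parcels sit well inside
fields, so a 7×7 estimator window on a labeled pixel must see pure class
statistics, not parcel/background mixtures. Parcels alternate between
training and verification within each class (50/50, disjoint).

The default phenology schedule fixes, per class and date, one mixture:

* water: pure specular surface every date (alpha_B ≈ 0.6°);
* urban: double-bounce dominated every date (≈81°);
* SNL: rough moist surface, co-polar ratio 1.5 (≈25°);
* T-H: surface-dominated seedlings over flooded ground (≈10°), rise to
  elongation (≈61°), slight booting dip (≈55°), plateau through
  maturity, then harvest reverts to bare soil (≈16°);
* D-J: the same shape from moist-soil seedlings (≈18°) but **no**
  harvest drop (still standing on the last date, ≈57°).

These fractions were chosen once, analytically, from the closed-form
alpha_B of each mixture so that the trajectories realize the qualitative
crop narrative (rise / dip / plateau / asymmetric harvest); they are
tunable configuration, and no test asserts the specific default values
as ground truth — tests assert orderings and analytic limits. What the
generator deliberately omits: incidence-angle and topographic effects,
soil-moisture dynamics, row-structure azimuth modulation, texture
(non-Gaussian speckle) and inter-date correlation. Passing tests
therefore demonstrate the correctness and internal consistency of the
method chain under ideal mixture statistics, not classification skill on
real imagery.

## Classification and analyses

Features are per-date alpha and delta-alpha rasters of a chosen mode
(quad-pol, π/4, CTLR, or an arbitrary ellipse), named
`alpha_B_<date>` / `dalpha_B_<date>`. Separability between the two rice
classes is the "difference degree" — implemented as the standardized
mean difference |m_a − m_b|/√(v_a + v_b) on training pixels, a pluggable
metric (the field also uses Jeffries–Matusita or histogram overlap).
Ranking is deterministic with lexicographic tie-breaks; the default
selection keeps the top 8 features.

The classifier is an RBF-kernel SVM with C = 100 and gamma equal to the
reciprocal of the number of input features, applied at native pixel
resolution with probability threshold 0. Features are z-scored with
training statistics before fitting (the angle features span different
ranges). Both a single five-class pass and a two-stage scheme (four
classes with rice merged, then a rice-only split) are provided.

Accuracy on verification parcels: confusion matrix with reference in
rows, producer's accuracy PA = diag/reference counts, user's accuracy
UA = diag/prediction counts, average accuracy (PA + UA)/2, overall
accuracy OA and kappa = (OA − p_e)/(1 − p_e) with the standard chance
agreement p_e. Classes absent from the verification set are reported as
NaN, not dropped.

`parameter_sweep` evaluates the decomposition on a grid of one transmit
angle with the other fixed (χ ∈ [−π/4, π/4] at fixed θ, or
θ ∈ [−π/2, π/2] at fixed χ), recording grid points excluded by the
singular-transmit guard (at χ = 0 these are θ = 0 and ±π/2).
`temporal_curves` reduces six-date decompositions to per-class mean
trajectories with rise/drop/flat flags (threshold 2°).

## Problem sizes and statistical checks

Benchmarks and tests run at desk scale: Monte-Carlo limits use 10⁵
single pixels, covariance-recovery checks 10⁴–10⁵ pixels, and the
end-to-end chain the 178×200 six-date scene (≈2×10⁵ decomposed pixels
per mode); the whole suite completes in well under a minute. One
statistical subtlety: the global alpha_B estimate from 10⁴ speckle
pixels has a standard error of ≈0.4° for mid-range mixtures (measured
empirically; the estimator is unbiased), so the 0.5° parameter-recovery
bound is asserted on the median absolute error over independent
10⁴-pixel replicates rather than on a single draw, which would fail with
≈20% probability for any seed.

## Known limitations

* The scene model is pixel-wise Gaussian with stationary per-parcel
  statistics; no texture, autocorrelation, or mixed pixels at parcel
  interiors.
* The decomposition's volume response depends on the assumed volume
  covariance; other canopy models shift the mid-range angle.
* Accuracy figures obtained on the synthetic scene characterize the
  pipeline under separable ideal conditions and say nothing quantitative
  about real sensor data.
* Only monostatic, reciprocal scattering is handled; the dual-circular
  CP mode and pseudo-quad-pol reconstruction are not implemented.
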