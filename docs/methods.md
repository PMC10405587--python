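# Methods

`sasbead` simulates solution small-angle scattering (SAS) from particles
assembled out of geometric subunits, the way Monte Carlo "bead model"
calculators do: the particle becomes a cloud of point scatterers, and every
observable is derived from the contrast-weighted pair distances of that
cloud.  This note records the model, the numerical choices, and what the
package's own synthetic data can and cannot tell you about real experiments.

## Bead representation

A particle is an ordered list of subunits (sphere, triaxial ellipsoid,
cylinder, disc, cube, cuboid, hollow sphere, hollow cube, cylindrical ring,
discoidal ring), each with dimensions in Å, an excess scattering-length
density ΔSLD (contrast against the solvent, unitless here — no absolute
cm⁻¹ calibration is attempted) and a center-of-mass displacement.  Points
are drawn uniformly inside each subunit by rejection sampling from its
bounding box, which is exactly uniform for every supported shape.  The
total point budget N (default 3000) is split across subunits proportionally
to their analytic volumes by the largest-remainder rule, so the point
density is constant and each point carries the same effective volume
V = ΣV_i/N and excess scattering length Δb = ΔSLD·V.

Overlaps are resolved by precedence: points of a later subunit that fall
inside an earlier one are deleted, not resampled.  Deletion keeps the
density exactly uniform in the surviving region and makes multi-contrast
particles (core–shell bodies) constructible from overlapping primitives.
After deletion, the particle volume used for the forward scattering is
V_p = V·N_kept, the volume the retained points actually represent.
Containment is boundary-inclusive; subunits translate but do not rotate.

The point cloud can be exported as pseudo-atom PDB (one carbon per point),
which standard structure viewers read; the fixed-width serial field caps
exports at 99 999 points.

## Scattering

The normalized intensity of dilute, randomly oriented particles is the
orientation-averaged Debye double sum over scatterers.  Binning the
N(N−1)/2 unordered pair distances into M bins (default 200 over [0, D_max])
reduces it to a single sum,

    I_norm(q) = Σ_i p_i sinc(q r_i) / Σ_i p_i ,

with p_i the sum of Δb_j·Δb_k over pairs in bin i.  Self terms (j = k) are
excluded — they vanish in the continuum limit — and p(0) = 0 is prepended
to the output p(r), which is normalized to unit maximum.  sinc is evaluated
through `numpy.sinc`, which handles qr → 0 exactly.  Pair distances are
accumulated in row blocks of 512, so memory stays O(block·N) and models of
10⁴–10⁵ points are feasible.

D_max is reported as the largest *sampled* pair distance; it underestimates
the true support by O(N^(−1/3)) (≈ 1 Å at N = 3000 for a 100 Å particle).
R_g comes from the histogram second moment, R_g² = Σp_i r_i²/(2Σp_i + ΣΔb²);
restoring the self-term ΣΔb² in the normalization (equal to making the
denominator (ΣΔb)²) removes an O(1/N) bias and makes exact small cases
(two-point dumbbell: R_g = d/2) come out right, while converging to the
classic continuum formula.

Default q grid: 400 logarithmically spaced points in [10⁻³, 0.5] Å⁻¹, a
typical synchrotron SAXS window.  With 200 bins the binning error lies
below the point-sampling noise at N = 3000.

**Accuracy and its floor.**  The method carries an intrinsic Monte Carlo
noise floor of order 1/N in I_norm (≈ 2·10⁻⁴ at N = 5000).  Away from
form-factor zeros a 5000-point sphere reproduces the analytic curve to a
few percent up to q ≈ 0.2 Å⁻¹; *at* the zeros of high-symmetry shapes
(where the analytic intensity drops below 10⁻⁵) the relative deviation is
unbounded — no bead model at practical N resolves a true zero.  Tests
assert tight agreement where the curve is above the noise floor and treat
the zero neighborhoods as out of reach by construction.

## Polydispersity

Gaussian size polydispersity is a scale factor s ~ N(1, σ_s²) applied to
all distances (r → s·r), truncated to [1 − 3σ_s, 1 + 3σ_s] (σ_s < 1/3 keeps
scales positive).  Each size is weighted by G(s; 1, σ_s)·s⁶: the s⁶ = v_s²
factor accounts for scattering growing with the squared particle volume
(exact for isotropic scaling).  The ensemble average is a 21-node trapezoid
quadrature over s — the integrand is smooth, and 21 nodes agree with a
5000-draw Monte Carlo average to < 0.5% in the tests.  Rescaling the
*histogram* (bin centers r → s·r, weights unchanged) is exactly equivalent
to rescaling the point cloud and costs O(M) per size.  The ensemble p(r) is
averaged as a density on a common grid, p_s(r) = p(r/s)/s, with the same
weights.  I_norm is normalized after averaging, so the ensemble curve has
I_norm(0) = 1.

## Structure factors

At finite concentration the measured intensity is modulated by S(q).  Two
analytic choices are provided:

- **Percus–Yevick hard spheres** (repulsion), parameters R_hs (Å) and
  volume fraction η ∈ (0, 0.74): the standard closed form in A = 2qR_hs
  with coefficients α, β, γ in η.  The A → 0 branch switches to the series
  limit (G/A → α/3 + β/4 + γ/6) below A = 10⁻³, reproducing the
  compressibility limit S(0) = (1−η)⁴/(1+2η)² to 10⁻⁶.
- **Fractal aggregates** of dimension 2: S_agg(q) = 1 + (N_agg − 1)/(1 +
  (qR_eff)² N_agg/3), mixing linearly with a free-particle population via
  the aggregated fraction.  S_agg(0) = N_agg, S_agg → 1 at large q.

For non-spherical or multi-contrast particles the spherical S(q) is applied
through the decoupling approximation, S_eff = 1 + β(q)(S − 1) with
β = ⟨F⟩²/⟨F²⟩ computed from the point model itself: ⟨F(q)⟩ = ΣΔb_j sinc(qr_j)
with r_j measured from the |Δb|-weighted centroid (robust when the net
contrast is small), and ⟨F²⟩ the unnormalized Debye intensity with self
terms restored.  β is clipped to [0, 1] (it is analytically in that range;
sampling noise near form-factor zeros can push the ratio outside), and
S_eff is floored at 10⁻⁶ so noise cannot produce negative intensities.
β is computed from the monodisperse model even when polydispersity is on —
a documented simplification, as no ensemble recipe is defined here.
Structure factors modify I(q) only; the reported p(r) always describes
non-interacting particles.

## Virtual experiment

1. **Interface roughness**: sharp subunit boundaries are smeared by the
   multiplicative factor exp(−(qσ_rough)²) on the *intensity* (i.e.
   exp(−(qσ)²/2) per amplitude; both conventions exist in the literature —
   this one is fixed here and configurable in the sense that σ_rough is the
   only knob).  p(r) is untouched.
2. **Forward scattering**: I(0) = η(ΣΔb_j)²/V_p in arbitrary units — linear
   in volume fraction η (default 0.01, a dilute biological sample),
   quadratic in contrast; for a uniform particle it reduces to ηΔρ²V_p.
3. **Noise**: an empirical SAXS error model assigns
   σ²(q) = (I(q) + c)/(k·q·t) with relative exposure t (t = 1 resembles a
   synchrotron exposure; t ≈ 0.1 a laboratory source — σ ∝ 1/√t exactly)
   and calibration constants c = 0.85, k = 4500 in the model's intensity
   units.  The form captures counting-statistics growth with I, a
   background-dominated floor at vanishing intensity, and the ~1/q solid
   angle of isotropic azimuthal averaging.  The constants were chosen so a
   lysozyme-like dilute-protein curve at default η shows percent-level
   low-q errors, and are exposed in the config for recalibration.
4. **Sampling**: I_sim(q) ~ N(I(q), σ(q)²), independent per point; negative
   draws are kept, as in real background-subtracted data.

## Analytic reference models and fitting

Closed-form, orientation-averaged form factors (sphere; cylinder; ellipsoid
of revolution; core–shell cylinder) serve as the validation surface.
Anisotropic shapes are averaged by 64-node Gauss–Legendre quadrature over
cos α, which matches a 512-node reference to 10⁻⁴ relative over the default
q range.  All models are normalized to P(0) = 1 and evaluated as
I = scale·P + background.

`fit_weighted` minimizes Σ[(I_sim − I_model)/σ]² with a bounded
Levenberg–Marquardt minimizer (lmfit), multi-started from the supplied
model and two jittered copies to escape the shallow minima caused by
contrast–scale correlation.  σ are treated as absolute errors, so standard
errors come directly from the weighted least-squares covariance (doubling
every σ doubles them).  Scale and background stay free unless explicitly
fixed.

**Parameter-recovery experiment.**  The end-to-end check simulates a
core–shell cylinder (core radius 20 Å, core length 360 Å, shell thickness
20 Å, contrasts −1/+1) at N = 3000, with default grid and noise, and fits
the analytic core–shell cylinder with the core contrast fixed at −1
(freeing both contrasts and the scale is degenerate).  Fits are performed
over the full simulated q range with free scale and background.  Across
independent simulations the recovery is unbiased at the construction
values; the per-simulation scatter (sd ≈ 0.4 Å on the core radius, ≈ 0.065
on the shell contrast at N = 3000) comes from bead-sampling noise, which
also dominates the fit residuals (reduced χ² ≫ 1 because the error model
describes measurement noise, not discretization error).  The same particle
can be built from four non-overlapping subunits or from two overlapping
cylinders with precedence deletion; both routes give p(r) curves agreeing
within Monte Carlo noise, and intensities agreeing except in the immediate
neighborhood of the deep minimum near q ≈ 0.18 Å⁻¹, where the noise floor
dominates (see "Accuracy and its floor").

## What the synthetic data do not emulate

Instrumental resolution smearing, incoherent background and multi-setting
merging (all prominent in SANS), absolute-scale calibration, atomic form
factors, interparticle effects on p(r), polydispersity in a single
dimension, and 2D detector images.  Passing tests therefore demonstrate the
internal consistency of the Debye/bead machinery and the error model's
statistical self-consistency — not agreement with any specific instrument.

## Degenerate inputs and tie-breaks

Hollow/ring kinds require inner < outer; point models need ≥ 2 points for a
histogram and nonzero Σp for normalization; R_g and β are undefined at zero
net contrast and raise; disc and discoidal ring are parameter aliases of
cylinder and cylindrical ring (no distinct mathematics; the names express
intent).  Boundary containment is inclusive, fixed for determinism.  All
randomness flows through one seedable NumPy generator per model run; the
run orchestrator derives per-model streams from (seed, model index), so
outputs are byte-identical across reruns and independent of model order.

## Problem sizes used in the shipped checks

Unit and end-to-end tests run at N = 500–10 000 points, 200–400 bins, and
20 repeat simulations for the recovery experiment; the reproduction script
averages 100 repeats at N = 3000.  These sizes put sampling error well
below the assertion tolerances while keeping the whole suite inside a few
minutes on one core.
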