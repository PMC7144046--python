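# Methods

`icrsplan` models the planning problem of intracorneal ring segment (ICRS)
surgery for keratoconus: given the anterior corneal surface of an eye,
which one- or two-segment configuration (family, arc length, thickness,
bisecting line) yields the best postoperative optical quality?  The
package contains five scientific layers — Zernike surface representation,
Fourier PSF optics, clinical metrics, a trainable feedforward surrogate of
the implant effect, and an exhaustive planner — plus a synthetic-cornea
module that provides the training and validation population in place of
clinical data, and file/CLI plumbing.

## Surface representation

Anterior elevation maps are heights in μm (sag convention, posterior
positive) on a uniform rectangular mm grid.  They are decomposed into
Zernike polynomials up to radial order 7 (36 terms) over an 8 mm aperture
by linear least squares (`numpy.linalg.lstsq`, orthogonal decomposition —
the normal equations are never formed).  Conventions: ANSI/OSA
double-index ordering and unit-variance normalization, so the Euclidean
norm of a coefficient vector is the surface RMS over the pupil and the
clinical aberration groups are sums of squares.  Samples flagged missing
are excluded; a fit refuses to run when more than 20% of the in-aperture
samples are missing or when fewer than three samples per coefficient
remain, and a rank-deficient design raises an error naming the
deficiency.

Coefficients fitted on 8 mm are restricted to smaller apertures (the 6 mm
reporting zone, the 3–4 mm PSF pupils) by an exact linear map computed
per azimuthal frequency from the radial orthogonality of the Zernike
polynomials, with the polynomial integrals evaluated by Gauss–Legendre
quadrature at machine precision.  Rescaling to a *larger* aperture would
extrapolate beyond the data and is refused.

RMS aberration groups at 6 mm follow the common clinical partition:
total = orders 2–7 (piston and tilt always excluded), higher-order =
orders 3–7, astigmatism = (2, ±2), coma-like = all odd orders (3, 5, 7),
spherical-like = (4, 0) and (6, 0).  The residual of the higher-order
group (even-order non-rotational terms of orders 4 and 6) is non-negative
by construction.

## Corneal wavefront and Strehl ratio

A first-surface wavefront is obtained from elevation by multiplying by
the refractive index step Δn = 0.376 (air → stroma).  For PSF purposes
the elevation of an emmetropic reference sphere is subtracted first and
piston/tilt are removed: the raw sag of any cornea contains hundreds of
μm of base-sphere power that carries no image-quality information, and
the reference-relative optical path difference (OPD) is what corneal
topographers report as "corneal aberrations" on the μm scale.  The
reference radius defaults to 7.80 mm (43.3 D, the textbook average
cornea) and is configurable; the synthetic module uses its own
population's emmetropic base (8.30 mm) so that the spherical-equivalent
proxy is centred correctly.

The PSF is computed by Fourier optics: unit amplitude inside the pupil,
phase 2π·OPD/λ, zero-padded FFT, squared magnitude.  The Strehl ratio is
the intensity peak relative to the unaberrated pupil of identical
geometry (on-axis peak definition, not encircled energy).  Defaults:
λ = 550 nm (photopic peak), 256 samples across the pupil, padding ×8,
with sub-pixel parabolic refinement of the sampled peak; a convergence
test shows doubling either grid parameter changes Strehl by < 0.5% for
wavefronts with RMS ≤ 0.25 μm (padding ×4 alone leaves a 1–2% peak
undersampling bias, which is why ×8 is the default).  For *ranking* (the
planner and the batch
scorer) piston and tilt are dropped from the wavefront before the FFT:
piston is invisible and tilt only translates the image, and dropping them
makes the score exactly invariant instead of invariant only up to pixel
sampling.  The low-level `pupil_function`/`compute_psf` pair keeps all
terms so that textbook identities (half-wave piston → field −1) hold
literally.

Numerical caveat: for wavefronts several waves deep (uncorrected
keratoconic eyes) the discrete PSF peak sits on a speckle floor of order
1/N_aperture; Strehl values below ~10⁻³ on the small scoring grids are
regime markers, not converged physical values.  The planner is therefore
normally run in corrected-vision mode (second order removed) at a small
photopic pupil, where candidate Strehl values are well resolved.

The "second-order toggle" implements the choice of optimizing
uncorrected or spectacle-corrected vision: keeping the second order
(defocus + both astigmatisms) ranks candidates by uncorrected image
quality (UDVA); removing it assumes the sphero-cylinder is corrected by
spectacles and ranks by higher-order quality (CDVA).  Which pairing the
original software used is not documented; this assignment is this
package's documented assumption.

## Clinical metrics

Visual acuity converts between decimal and LogMAR scales as
LogMAR = −log₁₀(decimal), rounded half-even to two decimals; one chart
line is 0.1 LogMAR.  Visual-limitation grades I/II/III/IV/Plus follow the
CDVA thresholds 0.90/0.60/0.40/0.20.  Simulated keratometry samples 180
meridians at 1° across the central 3 mm zone (bicubic spline
interpolation of the grid), fits a circle to each meridional height
profile (algebraic Kåsa fit — exact for circular sections) and converts
the radius to diopters with the keratometric index 1.3375
(K = 337.5/R_mm).  K1/K2 are the flattest/steepest meridians.

The success filter marks a treated eye successful when any of three
criteria holds at follow-up: (A) ≥ 1 line (0.1 LogMAR) gained in
uncorrected or corrected acuity, (B) spherical-equivalent magnitude
reduced by ≥ 2 D (movement of the signed SE toward zero), (C) higher-order
or coma-like RMS reduced by ≥ 1 μm.  The threshold in (C) is sometimes
quoted as "1 mm", which is dimensionally impossible for RMS values
tabulated in μm; it is implemented as 1 μm.  Only successful
cases may train the surrogate.  The ectasia-progression criterion
(cross-linking indication) is the conjunction of ≥ 1 D steepening of K2
and ≥ 1 D increase of refractive astigmatism.

## The surrogate network

The implant-effect surrogate is a fully-connected feedforward network
written from scratch: tanh hidden layers, linear output, full-batch
gradient descent on the mean squared error with the classical momentum
update Δw_t = −η∇E + αΔw_{t−1}.  Inputs are the 36 preoperative Zernike
coefficients at 8 mm plus two 10-value segment slots (family one-hot, arc
one-hot within family, thickness/100 μm, bisecting line as (sin a, cos a),
presence flag; the slot of an absent second segment is zero).  Segments
are canonically sorted so encoding is order-independent.  Outputs are the
36 postoperative coefficients on the same aperture.

Two design choices matter:

* **Residual output.**  The network predicts the implant-induced
  coefficient *change*; the preoperative vector is added back at the
  output.  Surgery perturbs the cornea by a few μm against a backdrop of
  hundreds; with cohorts of paper scale (75 cases) a direct
  postoperative-vector network spends its capacity re-learning the
  identity map and generalizes poorly (held-out RMSE ≈ 0.36 of output SD
  in our experiments), while the residual form reaches ≈ 0.16 with the
  same budget.
* **Standardization.**  Inputs and targets are standardized per feature
  from the training set; the statistics are stored inside the model, so a
  saved model is self-contained.

Defaults: one hidden layer of 40 units, η = 0.01, α = 0.9, 2000 epochs,
seeded uniform init scaled by fan-in.  Everything is deterministic given
the seed; training refuses non-success cases and reports divergence (NaN
loss) naming the learning rate.  Models serialize to a versioned JSON
container with byte-identical output for identical training runs.

## The planner

The planner enumerates every candidate: all 8 catalog segments
(SI5-90/120/160/210, SI6-90/120/150/210) × thickness set × bisecting-line
grid, singly and in unordered pairs whose arcs do not overlap on the
ring circle (two 210° arcs can never coexist).  Each candidate's
predicted postoperative elevation is rescaled to the scoring pupil,
converted to reference-relative OPD, optionally stripped of its second
order, and scored by Strehl ratio; scoring is vectorized (batched FFTs)
so thousands of candidates are feasible.  Plans are ranked by Strehl
descending with deterministic tie-breaks: fewer segments, then lower
total thickness, then lexicographic encoding.  A no-implant baseline is
always scored and a `no_benefit` flag is raised when no candidate beats
it — an already-regular cornea should not be operated on.

Defaults: scoring pupil 4 mm (photopic), axis step 15°, thicknesses
{150, 200, 250, 300, 350} μm.  The thickness catalog is a
manufacturer-typical range, not a clinically reported set.  The
axis default is a runtime compromise: at 5° the two-segment candidate
space exceeds 10⁶ PSF evaluations; 5° remains available through the
option for exhaustive runs.  The implant-center choice (corneal vertex,
geometric center, pupil center) translates the map to the requested
landmark before fitting, so the whole prediction chain operates in the
implant-centered frame.

## Synthetic corneas and the mechanistic implant model

No elevation data ship with the package; the synthetic module defines the
study population.  A cornea is a biconic base (per-meridian curvature
from apical radius and astigmatism, shared asphericity Q) minus a
Gaussian cone bulge (an anterior protrusion, which steepens local
curvature exactly as a keratoconic cone steepens keratometry), plus
seeded Gaussian measurement noise.  The default population — base radius
U(8.1, 8.8) mm, Q U(−0.6, −0.1), cone amplitude U(40, 100) μm at
0.4–1.2 mm eccentricity with width U(1.0, 1.6) mm, astigmatism
U(0.5, 3.5) D — was calibrated once against the clinical preoperative
regime this package targets: mean Sim-K ≈ 48 D, SE ≈ −3.4 ± 1.8 D,
higher-order RMS ≈ 3.0 μm, coma-like ≈ 2.4 μm at 6 mm.

The implant effect is a deterministic closed-form kernel in sag space,
per segment, scaled by (thickness/300 μm)·(arc/360°): a central Gaussian
dome (σ = 0.8 × track radius, 45 μm full-scale) that lowers curvature in
the keratometry zone — the central flattening that lowers Sim-K — and an
inner lobe (at 0.35 × track radius, width 1.2 mm, 30 μm full-scale) under
a raised-cosine angular window around the bisecting line, which cancels
part of a cone sitting on that side — the coma reduction.  A 210°/300 μm
segment aligned with the cone lowers mean Sim-K by ≈ 1 D and coma-like
RMS by ≈ 1 μm; two segments roughly double the effect, matching the
surgery-scale changes reported clinically.  This kernel is a smooth,
learnable stand-in for biomechanics, not a mechanical claim; its additive
form (independent of the preoperative surface apart from the attenuation
geometry) is a known simplification.

Clinical proxies close the loop for cohort generation: SE from the
paraxial relation SE = −4√3·c(2,0)/r² applied to the reference-relative
OPD at 6 mm; acuities from the documented monotone stand-in
LogMAR = clip(−0.1·log₁₀ S, −0.1, 1.5) with S the Strehl ratio at a 4 mm
pupil (with second order for UDVA, without for CDVA) plus N(0, 0.02)
measurement noise.  The stand-in is monotone and surgery-responsive; it
does not model neural contrast sensitivity and its absolute grades are
not calibrated to charts.  Cohorts are rejection-sampled: random cornea,
random plausible implant (bisecting line near the cone meridian, 25%
deliberately misaligned so a trained surrogate also sees the penalty of
off-axis segments, 35% two-segment), mechanistic effect, metrics, keep if
successful; an acceptance rate collapse raises an error naming the knobs.

## What passing tests do and do not show

The synthetic pipeline demonstrates that the machinery is correct and
that the surrogate-plus-planner loop recovers near-optimal plans *when
the implant effect is the mechanistic model that generated the training
data*.  Real surgical remodeling is biomechanical, posterior-surface
coupled, and noisier; nothing here validates clinical predictive power.
The proxies (VA from Strehl, SE from defocus) are labelled stand-ins
throughout.  Pachymetry, corneal volume and posterior-surface quantities
are out of scope — they require tomographic data not derivable from
anterior elevation.

## Validating the planner against ground truth

Because the synthetic module knows the true implant effect, the planner
can be validated end to end: plan with the trained surrogate, then score
the chosen configuration with the *mechanistic* model and compare with
the mechanistic optimum over the same candidate grid.  Two regimes are
checked:

* **Predictive skill at clinical cohort size.**  A surrogate trained on
  75 cases with the default hyperparameters predicts held-out
  postoperative coefficient vectors to better than 20% of their spread.
* **Plan fidelity with a converged surrogate.**  Discriminating the top
  of the Strehl landscape (candidates within a few percent of each
  other) demands more precision than 75 cases can pin down — the
  decisive quantity is ~0.1 μm of optical path at a 3 mm pupil.  The
  shipped fidelity check therefore trains a two-seed committee of
  three-hidden-layer residual networks on a 600-case cohort (averaging
  independently seeded runs halves the variance of the learned implant
  response) and verifies that on ≥ 80% of 50 random corneas the planned
  surgery's true Strehl is within 5% of the true optimum, in
  corrected-vision mode at a 3 mm pupil over 8 arcs × 2 thicknesses ×
  30° axis steps.

## Problem sizes used in the shipped checks

The test suite and the reproduction script use deliberately scaled-down
problem sizes chosen as sensible defaults for a desk run: cohorts of
75–100 cases (the clinical training size) for skill checks and 600 for
the plan-fidelity check, PSF grids of 64–256 samples with padding 2–4,
planner grids of 8 arcs × 1–2 thicknesses × 30–90° axis steps, and
500-sample population statistics.  All are configurable upward.
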