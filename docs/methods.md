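# Methods

## The model

`nafsim` simulates and quantifies a single mechanistic claim about ¹⁸F-NaF
PET of vascular calcification: the fluoride ion adsorbs to hydroxyapatite
with one-site kinetics, but only on the mineral surface that the tracer can
reach. In intact tissue a macrocalcific deposit exposes just a thin outer
shell, while microcalcifications (diameter < 50 μm, the conventional cutoff;
macro ≥ 50 μm) are accessible throughout. Because a sphere's shell fraction
1 − ((R−d)/R)³ falls with radius, signal per unit mineral volume is
systematically higher for micro- than for macrocalcification, and a PET
tracer therefore highlights nascent microcalcification that CT cannot
resolve. Sectioning the tissue before incubation opens deposit interiors and
removes the restriction.

Binding follows the standard one-site rate law. During incubation at free
ligand concentration L the bound signal grows as

    B(t) = B_eq · (1 − e^(−k_obs·t)),   k_obs = k_on·L + k_off,

and washes out as B(t) = B₀·e^(−k_off·t). Derived quantities are the
affinity K_D = k_off/k_on and the half-times ln2/k_obs and ln2/k_off. The
default constants are the measured plaque values, k_on = 4.5×10⁹ M⁻¹ min⁻¹
and k_off = 0.0027 min⁻¹, giving K_D = 0.6 pM, an association half-time of
≈14.5 min at the clinical incubation concentration of 10⁻¹¹ M, and a
dissociation half-time of ≈257 min.

Two equilibrium regimes are implemented because the data motivate both and
the package does not adjudicate between them. The default is the *linear
site-excess* regime — bound activity proportional to L — which matches the
observed log–log calibration (slope ≈ 0.92 across 10⁻¹²–10⁻⁷ M). A
*saturable* regime with hyperbolic occupancy L/(L+K_D), the strict reading
of the sub-picomolar K_D, is available behind `saturable=True`. Note that
even in the linear regime strict proportionality to L holds only at
equilibrium: at finite incubation times k_obs itself depends on L, so
doubling L slightly more than doubles the 60-min signal. Tests assert exact
linearity at 20 association half-times.

## Phantoms

Deposits are spheres (discs in 2D) so that every rasterized quantity has a
closed-form oracle; irregular macrodeposit shapes are out of scope. A voxel
is calcified when its center lies in a deposit (closed ball, half-open
domain [0, extent), positions at voxel centers). Deposits are kept pairwise
disjoint with a one-voxel gap — per-deposit ground truth stays unambiguous —
by bounded rejection sampling (1,000 attempts per deposit, then a
`PlacementError` naming the deposit).

Defaults describe an 8 × 8 mm endarterectomy-like section at 5 μm pixels
(10 μm voxels in 3D): 6 macrodeposits with radii 150–1200 μm (the field
describes macrocalcification up to several mm) and 150 microdeposits with
radii 6–24 μm, mineral density uniform in 0.85–1.0. No published number
density or radius distribution exists for plaque deposits; these defaults
are illustrative and fully exposed in the configuration. The phantom has no
vessel anatomy (lumen, media/intima, necrotic core).

The accessible shell is computed with a Euclidean distance transform:
deposit voxels whose center-to-center distance to the nearest non-calcified
voxel is ≤ the penetration depth (deposits no larger than the depth are
taken whole). This slightly *under*-fills the analytic shell (≈ −9% relative
for R = 500 μm, d = 20 μm at 10 μm voxels) and converges as the voxel
shrinks. The penetration depth defaults to 20 μm — one cryosection
thickness, the scale at which surface-restricted binding is resolved; it is
a modeling choice, since no measured value exists.

Sectioning cuts a 3D phantom into serial slabs (default use case: 20 μm
cryosections), conserving every calcified voxel exactly once and recording
per section which deposits are newly opened at its cut faces.

## Imaging

Each modality is a point-spread function plus sampling grid plus noise:
Gaussian blur with σ = FWHM/2.3548, block-average resampling by the integer
factor round(out/in) (zero-padded at the high edge, so total signal is
conserved exactly; the effective grid, factor·truth voxel, is recorded —
e.g. the 22 μm μCT grid renders at 20 μm from 5 μm truth), then Poisson
(PET-like) or additive Gaussian (CT-like, σ = 15 HU) noise with an explicit
seed. Presets: autoradiography 50 μm FWHM @ 25 μm; μPET 900 μm @ 300 μm and
μCT 30 μm @ 22 μm (printed scanner values); clinical PET 4.5 mm @ 2 mm and
clinical CT 0.6 mm @ 0.5 mm (conventional values for the scanner class —
the study does not print them). Sinogram-level effects (scatter, randoms,
attenuation, OSEM/FBP) are out of scope; the PSF stands in for the whole
chain.

Mineral maps render as HU with background 0 (water bath), soft tissue 40,
and mineral 1300 × density, placing all deposits comfortably above the
1,000 HU calcification rule so that partial volume — not the mapping —
governs detectability. At these presets a simulated clinical CT cannot push
any sub-50 μm deposit above 1,000 HU, and even a 300-μm deposit survives
only on μCT: the partial-volume ordering the study turns on.

## Quantification

Thresholding follows the 2D/3D pipelines: Otsu (between-class variance,
256-bin histogram, ties to the lowest cut; delegated to scikit-image) and
Li's minimum-cross-entropy threshold, implemented as the Li–Tam fixed-point
iteration t' = (μ_low − μ_high)/(ln μ_low − ln μ_high) from the image mean,
converged to |Δt| < 1e-4 within 200 iterations (non-convergence raises with
the iterate trace; a zero lower-class mean takes the limit t' → 0). Masks
use strict `>`; the HU calcification rule uses `≥ 1000`. Both thresholds are
tested against exhaustive-search oracles — note that cross-entropy depends
only on the induced partition, so its minimizers form a plateau and
equivalence is asserted against the plateau, not a single value. Li's
objective is not shift-invariant; the scikit-image cross-check therefore
runs on min-shifted images.

The segmentation-mask recipe is threshold → Gaussian blur of the binary
field (σ = 20 *pixels of the analyzed image*; the source pipelines did not
state units, pixels assumed and parameterized) → re-threshold. It absorbs
resolution mismatch between co-registered channels and deletes isolated
positives that are small relative to genuine structures.

Tri-class accounting partitions the union of PET-positive and CT-positive
voxels into PET+/CT−, PET+/CT+, PET−/CT+; percentages use the union as
denominator so the three classes sum to 100. Masks from different grids are
upsampled to the common truth grid by nearest-neighbour repetition before
comparison. Mask correlation is plain Pearson over {0,1} values. Transects
sample both volumes by linear interpolation along a physical line.

## Kinetic and dynamic analysis

Nonlinear fits use Levenberg–Marquardt least squares (scipy `curve_fit`)
with log-linear heuristic starting values (association rate from the first
half-plateau crossing, washout rate from the endpoint log-slope), suitable
for the sparse 5–9-point curves these experiments produce; standard errors
come from the Jacobian covariance at the optimum, no bootstrap. `k_on` is
derived as (k_obs − k_off)/L with k_off either supplied (e.g. from a
separate washout fit) or omitted; both modes exist because the provenance of
the printed k₁ is ambiguous. Amplitudes are free nuisance parameters
throughout (absolute activity units for the binding assays are not defined).

Plasma clearance is biexponential, C(t) = A1·e^(−λ1·t) + A2·e^(−λ2·t) with
λ1 > λ2 > 0. The default (A1 = 0.9, A2 = 0.1, λ1 = 0.25 min⁻¹,
λ2 = 0.00851384 min⁻¹) puts the 60-min plasma activity at 6.0% of peak —
the midpoint of the observed 4–8% range; λ2 is the root of
C(60)/C(0) = 0.06 given the other three values. The plasma-to-whole-blood
partition is folded into a single ratio parameter.

Dynamic studies follow the irreversible-trapping forward model
C_t(t) = Ki·∫₀ᵗC_b dτ + V·C_b(t) on the 28-frame clinical schedule
(12 × 10 s, 4 × 30 s, 12 × 240 s, 52 min). Frame values are duration-weighted
means computed from closed-form integrals of the biexponential — no
quadrature error enters the synthesis.

Patlak analysis plots C_t/C_b against (∫₀ᵗC_b)/C_b and fits a line to points
from the 10-min equilibrium cutoff onwards (configurable); the slope
estimates the net influx Ki, the intercept the effective distribution
volume V. For plain sampled curves the integral is cumulative trapezoid
(with a rectangle for the pre-first-sample segment). For frame-binned data
trapezoid integration across the sparse 240-s frames biases Ki by ~1% and V
by several percent, so when frame durations are supplied the integral
through each frame start is taken as the exact cumulative sum of
mean × duration, and the within-frame remainder comes from a biexponential
fitted to the frame means through its own frame-mean prediction (falling
back to a half-frame rectangle if that fit fails). On noiseless
forward-model data this inverts (Ki, V) to machine precision; tests assert
0.1%.

## What the synthetic data do and do not show

The generator emulates: the micro/macro size dichotomy, surface-restricted
labeling, the resolution ladder of four modalities with realistic PSFs, a
≥1,000 HU mineral contrast, one-site kinetics with the measured constants, a
biexponential input function, and the clinical frame schedule. It does not
emulate: irregular deposit morphology, vessel anatomy, registration error
(channels are co-registered by construction), scanner reconstruction
artifacts, metabolites, radioactive decay (activities are assumed
decay-corrected), or reaction–diffusion transport through soft tissue
(diffusion outside mineral is instantaneous). Passing tests therefore
demonstrate internal consistency of the mechanism and pipeline — e.g. that
the PET+/CT− fraction must grow as resolution falls, purely from partial
volume — not agreement with any patient measurement; the patient-derived
percentages and correlations require clinical data that are not public.

## Problem sizes

Test and demonstration runs use the 8 × 8 mm 2D default phantom (1600²
pixels), 3D oracle phantoms up to 240³ voxels, 200 replicates for noisy
recovery experiments, and the 28-frame schedule — sizes chosen so the whole
suite runs on a laptop-class single core in minutes while keeping
rasterization error inside the stated tolerances.
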