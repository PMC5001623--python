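# Methods

## The problem

High-content fluorescence microscopy of dense or three-dimensional cell
cultures produces images in which stained nuclei pile up on top of each
other. Classical single-object segmentations (thresholding, watershed,
per-pixel classifiers) assign each pixel to at most one object, so they
cannot represent two nuclei occupying the same pixels, and shape-free
methods happily merge or fragment clumps. `mlgoc` implements a
multi-layer "gas of near circles" (MLGOC) phase-field model with an
additive intensity data term that addresses both failure modes at once:
the shape prior knows nuclei are near-circles of a preferred radius, and
the data term knows that fluorescence from stacked nuclei adds.

## Model

### Phase-field representation

A segmentation layer is a real field φ on the pixel lattice taking
values near −1 (background) and +1 (inside an object); thresholding at 0
recovers the region. The state is a stack of k independent layers
φ⁽¹⁾…φ⁽ᵏ⁾; overlapping objects live in different layers. The counting
field

    φ₊ = Σᵢ (1 + φ⁽ⁱ⁾)/2

approximates, at each pixel, the number of objects covering it.

### Geometric term (per layer)

    E_g(φ) = Σₓ [ D/2 |∇φ|² + λ_f (φ⁴/4 − φ²/2) + α_f (φ − φ³/3) ]
             − β_f/2 Σₓ ∇φ · (Ψ ⋆ ∇φ)

The quartic double-well keeps φ near ±1; the stiffness D sets the
interface width; α_f > 0 penalises foreground area; the compactly
supported quadratic nonlocal term (interaction function Ψ, range d,
C¹ plateau–sinusoid–zero profile with transition half-width ε) makes
collections of near-circles of a preferred radius the low-energy
configurations. The multi-layer geometric energy is the plain sum over
layers — there are no geometric inter-layer couplings, so objects in
different layers neither repel nor merge even when coincident. An
optional inter-layer overlap penalty Σ_{i<j} p_i²p_j² (p = (1+φ)/2),
inherited from the predecessor multi-layer model, is kept behind a
weight that defaults to 0: with the additive data term below, duplicated
segmentations of one object across layers raise φ₊ above the observed
multiplicity and are suppressed by the data itself.

### Additive intensity model and data term

Measured intensity is proportional to fluorophore density, so n stacked
nuclei produce mean μ₋ + nΔμ and variance σ₋² + nΔσ², where (μ₋, σ₋²)
describe the background and (Δμ, Δσ²) the per-cell increments. All four
parameters are estimated by Gaussian maximum likelihood over a
background region and a single-cell region (given as masks, or derived
from a global Otsu split eroded by 2 px to drop mixed boundary pixels);
Δσ² is floored at 0. With v(φ₊) = σ₋² + max(φ₊,0)Δσ² the data term is
the Gaussian negative log-likelihood

    E_d = γ_d Σₓ [ (I − μ₋ − φ₊Δμ)² / (2v) + ½ ln v ]

minimised when φ₊ matches the local multiplicity. The ln v term can be
switched off (pure weighted least squares); it defaults to on. The
variance argument is clamped at φ₊ = 0 and the variance-derivative
terms are gated by 1{φ₊>0}, because phase fields transiently undershoot
−1 and an unclamped model would drive v non-positive.

### Discretization

Unit pixel spacing. The gradient operator inside the energies is the
forward difference with replicated-edge (Neumann) boundary; every
analytic gradient is the exact adjoint chain of the operators used in
the energy, so the stiffness part of δE/δφ is the 5-point Laplacian
with reflecting boundary and finite-difference checks of all gradients
pass at machine precision. Ψ ⋆ ∇φ is computed by FFT with zero
extension outside the image: zero extension avoids wrap-around coupling
between opposite edges and, unlike a mirror extension, does not double
the nonlocal self-interaction of border pixels (a mirror extension
makes thin foreground strips along the image edge spuriously cheap and
nucleates border artifacts at low SNR). The convolution operator is
self-adjoint for the symmetric kernel, and the FFT path is verified
against direct O(N²) pairwise summation.

## Radius calibration

Rather than porting a closed-form stability analysis from the contour
formulation, the preferred radius r̂ is imposed numerically. Ideal
circle fields (+1 inside, −1 outside, 1-px linear ramp, area-sampled on
a 4×4 sub-pixel grid so the profile is smooth in radius) are rendered
over a radius grid and the circle energy relative to uniform background,

    ΔE(r) = D·u(r) + λ_f·v(r) + α_f·w(r) − β_f·z(r),

is linear in the weights, so the unit-weight components u, v, w, z are
computed once. With D = λ_f = 1, d = r̂ and ε = d/2 fixed, α_f is
solved from stationarity of ΔE at r̂ for each candidate β_f, and the
smallest β_f is kept whose profile shows, on several sub-pixel-shifted
radius grids, (a) a strict interior minimum within 0.75 px of r̂,
(b) ΔE < 0 at the minimum (creating a circle of the preferred radius is
favourable against background), and (c) a positive barrier at smaller
radii (specks shrink away rather than nucleate). Phase stability of the
±1 wells additionally requires |α_f| < λ_f; the search caps |α_f| at
0.85 λ_f. Typical calibrated values at r̂ = 15: α_f ≈ 0.088,
β_f ≈ 0.044. The calibrated profile attains its minimum within ±1 px of
r̂ for r̂ ∈ {10, 15, 17, 20} on an independent 0.5-px check grid.

## Initialization

*Neutral*: each layer is iid Gaussian white noise with mean at the
interphase equilibrium of the local potential — the saddle between the
two wells, which for this potential sits at α_f/λ_f — and standard
deviation 0.15 (configurable). Every layer receives the identical data
gradient, so inter-layer symmetry must be broken by the initial noise;
with much smaller noise (e.g. sd 0.01) the layers stay synchronized and
the common-mode overshoot of φ₊ collapses the whole state to background
before objects can form. 0.15 is still small against the ±1 phase
separation and reliably breaks the symmetry.

*Seeded*: given approximate object centres, each layer is 1 on disks of
radius r̂/2 around its seeds and a configurable background level (0 by
default, the literal rule; −1, the background phase, is the
alternative) elsewhere. Seeds are distributed over layers by greedy
colouring of the conflict graph, processed in decreasing-degree order;
two seeds conflict when closer than 2.5 r̂ + 0.5 px. The factor 2.5
reflects that with d = r̂ the nonlocal interaction acts between
boundary points up to d + ε apart, i.e. same-layer repulsion persists
past one diameter; the +0.5 px covers rasterization contact of exactly
tangent disks. When a conflict clique needs more layers than available,
surplus seeds join the least-conflicted layer and a warning is emitted.

## Minimisation

Plain explicit gradient descent on the total energy with step-size
safeguarding: a step that would increase the energy is retried at half
size (down to 10⁻⁶ of the nominal step), and the accepted step is
carried to the next iteration with one upward probe (×2, capped at the
nominal step), so a stiff data term does not force re-halving from
scratch every iteration. The energy trace is non-increasing at accepted
steps. Convergence is declared when the relative energy decrease over a
10-iteration window falls below `tol` (default 10⁻⁶); `max_iter`
defaults to 1000. Defaults: step 0.1, threshold 0 for binarization,
8-connectivity for instance extraction, minimum object area
⌈π(r̂/4)²⌉.

Because the per-pixel curvature of the data term is ≈ γ_d Δμ²/σ₋², a
fixed γ_d makes the descent arbitrarily stiff at high SNR (tiny stable
steps, slow interface motion). The benchmark layer therefore offers a
stiffness-normalised weight γ_d = 80 σ₋²/Δμ² (capped at 1), keeping
descent dynamics comparable across noise levels; choosing the data
weight per noise level is part of the method.

## Synthetic benchmarks

The generator produces scenes of circles/ellipses rendered under the
additive model (pixel value μ₋ + n(x)Δμ, binary centre-in-shape
rasterization so area bookkeeping is exact) with Gaussian white noise at
a prescribed SNR; signal power is the spatial variance of the noiseless
image, so 0 dB means noise variance equals signal variance. Shapes are
placed by uniform rejection sampling with a cap on every pairwise
rasterized intersection (as a fraction of the smaller shape's area) and
are kept fully inside the image. Layered ground truth assigns
overlapping shapes to different label-stack pages.

Suite defaults (all overridable):

| suite | geometry | intensities | noise |
|---|---|---|---|
| `two_radius` | 5 circles r=15 + 5 circles r=5, 200², overlap ≤ 10% | 40/100 | 10 dB |
| `noise_ladder` | 15 circles r=15, 400², overlap ≤ 20%, 50 images/level | 40/100 | 20…−5 dB |
| `triangle_series` | 3 circles r=15 at equilateral-triangle corners, centre distance w = 0…4r in steps of 0.25r, 170² | 40/100 | 0 dB |
| `ellipse_series` | 5 ellipses r_min=10, r_max=11…25, 150², overlap ≤ 10%, 100 images/ratio | 40/100 | 10 dB |
| `init_benchmark` | 60×400² with {30,35,40} circles + 140×150² with 4–10 circles, r=15, overlap free | bg {30,40,50}, fg {90,100,110} | 10 dB |

Where the benchmark family fixes no noise level, 10 dB — the level used
by the initialization benchmark — is the default. The two-radius suite
is segmented with neutral initialization, 3 layers and γ_d = 0.02: size
selectivity is deliberately a prior-dominated regime, since the smaller
circles are genuinely present in the data and only the shape prior can
veto them.

What the generator does **not** emulate: optical point-spread blur,
uneven illumination, autofluorescence, quantization, or non-Gaussian
(Poisson) noise. Passing benchmarks therefore demonstrate correctness
of the energy, its minimisation and the evaluation pipeline under the
stated image-formation model — not performance on real microscope data,
where illumination correction and parameter estimation quality dominate.

## Evaluation

Predicted and ground-truth objects are matched by the Hungarian
algorithm on costs 1/|A∩B|; pairs with zero overlap are ineligible.
Maximum cardinality over eligible pairs is enforced first (ineligible
pairs carry a finite cost larger than any feasible total of eligible
costs, which are each ≤ 1), otherwise leaving objects unmatched would
trivially minimise the total reciprocal weight. Object-level precision
and recall are TP/(TP+FP) and TP/(TP+FN); pixel-level accuracy is the
mean Jaccard index |A∩B|/|A∪B| over matched pairs, undefined (NaN) when
nothing matches. The implementation is verified against exhaustive
enumeration over all matchings on small instances.

## Problem sizes used in the shipped checks

The test suite and the reproduction script run reduced versions of the
benchmark families — e.g. 10 images per noise level at 256² for the
noise ladder, 10 images per elongation ratio for ellipses, and 7 small
(150²) plus 2 large (400²) images with a 3-point data-weight grid for
the initialization comparison. These sizes are the package's own choice
of a desk-scale experiment; all counts are parameters, so larger runs
only need different arguments.

## Known limitations

- Explicit descent is robust but slow on stiff (high-SNR) data terms;
  there is no semi-implicit or spectral time stepping.
- Neutral initialization relies on noise-driven symmetry breaking; on
  heavily overlapped cliques it can still merge or duplicate objects,
  which is precisely the gap the seeded mode (and the reported
  seeded-vs-neutral accuracy difference) quantifies.
- Seeds are supplied by the caller; no automatic seed detection.
- The exact potential coefficients and interaction profile of the
  original model family exist in several published variants; the forms
  implemented here are the standard phase-field ones, with all weights
  exposed in configuration.
- Elongated objects beyond roughly 1.75:1 axis ratio are outside the
  prior's comfort zone; accuracy degrades monotonically with
  elongation, as the ellipse benchmark shows.
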