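# Methods

## Scope and model

The package treats a fluorescence projection of a fibrous cytoskeletal
pattern as a 2D scalar intensity field carrying an unsigned director
field θ(x) ∈ [0°, 180°). Two order parameters summarize the pattern,
by analogy with liquid crystals:

- the **nematic order parameter** S measures orientational alignment:
  within a circular window, S is the resultant length of the doubled
  angles, S = √(⟨cos 2θ⟩² + ⟨sin 2θ⟩²). This equals ⟨cos 2(θ − θ̄)⟩
  with θ̄ the window's mean director, i.e. the axis-referenced mean
  cosine when angles are measured against the local director. The
  resultant form is frame-free: it needs no externally chosen
  reference axis, is invariant under global rotation and under
  θ → θ + 180°, and reaches 1 exactly when all window angles agree.
- the **smectic order parameter** τ measures positional (layer-like)
  regularity of the fiber array: the normalized dominant Fourier
  amplitude of the cross-fiber intensity profile,
  τ = min(1, 2|p̂(f*)|/p̂(0)), with the characteristic fiber distance
  d = 1/f*. The 2× factor and the ratio to the profile mean map a
  full-contrast raised-cosine lattice to τ = 1 and flat intensity to
  0. Because p̂(0) contains any constant background, τ on real images
  reflects modulation relative to total intensity — values well below
  1 are the norm.

Angle convention, fixed everywhere: θ is measured from the +x (column)
axis, counterclockwise with y pointing up (toward decreasing row
index). The generator and the estimator share the convention; all
downstream statistics consume 2θ trigonometry only.

Working on maximum-intensity projections of a curved surface means all
lengths are chord-projected; correlation lengths are therefore
underestimates of the true geodesic scale. No curvature correction is
attempted.

## Orientation estimation

The structure tensor uses Gaussian-derivative gradients (scale
`sigma_grad`, default 1 px expressed in μm) whose outer products are
averaged with a Gaussian window (`sigma_window`, default 4 px). The
fiber angle is the eigenvector of the smaller eigenvalue (direction of
minimal intensity variation); coherency = (λmax − λmin)/(λmax + λmin)
with 0/0 → 0; energy = λmax + λmin. A constant image yields a zero
tensor flagged `is_flat` rather than an error; exactly degenerate
tensors report an arbitrary angle flagged unreliable.

Pixels within 3·sigma_window of the frame or the mask boundary are
excluded from every downstream average: the smoothing window is
truncated there and angles are biased toward the border tangent.

The tissue mask is an Otsu threshold on a lightly smoothed image,
small holes filled, largest 8-connected component kept. Its
equivalent-circle diameter 2·px·√(area/π) normalizes correlation
lengths.

## Nematic order, correlation length, defects

- Windowed S: circular window, default diameter 20 μm — a patch of a
  few cells, large enough to average pixel noise, small enough to
  resolve domains. Implemented as three FFT convolutions (masked
  cos 2θ, sin 2θ, and the mask itself); a spatial-domain path
  (`method="direct"`) exists for bit-exact checks. Windows with no
  valid sample are undefined (NaN), never 0.
- C(r) = ⟨cos 2Δθ⟩ over pixel pairs binned by separation
  (default dr = 2 μm). Pairs are formed among a seeded random subset
  of at most `n_points_max` valid pixels (default 3000, ≈4.5 M pairs);
  on small fields no subsampling occurs and the estimator is the exact
  all-pairs average. C(0) = 1 by construction. The correlation length
  is the first crossing of C = 0.2, linearly interpolated between
  bins; profiles that never reach the threshold return the last radius
  flagged censored. An alternative Pearson autocorrelation of the
  cos 2θ map was considered and rejected as the default: the
  ⟨cos 2Δθ⟩ form is the plain reading of "correlation between
  cos(2θ) values" and needs no mean subtraction policy.
- Defects: the winding of θ around a discrete circular loop (radius
  3 px by default, sitting outside the incoherent core), each angle
  increment wrapped to (−90°, 90°]. Candidate pixels with |winding| ≥
  1/4 are clustered within the merge radius (4 px); the cluster charge
  is the winding recomputed at the cluster centroid rounded to the
  nearest half-integer, and clusters rounding to zero (e.g. a merged
  ±1/2 pair) are dropped. Literal summation of per-pixel candidate
  charges would multi-count a single core, since every loop center
  near the core measures the full winding. Low-coherency cores are
  deliberately kept. Closed surfaces are handled as planar charts
  (e.g. two stereographic hemispheres); the detected total over charts
  of a sphere is +2 exactly.

## Smectic measurement

Non-overlapping windows (default 25 μm) are evaluated where at least
half the pixels are valid. The patch is resampled (cubic interpolation)
in a frame aligned with the window's mean director, averaged along the
fiber axis into a 1D profile across fibers, Hann-tapered, and
transformed with 8× zero padding (scalloping loss < 1%). The dominant
frequency is searched in the physical band 1.5–10 μm spacing, which
brackets the biologically expected ~3.4 μm while excluding DC and
pixel-scale noise. A window whose peak amplitude is under 4× the
median in-band amplitude keeps its τ but has d flagged unreliable;
aggregate means exclude flagged windows from d only. The window must
hold at least 4 periods of the band minimum (enforced). Linear
interpolation was tried for the profile resampling and attenuates
oblique high-frequency stripes by several percent; cubic keeps a pure
lattice at τ ≥ 0.98.

## Domains and the homogeneous-increase null

High-order domains are 8-connected components of {S ≥ threshold} with
area ≥ 25 px, labels ordered by decreasing area. The threshold default
is 0.6 and is recorded in every output; diameters are
equivalent-circle. Tracking links a parent (frame t) and child (frame
t+1) when their intersection covers at least `min_overlap_frac`
(default 0.3) of the parent *or* of the child — the symmetric rule
makes fusion (≥2 parents → 1 child) and split (1 parent → ≥2 children)
mirror images; unlinked labels are deaths/births. No registration is
applied between frames; a drifting sample should be registered
upstream.

The null model raises the initial S field uniformly —
clip(S₀ + (m(t) − m(0)), 0, 1), additive by default, multiplicative
behind a flag — so its spatial mean matches the observed trajectory
exactly (up to clipping, after which the realized mean is recomputed
and reported). Additive increase is the plain reading of "homogeneous
increase"; the same segmentation pipeline then yields null domain
diameters for comparison.

## Angle statistics

Axis-relative angles are folded to [0°, 90°] on input (|θ| mod 180°,
reflected). Binning is left-closed with the final bin closed:
[0, 30), [30, 60), [60, 90] — a convention had to be fixed since the
category labels overlap at the printed edges. Uniformity is tested by
dividing angles by 90 and applying the one-sample two-sided
Kolmogorov–Smirnov test (scipy.stats.kstest), exact null distribution
for n ≤ 100 (the realistic sample-size range), asymptotic beyond.
Group comparisons use the two-sided Mann–Whitney U test
(scipy.stats.mannwhitneyu), exact for min(n, m) ≤ 8 without ties,
normal approximation with tie correction otherwise; two identical
constant samples return p = 1 by convention. Measurement points are
treated as independent — appropriate when points are farther apart
than the angle correlation length. No per-sample mixed-effects
structure is modeled.

## Synthetic generator

The generator emulates the statistical structure of projected fiber
images: quasi-periodic bright stripes (raised-cosine profile, default
spacing 3.4 μm, at least 3 px per period enforced), a constant
background with Poisson-like Gaussian noise, peak-to-background
contrast 4 by default, tunable angular noise, per-fiber positional
jitter, Voronoi-mosaic multi-domain patterns with disordered boundary
stripes (line defects, default 5 px), standard 2D nematic defect
fields θ = Σᵢ sᵢφᵢ + θ₀, and time series of isotropically growing,
fusing ordered domains.

Angular noise is von Mises on the doubled angle (respecting θ ≡
θ+180°); κ = ∞ is noiseless, κ = 0 isotropic, and the implied order
level is I₁(κ)/I₀(κ) (exposed both ways as `order_for_kappa` /
`kappa_for_order`). Rendering uses overlap-add Hann tiles (16 px, 50%
overlap): each tile renders exact stripes at a per-tile
noise-perturbed angle, phase-anchored to the global base-angle phase
at the tile center. Zero noise therefore reproduces the global raised
cosine exactly (the exact-periodicity contract), while noise remains a
local perturbation — a naive global phase u = x sin θ(x) + y cos θ(x)
would amplify angle noise linearly with distance from the origin.
Phase jitter displaces each fiber (indexed by its period number) by a
Gaussian offset in units of the spacing, producing the expected
Debye–Waller-like attenuation of τ.

All generators are pure functions of (spec, seed); identical inputs
give bit-identical images.

What the generator does **not** emulate: the microscope PSF and
shot-noise statistics of real projections (intensity statistics are a
calibration-free choice, not a fit to any dataset), surface curvature
and the resulting projection distortion, two-layer
(ectoderm/endoderm) crossed fiber systems, and intensity
heterogeneity of real actin signal. Passing tests therefore
demonstrate correctness of the measurement chain on patterns with
known order, not instrument-level realism.

## Problem sizes and determinism

Test and acceptance workloads use 96–512 px images, ≤3000
autocorrelation points, 2000 KS replicates at n = 50, and ≤10-frame
time series at 128–200 px — sizes at which every stage completes in
seconds while leaving the estimators in their asymptotic regime. Every
stochastic choice flows from an explicit seed (per-stage substreams
derived from the master seed via SeedSequence), and pipeline reruns
with the same config and inputs are byte-identical.

## Known limitations

- τ depends on the background level through p̂(0); comparisons are
  meaningful within an imaging condition, not across arbitrary
  rescalings of background (pure gain rescaling cancels exactly).
- d estimates on strongly disordered windows are biased toward the
  band center and are flagged rather than suppressed; aggregate d
  should be read together with the flag counts.
- The correlation length of a single-domain aligned pattern is
  censored at r_max by design; censoring must be checked before
  averaging correlation lengths across samples.
- Defect detection assumes cores separated by more than the loop
  diameter; closer pairs merge (and may cancel) by construction.
- A sudden mask-area change (e.g. tissue deflation) transiently
  perturbs S through resolution effects; the pipeline reports mask
  area alongside S so such frames can be flagged, and applies no
  correction.
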