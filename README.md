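# fiberorder

Quantification of orientational (nematic) and positional (smectic)
order in fiber-pattern microscopy, built for the basal actin myonemes
of regenerating *Hydra* aggregates: dissociated cells re-aggregate,
rebuild supracellular actin fibers, and those fibers progress from a
disordered meshwork to a tissue-scale aligned, quasi-periodic array.
The package measures that progression on 2D grayscale projections and
ships a synthetic fiber-image generator with full ground truth, so
every stage of the measurement chain is verifiable without microscopy
data.

Intended users: developmental-biology and tissue-mechanics groups
quantifying cytoskeletal alignment in epithelia, and anyone needing a
tested structure-tensor → order-parameter pipeline with a generative
benchmark.

## What it computes

Fibers are unsigned directors: an angle θ ∈ [0°, 180°) with θ ≡ θ+180°,
so all statistics are built on the doubled angle 2θ.

- **Orientation field** — per-pixel fiber angle θ, coherency and energy
  from the Gaussian-gradient structure tensor; the fiber direction is
  the eigenvector of the smaller eigenvalue (minimal intensity
  variation).
- **Nematic order parameter** — over a circular window,
  `S = √(⟨cos 2θ⟩² + ⟨sin 2θ⟩²) = ⟨cos 2(θ − θ̄)⟩`,
  the resultant length of the doubled angles: 1 for perfect alignment,
  0 for an isotropic pattern.
- **Correlation length** — the angle autocorrelation
  `C(r) = ⟨cos 2(θ(x) − θ(y))⟩` over pixel pairs at distance r; the
  correlation length is the first crossing of C(r) = 0.2, optionally
  normalized by the aggregate's equivalent diameter.
- **Smectic order parameter and fiber spacing** — per window the image
  is resampled along the local director, averaged into a 1D intensity
  profile across the fibers, Hann-tapered and Fourier-transformed;
  `τ = min(1, 2|p̂(f*)|/p̂(0))` with f* the dominant in-band frequency,
  and the characteristic fiber distance is d = 1/f*. A full-contrast
  cosine lattice gives τ = 1; flat intensity gives 0.
- **Topological defects** — winding number of θ on small loops, with
  increments wrapped to (−90°, 90°]; charges are half-integers (±1/2,
  +1, …) and a closed spherical surface carries total charge +2.
- **High-order domains** — 8-connected components of {S ≥ threshold},
  their number and equivalent-circle diameters over time, fusion
  detection by frame-to-frame overlap, and a homogeneous-increase null
  model (the initial S field raised uniformly to match the observed
  mean trajectory) to test whether order grows by localized domains
  rather than everywhere at once.
- **Angle statistics** — axis-relative angles in [0°, 90°] binned as
  parallel (0–30°) / diagonal (30–60°) / orthogonal (60–90°),
  Kolmogorov–Smirnov uniformity tests on angles normalized to [0, 1],
  and two-sided Mann–Whitney comparisons (e.g. tip-to-defect distances
  against half inter-defect distances).

## Worked example

Generate a noisy synthetic aggregate and measure it:

```python
from fiberorder import (FiberPatternSpec, Mask, render_fibers, estimate_orientation,
                        local_order_parameter, mean_order, local_smectic,
                        aggregate_smectic, angle_autocorrelation, correlation_length)

spec = FiberPatternSpec(image_shape=(256, 256), pixel_size_um=0.5,
                        base_angle_deg=30.0, spacing_um=3.4,
                        angle_noise_kappa=4.0, phase_jitter_sd=0.15, seed=7)
img, truth = render_fibers(spec)
mask = Mask.full(img.shape, 0.5)
orient = estimate_orientation(img)

S = mean_order(local_order_parameter(orient, mask, window_um=20.0), mask)
tau, d = aggregate_smectic(local_smectic(img, orient, mask))
profile = angle_autocorrelation(orient, mask, dr_um=2.0, r_max_um=100.0, seed=7)
length, _, censored = correlation_length(profile, threshold=0.2)

print(f"mean nematic order S   = {S:.3f}")
print(f"smectic order tau      = {tau:.3f}")
print(f"fiber spacing d        = {d:.2f} um (generated: 3.40 um)")
print(f"correlation length     = {length:.1f} um (censored: {censored})")
```

Output:

```
mean nematic order S   = 0.994
smectic order tau      = 0.388
fiber spacing d        = 3.65 um (generated: 3.40 um)
correlation length     = 99.0 um (censored: True)
```

The directors are noisy at the pixel scale but share one base angle, so
the windowed S is high and the autocorrelation never decays below 0.2
within the profile — the correlation length is censored at the maximum
radius, as expected for a single-domain pattern. τ is well below 1
because the rendered stripes sit on a bright background (τ is the
modulation relative to the total mean intensity) and the per-fiber
jitter further attenuates the spectral peak; the spacing is recovered
near the generative 3.4 μm.

The numbered drivers under `analysis/` run the full study on synthetic
data: `01_simulate_maturation.py` builds a five-stage mosaic maturation
series, `02_order_quantification.py` measures S, correlation length, τ
and d across it, `03_domain_dynamics.py` tracks growing/fusing
high-order domains against the homogeneous-increase null, and
`04_perturbation_stats.py` runs the axis-relative angle statistics.
Tables land in `results/`, bulk images in `scratch/`.

There is also a CLI (`fiberorder generate|orient|nematic|smectic|domains|angstats|pipeline`)
for running the same measurements on TIFF inputs from a shell.

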