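"""Synthetic fiber-pattern generator with full ground truth.

Emulates maximum-intensity projections of basal actin fibers in
regenerating Hydra aggregates: quasi-periodic bright stripes (spacing
~3.4 μm) on a dark background, locally aligned directors with tunable
angular noise, mosaics of differently oriented domains separated by
disordered boundary stripes (line defects), ±1/2 and +1 topological
defect configurations, growing and fusing ordered domains over time, and
axis-relative angle samples.  Every generator is a pure function of its
spec and seed.

Angle convention matches :mod:`fiberorder.orientation`: θ in degrees
[0, 180) from the +x (column) axis, counterclockwise with y up.  The
stripe phase coordinate across the fibers is u = x·sinθ + y·cosθ with
x the column and y the row index.

Angular noise is von Mises on the doubled angle 2θ, which respects the
nematic identification θ ≡ θ+180°; κ=∞ means no noise, κ=0 a uniform
director.  The stripe profile is a raised cosine (1+cos(2πu/d))/2, whose
Fourier amplitude is known in closed form and calibrates the smectic
order parameter: a full-contrast cosine lattice maps to τ=1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, optimize, special

from .angstats import AngleMeasurementSet
from .orientation import Image2D

__all__ = [
    "FiberPatternSpec",
    "GroundTruth",
    "SyntheticTimeSeries",
    "make_director_field",
    "render_fibers",
    "make_time_series",
    "sample_angles",
    "order_for_kappa",
    "kappa_for_order",
]


def order_for_kappa(kappa: float) -> float:
    """Expected resultant length ⟨cos 2(θ−θ̄)⟩ of von Mises noise on 2θ.

    Equals I1(κ)/I0(κ); 1 at κ=∞ (no noise), 0 at κ=0 (uniform).
    """
    if math.isinf(kappa):
        return 1.0
    if kappa == 0:
        return 0.0
    return float(special.i1e(kappa) / special.i0e(kappa))


def kappa_for_order(s: float) -> float:
    """Invert order_for_kappa: concentration producing mean resultant s."""
    if not 0.0 <= s < 1.0:
        if s == 1.0:
            return math.inf
        raise ValueError("target order must be in [0, 1]")
    if s == 0.0:
        return 0.0
    return float(optimize.brentq(lambda k: order_for_kappa(k) - s, 1e-8, 1e6))


@dataclass
class FiberPatternSpec:
    """Generative parameters of a synthetic fiber image.

    spacing_um is the target inter-fiber distance d; phase_jitter_sd is
    a per-fiber positional jitter as a fraction of d (degrades smectic
    order); stripe_contrast the peak-to-background intensity ratio.
    """

    image_shape: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.5
    director_mode: str = "uniform"  # uniform | mosaic | defect | custom
    base_angle_deg: float = 0.0
    spacing_um: float = 3.4
    angle_noise_kappa: float = math.inf
    phase_jitter_sd: float = 0.0
    stripe_contrast: float = 4.0
    background_level: float = 2000.0
    background_noise_sd: float = 0.0
    domain_map: np.ndarray | None = None
    domain_angles_deg: dict[int, float] | None = None
    boundary_stripe_px: int = 5
    defects: list[tuple[float, float, float]] | None = None
    custom_angle_map: np.ndarray | None = None
    tile_px: int = 16
    seed: int = 0

    def validate(self) -> None:
        if self.spacing_um / self.pixel_size_um < 3:
            raise ValueError(
                "spacing must span at least 3 pixels per period "
                f"(got {self.spacing_um / self.pixel_size_um:.2f} px)"
            )
        if self.angle_noise_kappa < 0:
            raise ValueError("angle_noise_kappa must be >= 0")
        if self.phase_jitter_sd < 0 or self.background_noise_sd < 0:
            raise ValueError("noise parameters must be >= 0")
        if self.stripe_contrast < 1:
            raise ValueError("stripe_contrast is peak/background, must be >= 1")
        if self.director_mode not in {"uniform", "mosaic", "defect", "custom"}:
            raise ValueError(f"unknown director_mode {self.director_mode!r}")
        if self.director_mode == "mosaic" and self.domain_map is None:
            raise ValueError("mosaic mode requires a domain_map")
        if self.director_mode == "custom" and self.custom_angle_map is None:
            raise ValueError("custom mode requires custom_angle_map")
        if self.director_mode == "defect":
            if not self.defects:
                raise ValueError("defect mode requires a non-empty defect list")
            for r, c, s in self.defects:
                if abs(round(2 * s) - 2 * s) > 1e-12 or s == 0:
                    raise ValueError(f"charge {s} is not a nonzero half-integer")
            pts = np.array([(r, c) for r, c, _ in self.defects], dtype=float)
            if len(pts) > 1:
                d2 = np.sum((pts[:, None] - pts[None]) ** 2, axis=-1)
                np.fill_diagonal(d2, np.inf)
                if d2.min() < 4.0**2:
                    raise ValueError(
                        "defect cores closer than 4 px: director field ill-defined"
                    )

    @property
    def spacing_px(self) -> float:
        return self.spacing_um / self.pixel_size_um


@dataclass
class GroundTruth:
    """Generative ground truth matching a rendered image pixel-for-pixel."""

    angle_map_deg: np.ndarray  # [0, 180) per pixel
    order_map: np.ndarray  # S in [0, 1] implied by the noise model
    domain_map: np.ndarray  # nonnegative integer labels
    defect_list: list[tuple[float, float, float]]
    spacing_um: float

    def __post_init__(self) -> None:
        if np.any(self.angle_map_deg < 0) or np.any(self.angle_map_deg >= 180):
            raise ValueError("angle_map_deg must lie in [0, 180)")
        if self.domain_map.min() < 0:
            raise ValueError("domain labels must be nonnegative")
        if self.angle_map_deg.shape != self.order_map.shape != self.domain_map.shape:
            raise ValueError("ground truth arrays must share the image shape")


def make_director_field(spec: FiberPatternSpec) -> np.ndarray:
    """Noise-free director angle map (degrees in [0, 180)) for a spec.

    Defect fields superpose the standard 2D nematic form θ = Σ sᵢ·φᵢ + θ0
    with sᵢ the charge and φᵢ the polar angle about core i, so the
    winding measured on a loop around each core equals its charge.
    """
    spec.validate()
    rows, cols = spec.image_shape
    if spec.director_mode == "uniform":
        return np.full(spec.image_shape, spec.base_angle_deg % 180.0)
    if spec.director_mode == "custom":
        return np.mod(np.asarray(spec.custom_angle_map, dtype=float), 180.0)
    if spec.director_mode == "mosaic":
        angles = _mosaic_angles(spec)
        out = np.empty(spec.image_shape, dtype=float)
        for lab, ang in angles.items():
            out[spec.domain_map == lab] = ang % 180.0
        return out
    # defect mode
    y, x = np.mgrid[0:rows, 0:cols]
    theta = np.full(spec.image_shape, float(spec.base_angle_deg))
    for r0, c0, s in spec.defects:
        phi = np.degrees(np.arctan2(-(y - r0), x - c0))  # y-up polar angle
        theta = theta + s * phi
    return np.mod(theta, 180.0)


def _mosaic_angles(spec: FiberPatternSpec) -> dict[int, float]:
    labels = [int(l) for l in np.unique(spec.domain_map)]
    if spec.domain_angles_deg is not None:
        missing = set(labels) - set(spec.domain_angles_deg)
        if missing:
            raise ValueError(f"domain_angles_deg missing labels {sorted(missing)}")
        return {l: float(spec.domain_angles_deg[l]) for l in labels}
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xD0]))
    return {l: float(a) for l, a in zip(labels, rng.uniform(0, 180, len(labels)))}


def _hann_periodic(n: int) -> np.ndarray:
    # 50%-overlap partition of unity: w(i) + w(i + n/2) = 1
    i = np.arange(n)
    return 0.5 - 0.5 * np.cos(2 * np.pi * (i + 0.5) / n)


def _fiber_offsets(rng: np.random.Generator, n_half: int, jitter_px: float) -> np.ndarray:
    # per-fiber positional offsets, indexed by fiber number m + n_half
    return jitter_px * rng.standard_normal(2 * n_half + 1)


def _stripes_global(
    shape: tuple[int, int],
    angle_deg: float,
    period_px: float,
    offsets: np.ndarray,
) -> np.ndarray:
    """Exact raised-cosine stripes at one angle over the whole frame."""
    rows, cols = shape
    y, x = np.mgrid[0:rows, 0:cols]
    th = math.radians(angle_deg)
    u = x * math.sin(th) + y * math.cos(th)
    n_half = (len(offsets) - 1) // 2
    m = np.clip(np.floor(u / period_px + 0.5).astype(int) + n_half, 0, len(offsets) - 1)
    u_eff = u - offsets[m]
    return 0.5 * (1.0 + np.cos(2 * np.pi * u_eff / period_px))


def _stripes_tiled(
    shape: tuple[int, int],
    angle_map_deg: np.ndarray,
    base_angle_deg: float | None,
    period_px: float,
    kappa: float,
    offsets: np.ndarray,
    rng: np.random.Generator,
    tile_px: int,
    region: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Overlap-add Hann-tile rendering with per-tile noisy angles.

    Each tile renders exact stripes at the tile's (noise-perturbed)
    angle; the phase is anchored to the global base-angle phase at the
    tile center so that zero noise reproduces the global raised cosine
    exactly and angular noise stays a local perturbation.  Returns the
    blended pattern and the per-pixel rendered angle (degrees, [0,180)).
    """
    rows, cols = shape
    T = tile_px
    step = T // 2
    w1 = _hann_periodic(T)
    w2 = np.outer(w1, w1)
    pat = np.zeros((rows + 2 * T, cols + 2 * T))
    wc2 = np.zeros_like(pat)
    ws2 = np.zeros_like(pat)
    n_half = (len(offsets) - 1) // 2

    ty, tx = np.mgrid[0:T, 0:T].astype(float)
    for r0 in range(-T, rows + T, step):
        for c0 in range(-T, cols + T, step):
            if region is not None:
                rr0, rr1 = max(r0, 0), min(r0 + T, rows)
                cc0, cc1 = max(c0, 0), min(c0 + T, cols)
                if rr0 >= rr1 or cc0 >= cc1 or not region[rr0:rr1, cc0:cc1].any():
                    if math.isfinite(kappa) and kappa > 0:
                        rng.vonmises(0.0, kappa)  # keep the stream aligned
                    elif kappa == 0:
                        rng.uniform(0, np.pi)
                    continue
            # tile-center angle from the clean map
            cr = min(max(r0 + T // 2, 0), rows - 1)
            cc = min(max(c0 + T // 2, 0), cols - 1)
            th_deg = float(angle_map_deg[cr, cc])
            if kappa == 0:
                th_deg = math.degrees(rng.uniform(0, np.pi))
            elif math.isfinite(kappa):
                th_deg = th_deg + math.degrees(rng.vonmises(0.0, kappa)) / 2.0
            th = math.radians(th_deg)
            yc, xc = r0 + (T - 1) / 2.0, c0 + (T - 1) / 2.0
            th_a = math.radians(base_angle_deg) if base_angle_deg is not None else th
            anchor = xc * math.sin(th_a) + yc * math.cos(th_a)
            u = ((tx + c0) - xc) * math.sin(th) + ((ty + r0) - yc) * math.cos(th) + anchor
            m = np.clip(
                np.floor(u / period_px + 0.5).astype(int) + n_half, 0, len(offsets) - 1
            )
            tile = 0.5 * (1.0 + np.cos(2 * np.pi * (u - offsets[m]) / period_px))
            sl = (slice(r0 + T, r0 + 2 * T), slice(c0 + T, c0 + 2 * T))
            pat[sl] += w2 * tile
            wc2[sl] += w2 * math.cos(2 * th)
            ws2[sl] += w2 * math.sin(2 * th)
    crop = (slice(T, T + rows), slice(T, T + cols))
    rendered_angle = np.mod(np.degrees(0.5 * np.arctan2(ws2[crop], wc2[crop])), 180.0)
    return pat[crop], rendered_angle


def render_fibers(spec: FiberPatternSpec) -> tuple[Image2D, GroundTruth]:
    """Render a synthetic fiber image and its ground truth.

    Intensity = background · (1 + (contrast−1) · pattern) + Gaussian
    noise, clipped at 0; pattern is the raised-cosine stripe field
    modulated along the local director normal with period spacing/pixel.
    """
    spec.validate()
    angle_map = make_director_field(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xF1]))
    p = spec.spacing_px
    rows, cols = spec.image_shape
    n_half = int(2 * (rows + cols) / p) + 8
    jitter_px = spec.phase_jitter_sd * p

    noiseless = math.isinf(spec.angle_noise_kappa)
    order_level = order_for_kappa(spec.angle_noise_kappa)
    order_map = np.full(spec.image_shape, order_level)

    if spec.director_mode in {"uniform", "mosaic"}:
        if spec.director_mode == "uniform":
            domain_map = np.zeros(spec.image_shape, dtype=int)
            regions = {0: (np.ones(spec.image_shape, bool), spec.base_angle_deg % 180.0)}
        else:
            domain_map = np.asarray(spec.domain_map, dtype=int)
            angles = _mosaic_angles(spec)
            regions = {l: (domain_map == l, a % 180.0) for l, a in angles.items()}
        pattern = np.zeros(spec.image_shape)
        for lab, (region, ang) in sorted(regions.items()):
            offsets = _fiber_offsets(rng, n_half, jitter_px)
            if noiseless:
                stripes = _stripes_global(spec.image_shape, ang, p, offsets)
            else:
                stripes, rend = _stripes_tiled(
                    spec.image_shape,
                    np.full(spec.image_shape, ang),
                    ang,
                    p,
                    spec.angle_noise_kappa,
                    offsets,
                    rng,
                    spec.tile_px,
                    region=region,
                )
            pattern[region] = stripes[region]
        if spec.director_mode == "mosaic" and spec.boundary_stripe_px > 0:
            half = max(1, spec.boundary_stripe_px // 2)
            size = 2 * half + 1
            boundary = ndimage.maximum_filter(domain_map, size=size) != ndimage.minimum_filter(
                domain_map, size=size
            )
            if boundary.any():
                offsets = _fiber_offsets(rng, n_half, jitter_px)
                disordered, _ = _stripes_tiled(
                    spec.image_shape,
                    angle_map,
                    None,
                    p,
                    0.0,  # uniform angles: a disordered line-defect stripe
                    offsets,
                    rng,
                    max(8, spec.tile_px // 2),
                    region=boundary,
                )
                pattern[boundary] = disordered[boundary]
                order_map[boundary] = 0.0
    else:  # defect or custom: spatially varying director
        domain_map = np.zeros(spec.image_shape, dtype=int)
        offsets = _fiber_offsets(rng, n_half, jitter_px)
        kappa = spec.angle_noise_kappa if not noiseless else math.inf
        pattern, _ = _stripes_tiled(
            spec.image_shape,
            angle_map,
            None,
            p,
            kappa if math.isfinite(kappa) else math.inf,
            offsets,
            rng,
            spec.tile_px,
        )

    intensity = spec.background_level * (1.0 + (spec.stripe_contrast - 1.0) * pattern)
    if spec.background_noise_sd > 0:
        intensity = intensity + spec.background_noise_sd * rng.standard_normal(
            spec.image_shape
        )
    intensity = np.clip(intensity, 0.0, None)

    gt = GroundTruth(
        angle_map_deg=angle_map,
        order_map=order_map,
        domain_map=domain_map,
        defect_list=list(spec.defects or []),
        spacing_um=spec.spacing_um,
    )
    return Image2D(intensity, spec.pixel_size_um), gt


@dataclass
class SyntheticTimeSeries:
    """Frames of a growing/fusing-domain movie plus fusion ground truth."""

    frames: list[tuple[Image2D, GroundTruth]]
    merge_events: list[tuple[int, frozenset[int]]]  # (frame index, labels merged)

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def make_time_series(
    initial_domain_map: np.ndarray,
    growth_rate_px_per_frame: float,
    order_inside: float,
    order_outside: float,
    n_frames: int,
    seed: int,
    pixel_size_um: float = 1.0,
    spacing_um: float = 3.4,
    order_smooth_px: float = 2.0,
    render_images: bool = True,
) -> SyntheticTimeSeries:
    """Time series of isotropically growing, fusing ordered domains.

    Each seed region of ``initial_domain_map`` (labels ≥ 1, 0 =
    background) dilates by ``growth_rate_px_per_frame`` per frame
    (Euclidean disk growth, nearest-seed ownership).  Domains whose
    grown regions touch under 8-connectivity merge into one label; the
    first frame of each merge is recorded.  The ground-truth order map
    is ``order_inside`` on domains, ``order_outside`` elsewhere, lightly
    smoothed; images (when rendered) carry matching angular noise.
    """
    if order_inside <= order_outside:
        raise ValueError("order_inside must exceed order_outside")
    if growth_rate_px_per_frame < 0:
        raise ValueError("growth rate must be >= 0")
    init = np.asarray(initial_domain_map, dtype=int)
    seeds = init > 0
    if not seeds.any():
        raise ValueError("initial_domain_map has no seed labels")
    dist, (ir, ic) = ndimage.distance_transform_edt(~seeds, return_indices=True)
    owner = init[ir, ic]
    labels0 = [int(l) for l in np.unique(init) if l > 0]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x75]))
    angles = {l: float(a) for l, a in zip(labels0, rng.uniform(0, 180, len(labels0)))}

    parent = {l: l for l in labels0}

    def find(l: int) -> int:
        while parent[l] != l:
            parent[l] = parent[parent[l]]
            l = parent[l]
        return l

    eight = np.ones((3, 3), dtype=int)
    frames: list[tuple[Image2D, GroundTruth]] = []
    merge_events: list[tuple[int, frozenset[int]]] = []
    kappa_in = kappa_for_order(order_inside)
    kappa_out = kappa_for_order(order_outside)

    for f in range(n_frames):
        grown = dist <= f * growth_rate_px_per_frame
        grown |= seeds
        cc, n_cc = ndimage.label(grown, structure=eight)
        # group original labels by connected component; record new merges
        dm = np.zeros_like(init)
        for k in range(1, n_cc + 1):
            comp = cc == k
            members = sorted({int(l) for l in np.unique(owner[comp]) if l > 0})
            roots = {find(l) for l in members}
            if len(roots) > 1:
                merge_events.append((f, frozenset(members)))
                rep = min(roots)
                for l in roots:
                    parent[l] = rep
            dm[comp] = min(members)
        order = np.where(dm > 0, order_inside, order_outside)
        if order_smooth_px > 0:
            order = ndimage.gaussian_filter(order, order_smooth_px)
        angle_map = np.full(init.shape, 0.0)
        for l in labels0:
            angle_map[(dm > 0) & (owner == l)] = angles[l] % 180.0

        if render_images:
            spec = FiberPatternSpec(
                image_shape=init.shape,
                pixel_size_um=pixel_size_um,
                director_mode="mosaic",
                spacing_um=spacing_um,
                angle_noise_kappa=kappa_in,
                domain_map=np.where(dm > 0, dm, 0),
                domain_angles_deg={**{0: 0.0}, **{l: angles[find(l)] for l in labels0}},
                boundary_stripe_px=0,
                seed=seed + 7919 * f,
            )
            img, _ = render_fibers(spec)
            # overwrite the disordered exterior with an isotropic texture
            outside = dm == 0
            if outside.any():
                spec_out = replace(spec, angle_noise_kappa=kappa_out, seed=spec.seed + 1)
                img_out, _ = render_fibers(spec_out)
                intensity = img.intensity.copy()
                intensity[outside] = img_out.intensity[outside]
                img = Image2D(intensity, pixel_size_um)
        else:
            img = Image2D(np.zeros(init.shape), pixel_size_um)

        gt = GroundTruth(
            angle_map_deg=angle_map,
            order_map=np.clip(order, 0.0, 1.0),
            domain_map=dm,
            defect_list=[],
            spacing_um=spacing_um,
        )
        frames.append((img, gt))
    return SyntheticTimeSeries(frames=frames, merge_events=merge_events)


def sample_angles(
    distribution: str,
    n: int,
    seed: int,
    mu_deg: float = 0.0,
    kappa: float = 4.0,
) -> AngleMeasurementSet:
    """Sample axis-relative angles in [0°, 90°].

    ``uniform`` draws flat on [0, 90]; ``vonmises`` draws director
    angles with von Mises noise on 2θ about ``mu_deg`` and folds them to
    the acute axis-relative value.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA6]))
    if distribution == "uniform":
        ang = rng.uniform(0.0, 90.0, n)
    elif distribution == "vonmises":
        if kappa < 0:
            raise ValueError("kappa must be >= 0")
        if math.isinf(kappa):
            theta = np.full(n, mu_deg)
        else:
            theta = mu_deg + np.degrees(rng.vonmises(0.0, kappa, n)) / 2.0
        theta = np.mod(theta, 180.0)
        ang = np.minimum(theta, 180.0 - theta)
    else:
        raise ValueError(f"unknown distribution {distribution!r}")
    return AngleMeasurementSet(
        angles_deg=ang,
        sample_id=np.array([f"synthetic-{seed}"] * n),
        region=np.array(["synthetic"] * n),
    )
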