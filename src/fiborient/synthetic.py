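"""Synthetic fibrous-dermis phantoms: geometry, extension, rasterization.

Generates ground-truth fiber geometries with the statistical structure the
orientation analysis assumes — horizontal laminar bundles of tightly
packed, wavy (crimped) collagen fibers whose in-plane orientations follow
a 1–3 mode axial Gaussian mixture, plus a sparser elastic-fiber network
locally co-aligned with the collagen — and turns them into calibrated
8-bit two-channel z-stacks. Equibiaxial extension is simulated as an equal
in-plane affine map on fiber chords with arc-length-preserving reduction
of the crimp amplitude, so fibers straighten under stretch exactly as a
inextensible wavy fiber would.

The z coordinate of the geometry is depth below the papillary–reticular
boundary (µm); slice 0 of a rasterized stack sits at that boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .angles import axial_mean, fold180
from .mechanics import StressStrainCurve
from .stack import ImageStack

__all__ = [
    "FiberFieldSpec",
    "Fiber",
    "FiberGeometry",
    "ExtensionParams",
    "sample_mode_angles",
    "generate_collagen_geometry",
    "generate_elastic_geometry",
    "apply_biaxial_extension",
    "rasterize_stack",
    "generate_stress_strain",
    "arc_length",
    "chord_length",
]

_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))  # FWHM of a unit-σ Gaussian


@dataclass
class FiberFieldSpec:
    """Parameters of one 211 µm phantom tile.

    Defaults mirror the acquisition geometry of multiphoton dermal imaging
    (211 × 211 µm ≙ 512 × 512 px tiles, 2 µm z-interval, stacks to 500 µm)
    and a laminar bundle layout with ~30 µm spacing superficially
    (depth < 200 µm) and ~44 µm spacing in the deep reticular dermis.
    Orientations are drawn from a two-mode axial Gaussian mixture 66°
    apart. Crimp amplitude/wavelength are synthetic defaults, not measured
    anatomy.
    """

    field_xy: float = 211.0  # µm per tile side
    pixels_xy: int = 512
    z_extent: float = 500.0  # µm
    z_interval: float = 2.0  # µm
    #: (center depth µm, slab thickness µm) per bundle
    bundle_depths: Sequence[tuple[float, float]] = (
        (16.0, 12.0),
        (46.0, 12.0),
        (76.0, 12.0),
        (106.0, 12.0),
        (136.0, 12.0),
        (166.0, 12.0),
        (216.0, 14.0),
        (260.0, 14.0),
        (304.0, 14.0),
        (348.0, 14.0),
    )
    mode_centers: Sequence[float] = (30.0, 96.0)  # degrees, axial
    mode_weights: Sequence[float] = (0.6, 0.4)
    mode_dispersion: float | Sequence[float] = 10.0  # per-mode angular SD, degrees
    fiber_diameter: float = 5.0  # µm
    waviness_amplitude: float = 5.0  # µm (crimp amplitude; synthetic default)
    waviness_wavelength: float = 40.0  # µm (crimp period; synthetic default)
    packing_density: float = 0.8  # fraction of plane covered within a slab layer
    elastic_density: float = 3.0  # elastic fibers per (100 µm)² per bundle
    elastic_jitter_sd: float = 5.0  # degrees
    background_level: float = 10.0  # 8-bit DN
    fiber_intensity: float = 150.0  # 8-bit DN at fiber core
    noise_sd: float = 5.0  # DN
    psf_sigma: float = 0.5  # µm, in-plane Gaussian PSF
    #: True: each bundle draws one mixture mode and a bundle orientation
    #: from that mode (center + mode dispersion), and its fibers scatter
    #: tightly around the bundle orientation — laminar bundles are
    #: orientation-coherent, as depth-peak detection assumes.
    #: False: every fiber draws its own mode independently.
    bundle_coherent: bool = True
    within_bundle_jitter_sd: float = 2.0  # degrees, coherent bundles only
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.mode_weights, dtype=float)
        c = np.asarray(self.mode_centers, dtype=float)
        if c.size == 0 or c.size != w.size:
            raise ValueError("mode_centers and mode_weights must be non-empty, equal length")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("mode_weights must sum to 1")
        if np.any(w <= 0):
            raise ValueError("mode_weights must all be positive")
        if np.any(c < 0) or np.any(c >= 180):
            raise ValueError("mode_centers must lie in [0, 180)")
        if self.waviness_amplitude < 0:
            raise ValueError("waviness_amplitude must be >= 0")
        if 2 * self.waviness_amplitude >= self.field_xy:
            raise ValueError("waviness_amplitude too large for the field")
        if not (0 < self.packing_density <= 1):
            raise ValueError("packing_density must be in (0, 1]")
        if self.field_xy <= 0 or self.pixels_xy <= 0:
            raise ValueError("field_xy and pixels_xy must be positive")
        if self.z_interval <= 0 or self.z_extent <= 0:
            raise ValueError("z geometry must be positive")
        for d, t in self.bundle_depths:
            if t <= 0:
                raise ValueError("bundle thickness must be positive")
            if d - t / 2 < 0 or d + t / 2 > self.z_extent:
                raise ValueError(
                    f"bundle slab at depth {d} µm (thickness {t} µm) extends outside "
                    f"[0, {self.z_extent}] µm"
                )

    @property
    def pixel_pitch(self) -> float:
        """In-plane sampling, µm per pixel."""
        return self.field_xy / self.pixels_xy

    @property
    def dispersions(self) -> np.ndarray:
        """Per-mode angular SD (degrees), broadcast from a scalar if needed."""
        d = np.asarray(self.mode_dispersion, dtype=float)
        if d.ndim == 0:
            d = np.full(len(self.mode_centers), float(d))
        if d.size != len(self.mode_centers):
            raise ValueError("mode_dispersion must be scalar or one value per mode")
        if np.any(d < 0):
            raise ValueError("mode_dispersion must be >= 0")
        return d


@dataclass
class Fiber:
    """One fiber: a 3D polyline plus the crimp parameters that built it."""

    points: np.ndarray  # (n, 3) µm
    orientation_deg: float  # planted axial chord orientation, [0, 180)
    bundle_id: int
    channel: str  # "collagen" | "elastic"
    diameter_um: float
    mode_id: int = -1
    amplitude_um: float = 0.0
    wavelength_um: float = 40.0
    phase_rad: float = 0.0


@dataclass
class FiberGeometry:
    """Ground-truth fiber set within one tile's field bounds."""

    fibers: list[Fiber]
    field_xy: float
    z_extent: float

    def __len__(self) -> int:
        return len(self.fibers)

    def truth_table(self):
        """Per-fiber ground truth as a DataFrame."""
        import pandas as pd

        rows = [
            dict(
                fiber_id=i,
                bundle_id=f.bundle_id,
                depth_um=float(np.mean(f.points[:, 2])),
                orientation_deg=f.orientation_deg,
                mode_id=f.mode_id,
                channel=f.channel,
            )
            for i, f in enumerate(self.fibers)
        ]
        return pd.DataFrame(
            rows,
            columns=["fiber_id", "bundle_id", "depth_um", "orientation_deg", "mode_id", "channel"],
        )


@dataclass
class ExtensionParams:
    """Equibiaxial in-plane stretch λ with through-thickness scaling.

    ``thickness_factor`` defaults to the incompressibility value 1/λ²
    (0.64 at λ = 1.25); pass the empirical 0.6 to reproduce measured
    thinning instead.
    """

    lambda_xy: float
    thickness_factor: float | None = None

    def __post_init__(self) -> None:
        if self.lambda_xy < 1:
            raise ValueError("lambda_xy must be >= 1")
        if self.thickness_factor is None:
            self.thickness_factor = 1.0 / self.lambda_xy**2
        if not (0 < self.thickness_factor <= 1):
            raise ValueError("thickness_factor must be in (0, 1]")


def arc_length(points: np.ndarray) -> float:
    """Polyline arc length (µm)."""
    return float(np.sum(np.linalg.norm(np.diff(points, axis=0), axis=1)))


def chord_length(points: np.ndarray) -> float:
    """Endpoint-to-endpoint chord length (µm)."""
    return float(np.linalg.norm(points[-1] - points[0]))


def sample_mode_angles(
    centers: Sequence[float],
    weights: Sequence[float],
    dispersions: float | Sequence[float],
    n: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` axial angles from a Gaussian mixture folded to [0, 180).

    Returns ``(angles_deg, mode_ids)``.
    """
    centers = np.asarray(centers, dtype=float)
    weights = np.asarray(weights, dtype=float)
    disp = np.asarray(dispersions, dtype=float)
    if disp.ndim == 0:
        disp = np.full(centers.size, float(disp))
    modes = rng.choice(centers.size, size=n, p=weights / weights.sum())
    angles = centers[modes] + rng.normal(0.0, 1.0, size=n) * disp[modes]
    return fold180(angles), modes


def _line_box_range(anchor: np.ndarray, u: np.ndarray, lo: float, hi: float) -> tuple[float, float]:
    """Parameter range [t0, t1] keeping ``anchor + t·u`` inside [lo, hi]²."""
    t0, t1 = -np.inf, np.inf
    for k in range(2):
        if abs(u[k]) < 1e-12:
            continue
        a, b = (lo - anchor[k]) / u[k], (hi - anchor[k]) / u[k]
        t0 = max(t0, min(a, b))
        t1 = min(t1, max(a, b))
    return t0, t1


def _sinusoid_points(
    start: np.ndarray,
    u: np.ndarray,
    s0: float,
    s1: float,
    amplitude: float,
    wavelength: float,
    phase: float,
    z: float,
    step: float,
) -> np.ndarray:
    """Sample a planar crimped centerline at constant depth ``z``."""
    n = max(2, int(np.ceil((s1 - s0) / step)) + 1)
    s = np.linspace(s0, s1, n)
    v = np.array([-u[1], u[0]])
    if amplitude > 0:
        off = amplitude * np.sin(2 * np.pi * s / wavelength + phase)
    else:
        off = np.zeros_like(s)
    xy = start[None, :] + s[:, None] * u[None, :] + off[:, None] * v[None, :]
    return np.column_stack([xy, np.full(n, z)])


def generate_collagen_geometry(spec: FiberFieldSpec, seed: int | None = None) -> FiberGeometry:
    """Generate tightly packed wavy collagen fibers in laminar bundles.

    Each bundle is a z-slab populated with sinusoidal-centerline fibers
    until the cumulative covered area (chord length × diameter, per slab
    layer) reaches ``packing_density`` of the tile. Each fiber's axial
    chord orientation is drawn independently from the spec's Gaussian
    mixture; the draw is recorded in the truth table via ``mode_id``.
    """
    if len(spec.bundle_depths) == 0:
        raise ValueError("need at least one bundle")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    disp = spec.dispersions
    centers = np.asarray(spec.mode_centers, dtype=float)
    weights = np.asarray(spec.mode_weights, dtype=float)

    margin = spec.waviness_amplitude
    lo, hi = margin, spec.field_xy - margin
    step = min(spec.waviness_wavelength / 24.0, 1.0)
    fibers: list[Fiber] = []
    for b_id, (depth, thickness) in enumerate(spec.bundle_depths):
        n_layers = max(1, int(round(thickness / spec.fiber_diameter)))
        target = spec.packing_density * spec.field_xy**2 * n_layers
        bundle_mode = int(rng.choice(centers.size, p=weights))
        bundle_theta = float(fold180(centers[bundle_mode] + rng.normal(0.0, disp[bundle_mode])))
        covered = 0.0
        guard = 0
        while covered < target and guard < 100_000:
            guard += 1
            if spec.bundle_coherent:
                mode = bundle_mode
                theta = float(fold180(bundle_theta + rng.normal(0.0, spec.within_bundle_jitter_sd)))
            else:
                mode = int(rng.choice(centers.size, p=weights))
                theta = float(fold180(centers[mode] + rng.normal(0.0, disp[mode])))
            u = np.array([np.cos(np.deg2rad(theta)), np.sin(np.deg2rad(theta))])
            anchor = rng.uniform(lo, hi, size=2)
            s0, s1 = _line_box_range(anchor, u, lo, hi)
            if not np.isfinite(s0) or s1 - s0 < 2.0:
                continue
            half = thickness / 2 - spec.fiber_diameter / 2
            # bundle density peaks at the slab center (bundles are lens-
            # shaped, not flat slabs), so the degree-of-orientation depth
            # profile shows one peak per bundle
            z = depth if half <= 0 else depth + float(
                np.clip(rng.normal(0.0, thickness / 5.0), -half, half)
            )
            phase = rng.uniform(0, 2 * np.pi)
            pts = _sinusoid_points(
                anchor, u, s0, s1, spec.waviness_amplitude, spec.waviness_wavelength, phase, z, step
            )
            fibers.append(
                Fiber(
                    points=pts,
                    orientation_deg=theta,
                    bundle_id=b_id,
                    channel="collagen",
                    diameter_um=spec.fiber_diameter,
                    mode_id=mode,
                    amplitude_um=spec.waviness_amplitude,
                    wavelength_um=spec.waviness_wavelength,
                    phase_rad=phase,
                )
            )
            covered += (s1 - s0) * spec.fiber_diameter
    return FiberGeometry(fibers=fibers, field_xy=spec.field_xy, z_extent=spec.z_extent)


def generate_elastic_geometry(
    collagen: FiberGeometry,
    jitter_sd: float = 5.0,
    density: float = 3.0,
    seed: int = 0,
    diameter_superficial: float = 4.4,
    diameter_deep: float = 5.9,
    layer_boundary_um: float = 200.0,
    waviness_amplitude: float = 2.0,
    waviness_wavelength: float = 30.0,
) -> FiberGeometry:
    """Generate a sparse elastic network co-aligned with collagen bundles.

    Each elastic fiber adopts its bundle's collagen orientation (the axial
    mean over the bundle's fibers) plus axial Gaussian jitter of SD
    ``jitter_sd`` degrees. ``density`` is fibers per (100 µm)² per bundle;
    ``density = 0`` yields an empty geometry. Elastic fibers are thinner
    than collagen, with distinct superficial/deep default diameters, and
    carry a mild crimp of their own (mesh-like undulation).
    """
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    if density < 0:
        raise ValueError("density must be >= 0")
    rng = np.random.default_rng(seed)
    out: list[Fiber] = []
    bundles: dict[int, list[Fiber]] = {}
    for f in collagen.fibers:
        bundles.setdefault(f.bundle_id, []).append(f)
    if not bundles and density > 0:
        raise ValueError("collagen truth has no bundles")
    n_per_bundle = int(round(density * (collagen.field_xy / 100.0) ** 2))
    margin = waviness_amplitude
    lo, hi = margin, collagen.field_xy - margin
    for b_id in sorted(bundles):
        members = bundles[b_id]
        bundle_theta = axial_mean([f.orientation_deg for f in members])
        zs = np.array([np.mean(f.points[:, 2]) for f in members])
        z_lo, z_hi = float(zs.min()), float(zs.max())
        diam = diameter_superficial if np.mean(zs) < layer_boundary_um else diameter_deep
        for _ in range(n_per_bundle):
            theta = float(fold180(bundle_theta + rng.normal(0.0, jitter_sd)))
            u = np.array([np.cos(np.deg2rad(theta)), np.sin(np.deg2rad(theta))])
            anchor = rng.uniform(lo, hi, size=2)
            s0, s1 = _line_box_range(anchor, u, lo, hi)
            if not np.isfinite(s0) or s1 - s0 < 2.0:
                continue
            z = z_lo if z_hi <= z_lo else float(rng.uniform(z_lo, z_hi))
            phase = rng.uniform(0, 2 * np.pi)
            pts = _sinusoid_points(
                anchor, u, s0, s1, waviness_amplitude, waviness_wavelength, phase, z, 1.0
            )
            out.append(
                Fiber(
                    points=pts,
                    orientation_deg=theta,
                    bundle_id=b_id,
                    channel="elastic",
                    diameter_um=diam,
                    amplitude_um=waviness_amplitude,
                    wavelength_um=waviness_wavelength,
                    phase_rad=phase,
                )
            )
    return FiberGeometry(fibers=out, field_xy=collagen.field_xy, z_extent=collagen.z_extent)


def apply_biaxial_extension(geom: FiberGeometry, params: ExtensionParams) -> FiberGeometry:
    """Simulate equibiaxial extension: affine chords, conserved arc length.

    Fiber endpoints are mapped by the equal in-plane affine (x, y → λx, λy;
    z → thickness_factor·z), which preserves every in-plane chord direction
    exactly. Each fiber is then re-crimped along its new chord with the
    amplitude solved (by bisection on the arc-length residual) so that the
    fiber's arc length is conserved; once the stretched chord reaches the
    original arc length the fiber is fully straight and the amplitude is
    clamped to zero.
    """
    lam = params.lambda_xy
    tf = params.thickness_factor
    new_fibers: list[Fiber] = []
    scale = np.array([lam, lam, tf])
    for f in geom.fibers:
        L = arc_length(f.points)
        e0, e1 = f.points[0] * scale, f.points[-1] * scale
        chord = float(np.linalg.norm(e1 - e0))
        n_pts = len(f.points)
        wl = f.wavelength_um * lam
        if chord <= 0:
            new_fibers.append(replace(f, points=f.points * scale, amplitude_um=0.0))
            continue
        if L <= chord * (1 + 1e-9):
            # stretched beyond (or exactly to) straightening: straight chord
            t = np.linspace(0.0, 1.0, n_pts)[:, None]
            pts = e0[None, :] + t * (e1 - e0)[None, :]
            new_fibers.append(replace(f, points=pts, amplitude_um=0.0, wavelength_um=wl))
            continue

        u3 = (e1 - e0) / chord
        v = np.array([-u3[1], u3[0], 0.0])
        nv = np.linalg.norm(v)
        v = v / nv if nv > 0 else np.array([1.0, 0.0, 0.0])
        n = max(n_pts, int(np.ceil(chord / min(wl / 24.0, 0.5))) + 1)
        s = np.linspace(0.0, chord, n)
        # crimp offset de-trended to vanish at both ends, so the chord of
        # the rebuilt fiber is exactly the affine image of the original
        base = np.sin(2 * np.pi * s / wl + f.phase_rad)
        base = base - (base[0] + (s / chord) * (base[-1] - base[0]))

        def build(amp: float) -> np.ndarray:
            return e0[None, :] + s[:, None] * u3[None, :] + (amp * base)[:, None] * v[None, :]

        def resid(amp: float) -> float:
            return arc_length(build(amp)) - L

        a_hi = max(f.amplitude_um, 1.0)
        for _ in range(60):
            if resid(a_hi) >= 0:
                break
            a_hi *= 2.0
        amp = brentq(resid, 0.0, a_hi, xtol=1e-8, rtol=1e-12)
        new_fibers.append(replace(f, points=build(float(amp)),
                                  amplitude_um=float(amp), wavelength_um=wl))
    return FiberGeometry(
        fibers=new_fibers, field_xy=geom.field_xy * lam, z_extent=geom.z_extent * tf
    )


def rasterize_stack(
    geom: FiberGeometry,
    spec: FiberFieldSpec,
    channel: str | None = None,
    seed: int | None = None,
) -> ImageStack:
    """Render a geometry into a calibrated 8-bit z-stack.

    Each fiber is drawn as a Gaussian-profile tube whose FWHM equals its
    diameter, combined in quadrature with the in-plane PSF, then Gaussian
    read noise is added and the result is quantized to 8 bits. An empty
    geometry yields a pure background+noise stack. Slice count is
    ``z_extent/z_interval + 1``.
    """
    if seed is None:
        seed = int(np.random.SeedSequence([spec.seed, 0xA5]).generate_state(1)[0] % (2**31))
    rng = np.random.default_rng(seed)
    n_z = int(round(spec.z_extent / spec.z_interval)) + 1
    P = spec.pixels_xy
    pitch = spec.pixel_pitch
    fibers = [f for f in geom.fibers if channel is None or f.channel == channel]

    # accumulate splats per (slice, blur-σ group); blur once per group
    groups: dict[float, dict[int, np.ndarray]] = {}
    sigma_px_of: dict[float, float] = {}
    for f in fibers:
        sigma_d = f.diameter_um / _FWHM
        sigma_um = float(np.hypot(sigma_d, spec.psf_sigma))
        key = round(sigma_um, 3)
        sigma_px_of[key] = sigma_um / pitch
        canvases = groups.setdefault(key, {})
        pts = f.points
        if len(pts) < 2:
            continue
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        ds = float(seg.mean())
        w_pt = spec.fiber_intensity * np.sqrt(2 * np.pi) * sigma_px_of[key] * ds / pitch
        cols = (pts[:, 0] / pitch).round().astype(int)
        rows = (pts[:, 1] / pitch).round().astype(int)
        inside = (cols >= 0) & (cols < P) & (rows >= 0) & (rows < P)
        if not inside.any():
            continue
        pts, cols, rows = pts[inside], cols[inside], rows[inside]
        z = pts[:, 2]
        iz_lo = max(0, int(np.floor((z.min() - 3 * sigma_d) / spec.z_interval)))
        iz_hi = min(n_z - 1, int(np.ceil((z.max() + 3 * sigma_d) / spec.z_interval)))
        for iz in range(iz_lo, iz_hi + 1):
            zs = iz * spec.z_interval
            wz = np.exp(-((z - zs) ** 2) / (2 * sigma_d**2))
            if wz.max() < 1e-4:
                continue
            canvas = canvases.get(iz)
            if canvas is None:
                canvas = canvases[iz] = np.zeros((P, P), dtype=float)
            np.add.at(canvas, (rows, cols), w_pt * wz)

    from scipy.ndimage import gaussian_filter

    out = np.empty((n_z, P, P), dtype=np.uint8)
    signal: dict[int, np.ndarray] = {}
    for key, canvases in groups.items():
        for iz, canvas in canvases.items():
            blurred = gaussian_filter(canvas, sigma_px_of[key], mode="constant")
            acc = signal.get(iz)
            signal[iz] = blurred if acc is None else acc + blurred
    for iz in range(n_z):
        img = signal.get(iz, 0.0) + spec.background_level
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=(P, P))
        elif np.isscalar(img):
            img = np.full((P, P), img)
        out[iz] = np.clip(np.round(img), 0, 255).astype(np.uint8)
    ch = channel or (fibers[0].channel if fibers else "collagen")
    return ImageStack(
        data=out, pixel_pitch=pitch, z_interval=spec.z_interval, channel=ch, meta={"seed": seed}
    )


def generate_stress_strain(
    toe_limit_strain: float,
    linear_modulus: float,
    noise_sd: float = 0.0,
    n: int = 200,
    seed: int = 0,
    strip_width_mm: float = 3.0,
    strip_length_mm: float = 15.0,
    gauge_length_mm: float = 10.0,
) -> StressStrainCurve:
    """Synthesize a toe-then-linear stress–strain curve.

    The high-stress segment is the line ``E·(ε − ε*)`` with planted
    straightening strain ε* = ``toe_limit_strain``; below the knee at
    1.25·ε* an exponential toe joins it with C¹ continuity, so the
    extrapolated x-intercept of the linear region equals ε* by
    construction. Strain runs 0…3ε*; optional Gaussian stress noise is
    added and clipped at zero.
    """
    eps_star, E = toe_limit_strain, linear_modulus
    if eps_star <= 0 or E <= 0:
        raise ValueError("toe_limit_strain and linear_modulus must be positive")
    if n < 2:
        raise ValueError("need n >= 2 samples")
    knee = 1.25 * eps_star
    # C¹ join of a(e^{bε}−1) to E(ε−ε*): (1−e^{−x})/x = 1 − ε*/knee, x = b·knee
    ratio = 1.0 - eps_star / knee
    x = brentq(lambda t: (1 - np.exp(-t)) / t - ratio, 1e-9, 700.0)
    b = x / knee
    a = E / (b * np.exp(b * knee))
    strain = np.linspace(0.0, 3.0 * eps_star, n)
    stress = np.where(strain <= knee, a * (np.exp(b * strain) - 1.0), E * (strain - eps_star))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        stress = stress + rng.normal(0.0, noise_sd, size=n)
    stress = np.clip(stress, 0.0, None)
    return StressStrainCurve(
        strain=strain,
        stress=stress,
        meta=dict(
            strip_width_mm=strip_width_mm,
            strip_length_mm=strip_length_mm,
            gauge_length_mm=gauge_length_mm,
            planted_toe_limit_strain=eps_star,
        ),
    )
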