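"""Seeded synthetic phantoms emulating corrosion-cast scans.

The sinusoidal bed is modelled as a stationary isotropic Boolean model of
dilated line segments: a Poisson number of segments with uniform positions
(in a domain extended by segment half-length plus maximal radius, so the
restriction to the image window is stationary) and orientations uniform on
the sphere, each dilated to a cylinder with diameter drawn from a clipped
lognormal on 5-9 um.  The expected volume fraction of a Boolean cylinder
model is ``1 - exp(-lambda E[v])``, which fixes the segment intensity for a
requested volume fraction.

Macrovessels are straight tubes (> 30 um diameter) crossing the volume.
Their interior renders either at an intermediate bright level that a global
threshold assigns to the foreground ("filled", case 1) or background-like
with a bright rim ("hollow", case 2).  Transluminal pillars are carved as
transverse background tunnels through a host vessel; blind pockets as
dead-end indentations.  Rendering assigns mean intensities per phase,
applies a Gaussian point-spread blur and additive Gaussian noise, all from
a single seeded generator: every output is a pure function of the spec.

The generator reproduces the statistical structure the analysis assumes
(stationarity, isotropy, diameter range, tunnel band), not the connected
network topology of real sinusoids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from . import _morph
from .volume_io import BinaryVolume, GrayVolume

FILLED_CASE1 = "filled_case1"
HOLLOW_CASE2 = "hollow_case2"


@dataclass
class MacroTubeSpec:
    """A straight macrovessel crossing the whole volume along one axis."""

    axis: int                      # 0, 1 or 2
    center_um: tuple[float, float] # position in the two transverse axes
    diameter_um: float
    interior_mode: str = HOLLOW_CASE2

    def __post_init__(self) -> None:
        if self.diameter_um <= 30:
            raise ValueError("macrovessels have diameter > 30 um")
        if self.interior_mode not in (FILLED_CASE1, HOLLOW_CASE2):
            raise ValueError(f"unknown interior mode {self.interior_mode}")


@dataclass
class PhantomSpec:
    seed: int = 0
    dims: tuple[int, int, int] = (128, 128, 128)
    spacing: float = 0.65            # um per voxel edge
    target_vv: float | None = 0.15   # requested sinusoid volume fraction
    fiber_intensity: float | None = None  # segments per um^3 (overrides target_vv)
    segment_length_um: float = 30.0  # inter-branch segment length
    diameter_log_mean: float = 1.917  # ln(6.8 um)
    diameter_log_sigma: float = 0.12
    diameter_range_um: tuple[float, float] = (5.0, 9.0)
    macrovessels: tuple[MacroTubeSpec, ...] = ()
    wall_clearance_um: float = 4.0   # sinusoid-free gap around macrovessels
    rim_thickness_um: float = 8.0    # bright rim of hollow macrovessels
    # intensity model
    mu_background: float = 40.0
    mu_cast: float = 200.0
    mu_interior: float = 140.0       # filled (case 1) macro interior
    mu_hollow: float = 45.0          # hollow (case 2) macro interior
    mu_rim: float = 240.0
    noise_sigma: float = 8.0
    blur_sigma_vox: float = 0.7

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.mu_cast <= self.mu_background:
            raise ValueError("cast must be brighter than background")


@dataclass
class GroundTruth:
    sinusoid_mask: BinaryVolume
    macro_mask: BinaryVolume
    total_fiber_length_um: float
    true_V_V: float
    #: expected excess of M/pi over the centerline length: 2r per rounded
    #: segment end inside the volume plus pi*r/2 per boundary cut face
    end_correction_um: float = 0.0
    pillars: list[dict] = field(default_factory=list)
    pockets: list[dict] = field(default_factory=list)


def _rasterize_segment(mask: np.ndarray, p0: np.ndarray, p1: np.ndarray,
                       radius_vox: float) -> None:
    """OR a solid cylinder (with rounded caps) into ``mask`` (voxel coords)."""
    lo = np.floor(np.minimum(p0, p1) - radius_vox - 1).astype(int)
    hi = np.ceil(np.maximum(p0, p1) + radius_vox + 2).astype(int)
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, mask.shape)
    if (lo >= hi).any():
        return
    grids = np.meshgrid(*[np.arange(a, b) for a, b in zip(lo, hi)], indexing="ij")
    p = np.stack(grids, axis=-1).astype(float)
    seg = p1 - p0
    L2 = float(seg @ seg)
    if L2 == 0:
        d2 = ((p - p0) ** 2).sum(-1)
    else:
        t = np.clip(((p - p0) @ seg) / L2, 0.0, 1.0)
        proj = p0 + t[..., None] * seg
        d2 = ((p - proj) ** 2).sum(-1)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    mask[sl] |= d2 <= radius_vox**2


def _draw_diameter(rng: np.random.Generator, spec: PhantomSpec) -> float:
    lo, hi = spec.diameter_range_um
    for _ in range(100):
        d = rng.lognormal(spec.diameter_log_mean, spec.diameter_log_sigma)
        if lo <= d <= hi:
            return d
    return float(np.clip(d, lo, hi))


def _expected_segment_volume(spec: PhantomSpec, n: int = 4096) -> float:
    """Mean volume of one grain: a spherocylinder (the rasterizer rounds the
    segment ends)."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xE5]))
    d = np.array([_draw_diameter(rng, spec) for _ in range(n)])
    r = d / 2
    return float(np.mean(np.pi * r**2 * spec.segment_length_um
                         + 4.0 / 3.0 * np.pi * r**3))


def macro_tube_mask(spec: PhantomSpec) -> BinaryVolume:
    """Union of the macrovessel lumina (solid tubes)."""
    mask = np.zeros(spec.dims, dtype=bool)
    for tube in spec.macrovessels:
        ax = tube.axis
        rem = [a for a in range(3) if a != ax]
        shape2 = (spec.dims[rem[0]], spec.dims[rem[1]])
        g = np.meshgrid(*[np.arange(n) for n in shape2], indexing="ij")
        c = [cu / spec.spacing for cu in tube.center_um]
        r_vox = (tube.diameter_um / 2.0) / spec.spacing
        disc = (g[0] - c[0]) ** 2 + (g[1] - c[1]) ** 2 <= r_vox**2
        mask |= _tube_broadcast(disc, ax, spec.dims)
    return BinaryVolume(mask, spec.spacing)


def _tube_broadcast(disc: np.ndarray, axis: int, dims: tuple[int, int, int]) -> np.ndarray:
    out = np.expand_dims(disc, axis=axis)
    reps = [1, 1, 1]
    reps[axis] = dims[axis]
    return np.tile(out, reps)


def generate_fiber_system(
    spec: PhantomSpec, exclusion: np.ndarray | None = None
) -> GroundTruth:
    """Realize the Boolean segment model of the sinusoidal bed.

    ``exclusion`` (e.g. macrovessels plus wall clearance) is carved out of
    the fiber mask; the recorded centerline length counts only centerline
    inside the volume and outside the exclusion.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xF1]))
    dims = np.array(spec.dims)
    s = spec.spacing
    L_vox = spec.segment_length_um / s
    r_max_vox = (spec.diameter_range_um[1] / 2) / s

    if spec.fiber_intensity is not None:
        lam = spec.fiber_intensity
    else:
        vv = spec.target_vv if spec.target_vv is not None else 0.15
        if not 0 <= vv <= 0.5:
            raise ValueError("requested volume fraction must be in [0, 0.5] "
                             "(higher is not cast-like)")
        lam = -np.log(1.0 - vv) / _expected_segment_volume(spec)  # per um^3

    pad = L_vox / 2 + r_max_vox + 1
    ext_lo, ext_hi = -pad, dims + pad
    ext_vol_um3 = float(np.prod((ext_hi - ext_lo) * s))
    n_seg = int(rng.poisson(lam * ext_vol_um3))

    mask = np.zeros(spec.dims, dtype=bool)
    length = 0.0
    end_corr = 0.0
    step = 0.25
    for _ in range(n_seg):
        c = rng.uniform(ext_lo, ext_hi)
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        d_um = _draw_diameter(rng, spec)
        r_vox = (d_um / 2.0) / s
        p0, p1 = c - u * L_vox / 2, c + u * L_vox / 2
        _rasterize_segment(mask, p0, p1, r_vox)
        # centerline length inside the volume (and outside the exclusion)
        nstep = max(2, int(np.ceil(L_vox / step)))
        t = np.linspace(0.0, 1.0, nstep)
        pts = p0 + t[:, None] * (p1 - p0)
        idx = np.round(pts).astype(int)
        inside = ((idx >= 0) & (idx < dims)).all(axis=1)
        counted = inside.copy()
        if exclusion is not None and inside.any():
            ii = idx[inside]
            counted[inside] = ~exclusion[ii[:, 0], ii[:, 1], ii[:, 2]]
        length += float(counted.sum() / nstep) * spec.segment_length_um
        if counted[0]:
            end_corr += d_um  # rounded cap: 2r
        if counted[-1]:
            end_corr += d_um
        crossings = int(np.abs(np.diff(counted.astype(int))).sum())
        end_corr += crossings * np.pi * d_um / 4.0  # cut face: pi*r/2

    if exclusion is not None:
        mask &= ~exclusion
        avail = int(np.prod(spec.dims)) - int(exclusion.sum())
    else:
        avail = int(np.prod(spec.dims))
    vv_real = mask.sum() / avail if avail else 0.0
    return GroundTruth(
        sinusoid_mask=BinaryVolume(mask, s),
        macro_mask=BinaryVolume(np.zeros(spec.dims, bool), s),
        total_fiber_length_um=length,
        true_V_V=float(vv_real),
        end_correction_um=float(end_corr),
    )


def _local_edt_at(mask: np.ndarray, c: np.ndarray, half: int = 64) -> float:
    """Distance from voxel ``c`` to the nearest background voxel, computed
    in a local window (valid while the true distance is below ``half``)."""
    from scipy.ndimage import distance_transform_edt

    lo = np.maximum(c - half, 0)
    hi = np.minimum(c + half + 1, mask.shape)
    sub = mask[tuple(slice(a, b) for a, b in zip(lo, hi))]
    if sub.all():
        return float(half)
    return float(distance_transform_edt(sub)[tuple(c - lo)])


def place_disjoint_fibers(
    spec: PhantomSpec, n_fibers: int, min_gap_vox: float = 2.0, max_tries: int = 2000
) -> GroundTruth:
    """Rejection-sample ``n_fibers`` pairwise disjoint spherocylinders fully
    inside the volume.

    Unlike the Boolean model, the centerline length and end corrections are
    exact (no grain overlap), which makes this the reference structure for
    validating the length estimator M/pi.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xD7]))
    dims = np.array(spec.dims)
    s = spec.spacing
    L_vox = spec.segment_length_um / s
    mask = np.zeros(spec.dims, dtype=bool)
    length = 0.0
    end_corr = 0.0
    placed = 0
    for _ in range(max_tries):
        if placed == n_fibers:
            break
        d_um = _draw_diameter(rng, spec)
        r_vox = (d_um / 2.0) / s
        margin = r_vox + min_gap_vox + 1
        c = rng.uniform(margin + L_vox / 2, dims - margin - L_vox / 2)
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        p0, p1 = c - u * L_vox / 2, c + u * L_vox / 2
        if (np.minimum(p0, p1) < margin).any() or (np.maximum(p0, p1) > dims - margin).any():
            continue
        probe = np.zeros_like(mask)
        _rasterize_segment(probe, p0, p1, r_vox + min_gap_vox)
        if (probe & mask).any():
            continue
        _rasterize_segment(mask, p0, p1, r_vox)
        length += spec.segment_length_um
        end_corr += 2 * d_um  # two rounded caps, 2r each
        placed += 1
    if placed < n_fibers:
        raise RuntimeError(f"placed only {placed}/{n_fibers} disjoint fibers")
    return GroundTruth(
        sinusoid_mask=BinaryVolume(mask, s),
        macro_mask=BinaryVolume(np.zeros(spec.dims, bool), s),
        total_fiber_length_um=length,
        true_V_V=float(mask.sum() / mask.size),
        end_correction_um=float(end_corr),
    )


def insert_pillar(
    mask: BinaryVolume,
    center_vox: tuple[int, int, int],
    diameter_um: float,
    direction: tuple[float, float, float] | None = None,
) -> tuple[BinaryVolume, dict]:
    """Carve a transverse through-tunnel (the cast shadow of a tissue
    pillar) of ``diameter_um`` through the vessel covering ``center_vox``.

    The host vessel must be thicker than the tunnel (local thickness >
    diameter + 2 voxels).  Without an explicit direction the tunnel runs
    along the coordinate axis with the shortest foreground chord through
    the centre (the transverse direction).
    """
    m = mask.mask
    s = mask.spacing
    c = np.asarray(center_vox)
    if not m[tuple(c)]:
        raise ValueError("host position is not inside the vessel system")
    host_radius = _local_edt_at(m, c)
    host_thickness_um = 2.0 * host_radius * s
    if host_thickness_um <= diameter_um + 2 * s:
        raise ValueError(
            f"host vessel too thin: local thickness {host_thickness_um:.2f} um, "
            f"tunnel needs > {diameter_um + 2 * s:.2f} um"
        )
    if direction is None:
        chords = []
        for ax in range(3):
            n = 0
            for sgn in (-1, 1):
                p = c.copy()
                while 0 <= p[ax] < m.shape[ax] and m[tuple(p)]:
                    n += 1
                    p[ax] += sgn
            chords.append(n)
        u = np.zeros(3)
        u[int(np.argmin(chords))] = 1.0
        half = (chords[int(np.argmin(chords))] / 2 + 3)
    else:
        u = np.asarray(direction, dtype=float)
        u /= np.linalg.norm(u)
        half = host_radius * 4 + 3
    out = m.copy()
    tunnel = np.zeros_like(m)
    _rasterize_segment(tunnel, c - u * half, c + u * half,
                       (diameter_um / 2.0) / s)
    out &= ~tunnel
    record = {
        "center_vox": tuple(int(v) for v in c),
        "direction": tuple(float(v) for v in u),
        "diameter_um": float(diameter_um),
    }
    return BinaryVolume(out, s), record


def insert_pocket(
    mask: BinaryVolume,
    center_vox: tuple[int, int, int],
    diameter_um: float,
    direction: tuple[float, float, float] | None = None,
) -> tuple[BinaryVolume, dict]:
    """Carve a blind (dead-end) indentation: a tunnel that enters from one
    side and stops at the host centre."""
    m = mask.mask
    s = mask.spacing
    c = np.asarray(center_vox)
    if not m[tuple(c)]:
        raise ValueError("host position is not inside the vessel system")
    host_radius = _local_edt_at(m, c)
    host_thickness_um = 2.0 * host_radius * s
    if host_thickness_um <= diameter_um + 2 * s:
        raise ValueError("host vessel too thin for the pocket")
    if direction is None:
        chords = []
        for ax in range(3):
            n = 0
            for sgn in (-1, 1):
                p = c.copy()
                while 0 <= p[ax] < m.shape[ax] and m[tuple(p)]:
                    n += 1
                    p[ax] += sgn
            chords.append(n)
        u = np.zeros(3)
        u[int(np.argmin(chords))] = 1.0
        half = (chords[int(np.argmin(chords))] / 2 + 3)
    else:
        u = np.asarray(direction, dtype=float)
        u /= np.linalg.norm(u)
        half = host_radius + 3
    out = m.copy()
    pocket = np.zeros_like(m)
    _rasterize_segment(pocket, c, c + u * half, (diameter_um / 2.0) / s)
    out &= ~pocket
    record = {
        "center_vox": tuple(int(v) for v in c),
        "direction": tuple(float(v) for v in u),
        "diameter_um": float(diameter_um),
    }
    return BinaryVolume(out, s), record


def pillar_study_phantom(
    seed: int = 0,
    n: int = 256,
    spacing: float = 0.325,
    n_tunnels: int = 10,
    n_pockets: int = 5,
    tunnel_band_um: tuple[float, float] = (2.0, 4.0),
    host_diameter_um: float = 20.0,
) -> GroundTruth:
    """Deterministic pillar-detection study: straight 20 um host tubes
    carrying ``n_tunnels`` transluminal tunnels (diameters in the given
    band) and ``n_pockets`` blind pockets, pairwise separated by > 10 um
    and away from the volume boundary.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x91]))
    r = (host_diameter_um / 2.0) / spacing
    q = n // 4
    centers = [(q, q), (q, 3 * q), (3 * q, q), (3 * q, 3 * q)]
    mask = np.zeros((n, n, n), bool)
    g = np.mgrid[:n, :n]
    for cx, cy in centers:
        disc = (g[0] - cx) ** 2 + (g[1] - cy) ** 2 <= r**2
        mask |= np.repeat(disc[:, :, None], n, axis=2)
    X = BinaryVolume(mask, spacing)

    # slots: one per (tube, z-station); stations keep > 10 um separation
    margin = int(np.ceil((5.0 + 2 * spacing) / spacing)) + 4
    stations = np.linspace(margin + r, n - margin - r, 4).astype(int)
    slots = [(t, int(z)) for t in range(4) for z in stations]
    rng.shuffle(slots)
    if n_tunnels + n_pockets > len(slots):
        raise ValueError("too many structures for the slot grid")

    lo, hi = tunnel_band_um
    truth = GroundTruth(
        sinusoid_mask=X,
        macro_mask=BinaryVolume(np.zeros((n, n, n), bool), spacing),
        total_fiber_length_um=4 * n * spacing,
        true_V_V=float(mask.mean()),
    )
    for i in range(n_tunnels):
        t, z = slots[i]
        d = float(rng.uniform(lo, hi))
        X, rec = insert_pillar(X, (centers[t][0], centers[t][1], z), d)
        truth.pillars.append(rec)
    for i in range(n_tunnels, n_tunnels + n_pockets):
        t, z = slots[i]
        d = float(rng.uniform(lo, hi))
        X, rec = insert_pocket(X, (centers[t][0], centers[t][1], z), d)
        truth.pockets.append(rec)
    truth.sinusoid_mask = X
    return truth


def render_grayscale(truth: GroundTruth, spec: PhantomSpec) -> GrayVolume:
    """Render ground truth to a noisy 8-bit scan.

    Cast voxels take ``mu_cast``; macrovessel interiors take ``mu_interior``
    (filled regime) or ``mu_hollow`` with a ``mu_rim`` rim (hollow regime);
    everything else is ``mu_background``.  A Gaussian point-spread blur and
    additive Gaussian noise follow, both seeded from the spec.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xAB]))
    img = np.full(spec.dims, spec.mu_background, dtype=np.float32)
    img[truth.sinusoid_mask.mask] = spec.mu_cast

    if truth.macro_mask.mask.any():
        for tube in spec.macrovessels:
            single = PhantomSpec(seed=spec.seed, dims=spec.dims, spacing=spec.spacing,
                                 macrovessels=(tube,))
            tm = macro_tube_mask(single).mask
            if tube.interior_mode == FILLED_CASE1:
                img[tm] = spec.mu_interior
            else:
                rim_vox = spec.rim_thickness_um / spec.spacing
                inner = _morph.erode_ball(tm, rim_vox)
                img[tm & ~inner] = spec.mu_rim
                img[inner] = spec.mu_hollow

    if spec.blur_sigma_vox > 0:
        img = ndi.gaussian_filter(img, spec.blur_sigma_vox)
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape).astype(np.float32)
    return GrayVolume(np.clip(np.round(img), 0, 255).astype(np.uint8), spec.spacing)


def generate_phantom(spec: PhantomSpec) -> tuple[GroundTruth, GrayVolume]:
    """Convenience: macrovessels + clearance, fiber system, rendering."""
    macro = macro_tube_mask(spec)
    if macro.mask.any():
        clearance = _morph.dilate_ball(macro.mask,
                                       spec.wall_clearance_um / spec.spacing)
    else:
        clearance = None
    truth = generate_fiber_system(spec, exclusion=clearance)
    truth.macro_mask = macro
    gray = render_grayscale(truth, spec)
    return truth, gray
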