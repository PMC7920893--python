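"""Detection of intussusceptive pillars.

In a corrosion cast a transluminal tissue pillar appears as a small tunnel
(1-5 um inner diameter) through the resin foreground.  Detection follows a
two-step topological scheme:

1. candidate holes are marked: connected components of
   ``close(X, ball(d_max)) \\ X`` whose maximum local thickness lies in
   ``[d_min, d_max]``;
2. each candidate is classified by the Euler characteristic of its sleeve,
   the foreground shell ``X n dilate(marker, 1 voxel)``: a through-tunnel
   has a tube-like sleeve (chi = 0, torus-equivalent) and counts as a
   pillar; a blind pocket has a cap-like sleeve (chi = 1) and is rejected.

The topology of markers touching the image boundary is not observable, so
those are excluded and intensities are estimated on a minus-sampled reduced
window: only pillars anchored (lexicographically smallest voxel) inside the
reduced window count, making the counts translation- and padding-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from . import _morph
from ._minkowski import euler_characteristic
from .macrovessel import MeasurementWindow
from .volume_io import BinaryVolume

PILLAR = "pillar"
REJECTED = "rejected"
UNOBSERVABLE = "unobservable"
PENDING = "pending"


@dataclass
class PillarMarker:
    """A candidate transluminal tunnel."""

    voxels: np.ndarray            # (n, 3) int voxel coordinates
    anchor: tuple[int, int, int]  # lexicographically smallest voxel
    bbox: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]  # half-open
    max_thickness_um: float
    status: str = PENDING
    sleeve_chi: int | None = None


def _component_markers(holes: np.ndarray, spacing: float) -> list[PillarMarker]:
    labels, nlab = _morph.label_foreground(holes)
    if nlab == 0:
        return []
    edt = ndi.distance_transform_edt(holes)
    objects = ndi.find_objects(labels)
    # max inscribed-ball radius per component = max EDT over the component
    max_r = ndi.maximum(edt, labels=labels, index=np.arange(1, nlab + 1))
    markers = []
    shape = holes.shape
    for lab, (sl, r) in enumerate(zip(objects, np.atleast_1d(max_r)), start=1):
        comp = labels[sl] == lab
        coords = np.argwhere(comp) + np.array([s.start for s in sl])
        order = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0]))
        coords = coords[order]
        bbox = tuple((s.start, s.stop) for s in sl)
        # the ball closing cannot seal holes right at the faces, so a hole
        # leaving the image yields a residue stopping just short of it
        touches = any(s.start <= 2 or s.stop >= n - 2 for s, n in zip(sl, shape))
        markers.append(
            PillarMarker(
                voxels=coords,
                anchor=tuple(int(c) for c in coords[0]),
                bbox=bbox,  # type: ignore[arg-type]
                max_thickness_um=float(2.0 * r * spacing),
                status=UNOBSERVABLE if touches else PENDING,
            )
        )
    return markers


def mark_holes(
    X: BinaryVolume, d_min_um: float = 1.0, d_max_um: float = 5.0
) -> list[PillarMarker]:
    """Mark candidate holes with inner diameter in ``[d_min, d_max]`` um.

    Candidates are the 26-connected components of the closing residue
    ``close(X, ball of diameter d_max) \\ X`` whose maximum local thickness
    (largest inscribed ball) lies in the diameter band.  Components whose
    bounding box touches the volume boundary are flagged unobservable.
    """
    if not 0 < d_min_um < d_max_um:
        raise ValueError("require 0 < d_min < d_max")
    spacing = X.spacing
    r_close = (d_max_um / 2.0) / spacing
    closed = _morph.close_ball(X.mask, r_close)
    holes = closed & ~X.mask
    markers = _component_markers(holes, spacing)
    return [m for m in markers if d_min_um <= m.max_thickness_um <= d_max_um]


def classify_marker(
    marker: PillarMarker, X: BinaryVolume, sleeve_radius_vox: int = 1
) -> str:
    """Classify a marker by the Euler characteristic of its sleeve
    ``X n dilate(marker, sleeve_radius)``: chi = 0 (open tube, torus
    equivalent) means pillar; anything else is rejected.  Unobservable
    markers are left untouched."""
    if marker.status == UNOBSERVABLE:
        return UNOBSERVABLE
    pad = sleeve_radius_vox + 2
    (x0, x1), (y0, y1), (z0, z1) = marker.bbox
    shape = X.mask.shape
    lo = [max(0, x0 - pad), max(0, y0 - pad), max(0, z0 - pad)]
    hi = [min(shape[0], x1 + pad), min(shape[1], y1 + pad), min(shape[2], z1 + pad)]
    sub = X.mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    mbox = np.zeros_like(sub)
    v = marker.voxels - np.array(lo)
    mbox[v[:, 0], v[:, 1], v[:, 2]] = True
    sleeve = sub & _morph.dilate_ball(mbox, float(sleeve_radius_vox))
    chi = euler_characteristic(sleeve)
    marker.sleeve_chi = chi
    marker.status = PILLAR if chi == 0 else REJECTED
    return marker.status


def minus_sampling_window(
    W: MeasurementWindow, margin_um: float
) -> MeasurementWindow:
    """Reduce W so that every marker anchored inside is fully observable:
    erode by a cube of half-edge ``margin`` and trim a ``margin`` slab at
    each volume face."""
    if margin_um < 0:
        raise ValueError("margin must be >= 0")
    spacing = W.mask.spacing
    m = int(np.ceil(margin_um / spacing))
    mask = W.mask.mask
    if m > 0:
        mask = _morph.erode_cube(mask, 2 * m + 1)
        interior = np.zeros_like(mask)
        interior[m:-m or None, m:-m or None, m:-m or None] = True
        mask = mask & interior
    if not mask.any():
        raise ValueError("reduced window is empty")
    return MeasurementWindow(BinaryVolume(mask, spacing))


@dataclass
class PillarIntensities:
    N: int
    N_V: float   # per um^3 tissue
    N_V2: float  # per um^3 microvascular volume
    N_L: float   # per um microvascular length


def pillar_intensities(
    markers: list[PillarMarker],
    W_reduced: MeasurementWindow,
    X: BinaryVolume,
    L_V: float,
) -> PillarIntensities:
    """The three pillar-intensity normalizations on the reduced window:
    N_V = N/V(W), N_V2 = N/V(X), N_L = N/(L_V V(W)), with V(W), V(X) and
    L_V all referred to the reduced window."""
    if W_reduced.volume <= 0:
        raise ValueError("empty reduced window")
    wm = W_reduced.mask.mask
    N = sum(
        1 for m in markers
        if m.status == PILLAR and wm[m.anchor[0], m.anchor[1], m.anchor[2]]
    )
    if N == 0:
        return PillarIntensities(0, 0.0, 0.0, 0.0)
    V_W = W_reduced.volume
    V_X = float((X.mask & wm).sum()) * X.spacing**3
    if V_X <= 0:
        raise ValueError("pillars counted but V(X) = 0 in the reduced window")
    if L_V <= 0:
        raise ValueError("pillars counted but L_V = 0 in the reduced window")
    return PillarIntensities(
        N=N,
        N_V=N / V_W,
        N_V2=N / V_X,
        N_L=N / (L_V * V_W),
    )


def default_minus_margin_um(d_max_um: float, spacing: float) -> float:
    """Default minus-sampling margin: d_max plus one voxel."""
    return d_max_um + spacing
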