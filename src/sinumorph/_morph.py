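"""Binary morphology primitives shared across the pipeline.

Cubical structuring elements may have even edge length (the macrovessel
workflow uses cubes of size 4, 6, 20 and 92).  An even cube of edge ``s``
is anchored at ``floor(s/2)``, i.e. covers offsets ``{-s//2, ..., s-1-s//2}``
per axis; openings and closings use the reflected element for the dilation
half so they remain proper (idempotent, anti-/extensive) morphological
filters.  Ball elements are digital balls: all voxels whose centre distance
to the seed is at most ``r``; ball operations are computed through the exact
Euclidean distance transform.  Outside the volume counts as background.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi


def _check_size(size: int) -> None:
    if size < 1:
        raise ValueError("structuring element size must be >= 1")


def erode_cube(mask: np.ndarray, size: int) -> np.ndarray:
    """Erosion by the anchored cube B; outside the volume is background."""
    _check_size(size)
    if size == 1:
        return mask.copy()
    out = ndi.minimum_filter(mask.astype(np.uint8), size=size, mode="constant", cval=0)
    return out.astype(bool)


def dilate_cube(mask: np.ndarray, size: int, reflected: bool = False) -> np.ndarray:
    """Minkowski dilation by the anchored cube B (``reflected=True`` uses the
    point-reflected element instead)."""
    _check_size(size)
    if size == 1:
        return mask.copy()
    # max_filter window at origin 0 is B itself; dilation by B scans the
    # reflected window (origin -1 for even sizes), and vice versa.
    origin = 0 if (size % 2 or reflected) else -1
    out = ndi.maximum_filter(mask.astype(np.uint8), size=size, origin=origin, mode="constant", cval=0)
    return out.astype(bool)


def open_cube(mask: np.ndarray, size: int) -> np.ndarray:
    """Opening (X erode B) dilate B — anti-extensive and idempotent."""
    return dilate_cube(erode_cube(mask, size), size, reflected=False)


def close_cube(mask: np.ndarray, size: int) -> np.ndarray:
    """Closing (X dilate B) erode B with background padding so the dilation
    half is not clipped at the volume boundary."""
    _check_size(size)
    if size == 1:
        return mask.copy()
    p = size
    padded = np.pad(mask, p, mode="constant", constant_values=False)
    closed = erode_cube(dilate_cube(padded, size, reflected=False), size)
    sl = tuple(slice(p, -p) for _ in range(mask.ndim))
    return closed[sl]


def ball_element(radius_vox: float) -> np.ndarray:
    """Digital ball: voxels whose centre distance to the seed is <= r."""
    r = int(np.floor(radius_vox))
    g = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    return (g**2).sum(axis=0) <= radius_vox**2


def dilate_ball(mask: np.ndarray, radius_vox: float) -> np.ndarray:
    """Dilation with a digital ball via the Euclidean distance transform."""
    if radius_vox < 0:
        raise ValueError("radius must be >= 0")
    if radius_vox == 0 or not mask.any():
        return mask.copy()
    return ndi.distance_transform_edt(~mask) <= radius_vox


def erode_ball(mask: np.ndarray, radius_vox: float) -> np.ndarray:
    if radius_vox < 0:
        raise ValueError("radius must be >= 0")
    if radius_vox == 0:
        return mask.copy()
    return ndi.distance_transform_edt(mask) > radius_vox


def close_ball(mask: np.ndarray, radius_vox: float) -> np.ndarray:
    """Ball closing; the volume is padded so the dilation half does not
    interact with the image boundary."""
    if radius_vox == 0 or not mask.any():
        return mask.copy()
    p = int(np.ceil(radius_vox)) + 1
    padded = np.pad(mask, p, mode="constant", constant_values=False)
    closed = erode_ball(dilate_ball(padded, radius_vox), radius_vox)
    sl = tuple(slice(p, -p) for _ in range(mask.ndim))
    return closed[sl]


def label_foreground(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """26-adjacency labeling of foreground components."""
    return ndi.label(mask, structure=np.ones((3, 3, 3), bool))


def label_background(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """6-adjacency labeling of background components (complementary pair)."""
    return ndi.label(~mask, structure=ndi.generate_binary_structure(3, 1))


def background_face_counts(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Label the background (6-adjacency) and count, for each component,
    how many of the six volume faces it touches.

    Returns ``(labels, face_counts, nlab)`` where ``face_counts[i]`` belongs
    to label ``i`` (entry 0 is the foreground and is 0).
    """
    labels, nlab = label_background(mask)
    touched = np.zeros((nlab + 1, 6), bool)
    faces = [
        labels[0, :, :], labels[-1, :, :],
        labels[:, 0, :], labels[:, -1, :],
        labels[:, :, 0], labels[:, :, -1],
    ]
    for i, face in enumerate(faces):
        touched[np.unique(face), i] = True
    touched[0] = False
    return labels, touched.sum(axis=1), nlab
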