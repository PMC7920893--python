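"""Extraction of macrovessels (diameter > 30 um) and construction of the
capillary measurement window W.

In a corrosion cast every vessel lumen is resin, but large lumina image in
one of two regimes: the interior renders at an intermediate bright level
that a global Otsu threshold assigns (mostly) to the foreground (case 1,
"filled interior"), or the interior renders background-like with only a
bright rim (case 2, "hollow interior").  The workflow is case specific:

* case 1 — band threshold ``[t_low, t_high)`` bracketing the intermediate
  interior level (``t_low`` below the global Otsu threshold, ``t_high``
  above it, both from recursive Otsu on the respective sub-histograms),
  smoothing (closing 4, opening 6, dilation 6), subtraction of the Otsu
  binarization;
* case 2 — raised threshold (recursive Otsu above the global threshold)
  keeping the bright rim only, smoothing (closing 4, opening 6, dilation
  20), intersection with the Otsu binarization.

The result of either branch is a detection mask whose components are size
filtered: a component is retained iff, after filling its interior cavities
(sealing cavities that leave the image through at most two volume faces,
as a tubular lumen crossing the scan does), a 92-voxel cube — 29.9 um at
the native 325 nm spacing — fits inside it.  The returned macrovessel mask
is the sealed fill of the pre-dilation smoothed core restricted to retained
detections, i.e. solid lumina without the dilation margin, so that the mask
tracks the true vessel rather than a dilated halo.

The measurement window W is the scan domain minus the macrovessels dilated
by a 15 um ball: capillary liver tissue only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _morph
from .segmentation import _otsu_split, binarize, otsu_threshold
from .volume_io import BinaryVolume, GrayVolume

FILLED_INTERIOR = "filled_interior"
HOLLOW_INTERIOR = "hollow_interior"
NONE = "none"

#: sinusoids are vessels below this diameter; anything larger is a macrovessel
MACRO_DIAMETER_UM = 30.0


@dataclass
class MacrovesselParams:
    case: str = "auto"  # auto | filled_interior | hollow_interior
    closing_size: int = 4
    opening_size: int = 6
    dilation_size_case1: int = 6
    dilation_size_case2: int = 20
    size_opening_um: float = 29.9  # 92 voxels at 325 nm spacing
    exclusion_radius_um: float = 15.0
    t_low_override: float | None = None
    t_high_override: float | None = None

    def __post_init__(self) -> None:
        for s in (self.closing_size, self.opening_size,
                  self.dilation_size_case1, self.dilation_size_case2):
            if s < 1:
                raise ValueError("structuring element sizes must be >= 1")
        if self.exclusion_radius_um < 0:
            raise ValueError("exclusion radius must be >= 0")

    def size_opening_vox(self, spacing: float) -> int:
        return max(1, int(round(self.size_opening_um / spacing)))


@dataclass
class MeasurementWindow:
    """Region of the scan belonging to capillary liver tissue."""

    mask: BinaryVolume
    volume: float = field(init=False)  # um^3

    def __post_init__(self) -> None:
        self.volume = self.mask.volume_um3()


def _sub_otsu(volume: GrayVolume, mask_below: bool, t_global: float) -> float:
    """Otsu threshold on the sub-histogram below/above the global threshold."""
    sel = volume.data < t_global if mask_below else volume.data >= t_global
    vals = volume.data[sel].astype(np.float64)
    lo, hi = float(vals.min()), float(vals.max())
    if lo == hi:
        return t_global
    hist, edges = np.histogram(vals, bins=256, range=(lo, hi))
    return float(edges[_otsu_split(hist) + 1])


def _fill_sealed(mask: np.ndarray, max_open_faces: int = 2) -> np.ndarray:
    """Fill background cavities, treating cavities that leave the volume
    through at most ``max_open_faces`` faces (e.g. a lumen crossing the
    scan) as enclosed."""
    labels, faces, nlab = _morph.background_face_counts(mask)
    if nlab == 0:
        return mask.copy()
    fill = faces <= max_open_faces
    fill[0] = False
    return mask | fill[labels]


def classify_case(volume: GrayVolume, otsu_mask: BinaryVolume,
                  params: MacrovesselParams | None = None) -> str:
    """Decide the macrovessel imaging regime of a scan.

    hollow_interior: the raw Otsu binarization contains a background cavity
    larger than a (30 um)^3 volume (cavities may leave the image through up
    to two faces).  filled_interior: a foreground component survives the
    size-opening cube without such cavities.  none: neither.
    """
    params = params or MacrovesselParams()
    spacing = otsu_mask.spacing
    cavity_vox = (MACRO_DIAMETER_UM / spacing) ** 3
    labels, faces, nlab = _morph.background_face_counts(otsu_mask.mask)
    if nlab:
        sizes = np.bincount(labels.ravel(), minlength=nlab + 1)
        sizes[0] = 0
        cavity = (faces <= 2) & (sizes > cavity_vox)
        cavity[0] = False
        if cavity.any():
            return HOLLOW_INTERIOR
    filled = _fill_sealed(otsu_mask.mask)
    if _morph.erode_cube(filled, params.size_opening_vox(spacing)).any():
        return FILLED_INTERIOR
    return NONE


def size_filter_components(candidates: BinaryVolume, cube_edge: int = 92) -> BinaryVolume:
    """Retain whole candidate components into which a ``cube_edge`` cube fits
    after filling their interior cavities; remove the rest.

    Components are never split: each is kept or dropped in full.
    """
    if cube_edge < 1:
        raise ValueError("cube_edge must be >= 1")
    mask = candidates.mask
    if not mask.any():
        return BinaryVolume(np.zeros_like(mask), candidates.spacing)
    filled = _fill_sealed(mask)
    labels, nlab = _morph.label_foreground(filled)
    survivors = _morph.erode_cube(filled, cube_edge)
    keep = np.zeros(nlab + 1, dtype=bool)
    keep[np.unique(labels[survivors])] = True
    keep[0] = False
    out = mask & keep[labels]
    return BinaryVolume(out, candidates.spacing)


def extract_macrovessels(
    volume: GrayVolume,
    otsu_mask: BinaryVolume,
    params: MacrovesselParams | None = None,
) -> tuple[BinaryVolume, dict]:
    """Extract vessels with diameter > 30 um following the case-specific
    workflow; returns the (solid) macrovessel mask and a provenance dict.
    """
    params = params or MacrovesselParams()
    spacing = otsu_mask.spacing
    case = params.case
    if case in ("auto", None):
        case = classify_case(volume, otsu_mask, params)
    elif case in ("1", "filled", FILLED_INTERIOR):
        case = FILLED_INTERIOR
    elif case in ("2", "hollow", HOLLOW_INTERIOR):
        case = HOLLOW_INTERIOR

    info: dict = {"case": case}
    empty = BinaryVolume(np.zeros_like(otsu_mask.mask), spacing)
    if case == NONE:
        info["reason"] = "no macrovessel regime detected; empty mask"
        return empty, info

    t_global = otsu_threshold(volume)
    info["t_global"] = t_global
    cube = params.size_opening_vox(spacing)
    info["size_opening_vox"] = cube

    if case == FILLED_INTERIOR:
        t_low = params.t_low_override
        t_high = params.t_high_override
        if t_low is None:
            t_low = _sub_otsu(volume, mask_below=True, t_global=t_global)
        if t_high is None:
            t_high = _sub_otsu(volume, mask_below=False, t_global=t_global)
        info.update(t_low=float(t_low), t_high=float(t_high))
        band = binarize(volume, t_low, t_high).mask
        core = _morph.open_cube(_morph.close_cube(band, params.closing_size),
                                params.opening_size)
        cand = _morph.dilate_cube(core, params.dilation_size_case1) & ~otsu_mask.mask
        dil = params.dilation_size_case1
    else:
        t_raised = params.t_high_override
        if t_raised is None:
            t_raised = _sub_otsu(volume, mask_below=False, t_global=t_global)
        info.update(t_raised=float(t_raised))
        band = binarize(volume, t_raised, np.inf).mask
        core = _morph.open_cube(_morph.close_cube(band, params.closing_size),
                                params.opening_size)
        cand = _morph.dilate_cube(core, params.dilation_size_case2) & otsu_mask.mask
        dil = params.dilation_size_case2

    retained = size_filter_components(BinaryVolume(cand, spacing), cube)
    if not retained.mask.any():
        info["reason"] = "no component passed the size filter; empty mask"
        return empty, info

    # final geometry: sealed fill of the pre-dilation core, keeping only the
    # solid components near a retained detection
    solid = _fill_sealed(core)
    labels, nlab = _morph.label_foreground(solid)
    near = _morph.dilate_ball(retained.mask, dil + 1)
    keep = np.zeros(nlab + 1, dtype=bool)
    keep[np.unique(labels[near & solid])] = True
    keep[0] = False
    final = keep[labels] & solid
    info["macro_voxels"] = int(final.sum())
    return BinaryVolume(final, spacing), info


def build_measurement_window(
    domain: BinaryVolume, macro: BinaryVolume, radius_um: float = 15.0
) -> MeasurementWindow:
    """W = domain minus the macrovessels dilated by a ball of ``radius_um``."""
    if radius_um < 0:
        raise ValueError("radius must be >= 0")
    if domain.mask.shape != macro.mask.shape:
        raise ValueError("domain and macrovessel mask must share the grid")
    r_vox = radius_um / domain.spacing
    excl = _morph.dilate_ball(macro.mask, r_vox)
    w = domain.mask & ~excl
    return MeasurementWindow(BinaryVolume(w, domain.spacing))
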