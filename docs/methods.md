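# Methods

## Setting and model

The package analyzes 3D synchrotron-microtomography volumes of hepatic
vascular corrosion casts at isotropic sub-micron voxel spacing (natively
325 nm).  In a corrosion cast the resin-filled vessel lumen is the imaged
object, so the vasculature is the bright foreground.  The target structure
is the sinusoidal bed X — vessels with diameter below 30 µm — treated as a
realization of a stationary random closed set inside a measurement window
W of capillary liver tissue.  Stationarity justifies averaging statistics
(volume fraction, diameters, pillar counts) over the full window.

All modules use one grid convention: arrays indexed `[x, y, z]` with `z`
the TIFF slice axis, 0-based coordinates, half-open bounding boxes,
isotropic spacing in µm.  Foreground connectivity is 26-adjacency,
background 6-adjacency (a complementary pair), everywhere.

## Segmentation

A 7×7×7 median filter (reflective boundaries) precedes global Otsu
thresholding.  Otsu's threshold is computed on a 256-bin histogram spanning
the observed intensity range — stable for both 8- and 16-bit data — with
ties broken towards the lowest maximizing bin; the returned value is the
lower edge of the upper class, and binarization uses the band rule
`t_low <= I < t_high` so that an upper threshold can exclude the brightest
phase when needed.  Postprocessing fills every 6-connected background
component that does not touch the volume boundary (a cavity whose only
outlet leaves the image cannot be proven enclosed) and removes small noise
by opening with a 3-voxel cube.

Structuring elements with even edge length (4, 6, 20, 92) are anchored at
`floor(size/2)`; dilations scan the reflected window so that opening and
closing remain idempotent, anti-/extensive filters.  Outside the volume is
background.

## Macrovessel extraction and the window W

Large lumina image in two regimes: the interior at an intermediate bright
level that global Otsu assigns (mostly) to foreground (case 1), or
background-like with a bright rim (case 2).  The regime is classified
automatically: case 2 if the raw binarization contains a background cavity
larger than (30 µm)³ that leaves the image through at most two faces (a
tube crossing the scan does exactly that); case 1 if a foreground
component, after filling such cavities, admits the size-filter cube.

Rather than asking for manually tuned thresholds, the extraction uses
reproducible defaults: recursive Otsu on the sub-histogram below the
global threshold gives the case-1 band's lower bound, recursive Otsu above
the global threshold gives its upper bound (and the case-2 raised
threshold).  Both are config-overridable.

Detection then follows the case-specific sequence: band (case 1) or raised
(case 2) threshold; closing with a 4-cube; opening with a 6-cube; dilation
with a 6-cube (case 1) or 20-cube (case 2); subtraction of the Otsu
binarization (case 1) or intersection with it (case 2); 26-connected
labeling; and a size filter with a 92-voxel cube (29.9 µm at native
spacing).  Two refinements make this workflow meet its own goal:

* **Size filter on filled components.**  A hollow macrovessel at the
  raised threshold is a thin rim into which no 92-cube fits; retention
  therefore tests erosion of the component after filling its interior
  cavities (again sealing cavities that leave the image through ≤ 2
  faces).  Components are always kept or dropped whole.  Note the
  geometry: a 92-cube fits inside a tube only if its diameter exceeds
  92·√2 voxels ≈ 42 µm, so the filter in practice removes everything up to
  ~42 µm, not 30 µm.
* **Mask geometry from the pre-dilation core.**  The dilation steps exist
  to consolidate detections; keeping them in the output would add a 2–7 µm
  halo around every vessel (and, in case 1, subtracting the Otsu
  binarization would carve the interior back out of the very vessel being
  extracted).  The returned mask is therefore the sealed fill of the
  smoothed, pre-dilation core, restricted to components near a retained
  detection: solid lumina that track the true vessel to within the
  partial-volume blur (~1–2 voxels).

W is the scan domain minus the macrovessels dilated by a digital ball of
radius 15 µm (vessel walls carry no sinusoids), with `V(W)` in µm³.

## Minkowski functionals

Volume is voxel counting.  The Euler characteristic χ and the integral of
mean curvature M are estimated in a single pass from the histogram of
2×2×2 voxel configurations; each functional is a dot product of that
histogram with a 256-entry weight table built at import time:

* **χ (26, 6):** the continuous model of 26-adjacency is the polyhedral
  set ∪ conv(foreground vertices) over lattice cells.  Its χ decomposes
  over the open strata of the cubical grid with purely combinatorial local
  terms `t(g, S) = [S ≠ ∅] − Σ_{g'<g} t(g', S∩g')` (compactly supported
  Euler characteristic of `conv(S) ∩ relint(g)`).  The result agrees with
  the standard (26, 6) digital Euler number on every configuration
  (verified exhaustively against an independent implementation) and is
  exact on digital balls (1), tori (0) and hollow shells (2).
* **M via discrete Crofton:** for polyconvex bodies M = 2π·b, where the
  mean width b averages over directions the integral over positions of the
  χ of planar sections.  This is discretized over the 13 lattice
  directions (3 axes, 6 face diagonals, 4 space diagonals).  Each
  direction's stack of lattice planes is a 2D lattice whose section
  complexes — squares for axis and face-diagonal normals, triangles for
  space-diagonal normals — fit inside 2×2×2 cells, so the entire sum again
  reduces to a configuration LUT.  The three direction-class quadrature
  weights (0.032250, 0.084538, 0.099000) are solved from exactness of the
  spherical mean and of widths along axis and space-diagonal directions,
  with the face-diagonal residual balanced; spherical-Voronoi weights were
  rejected because they bias axis-aligned cylinders by −7%.  Accuracy on
  analytic phantoms: balls r = 10…30 within 2.2% (M) and 2% (V);
  axis-aligned cylinder ~0.1%; isotropically oriented fibers 2–3%.

**Minus-sampling:** with a window W, only 2×2×2 cells lying wholly inside
W contribute — unbiased under stationarity and free of boundary effects.
Without a window the image is padded with background, so an isolated
object is measured exactly.

Volume density is `V_V = V(X∩W)/V(W)`.  The specific length is
`L_V = M(X)/(V(W)·π·(1 − V_V))`; because the
(1 − V_V) factor is unconventional for a length density, the uncorrected
estimate `M/(π·V(W))` is logged and reported alongside.  For thin fibers
M/π approximates total centerline length; rounded fiber ends add 2r each
and boundary cut faces πr/2 each.  In a Boolean fiber system at V_V ≈ 0.15
grain overlap shortens the union's centerline relative to the sum of
segment lengths by ~10–15% — a property of the structure, not of the
estimator, which is validated on disjoint-fiber phantoms to ~1%.

## Local thickness and granulometry

Local thickness assigns to each foreground voxel the diameter of the
largest digital ball contained in X covering it, computed by sphere
covering on the exact Euclidean distance transform with radius resolution
0.5 voxel (descending radii; a voxel within distance r of a centre whose
EDT exceeds r is covered by a ball of diameter 2r).  Agreement with an
exhaustive inscribed-ball oracle is within one voxel of diameter — the
inherent discretization of digital balls.

The granulometry curve is the volume-weighted histogram of these diameters
over sinusoid voxels in W, with 1-voxel diameter bins.  Because
discretization places spurious 1–2 voxel balls along vessel boundaries,
the curve is cut before its first local minimum (smallest i ≥ 1 with
`w[i] <= w[i−1]` and `w[i] < w[i+1]` — deterministic on plateaus; no
minimum ⇒ no trimming, logged), renormalized, and smoothed with a cubic
smoothing spline whose parameter defaults to a two-fold cross-validation
choice over a geometric grid (config-overridable); negative spline values
are clipped and the curve renormalized.

## Pillar detection

An intussusceptive pillar appears in the cast as a tunnel of 1–5 µm inner
diameter through the foreground.  Candidates are 26-connected components
of `close(X, ball of diameter 5 µm) \ X` whose maximal inscribed-ball
diameter lies in [1, 5] µm.  Classification is topological: the sleeve
`X ∩ dilate(marker, 1 voxel)` of a through-tunnel is an open tube
(χ = 0, torus-equivalent) and counts as a pillar; a blind pocket's sleeve
is cap-like (χ = 1) and is rejected.  The sleeve construction is isolated
behind one operation so an alternative marker topology can be swapped in.

Markers near the image boundary (within 2 voxels — the ball closing,
computed with background padding, cannot seal holes in the outermost
layers) are unobservable and excluded.  Intensities are estimated by
minus-sampling: W is eroded by a cube of half-edge `d_max + 1 voxel` and
trimmed by the same margin at the volume faces; only pillars anchored
(lexicographically smallest voxel — a tie-free rule) in the reduced window
count.  This makes counts translation- and padding-invariant.  The three
normalizations `N_V = N/V(W)`, `N_V2 = N/V(X)`, `N_L = N/(L_V·V(W))` use
V(W), V(X) and L_V measured on the reduced window.

## Synthetic phantoms

The generator reproduces the statistical structure the analysis assumes,
with every output a pure function of the spec (including the seed):

* **Sinusoids:** a Boolean model of dilated line segments — Poisson count,
  uniform positions in a domain extended by half the segment length plus
  the maximal radius (so the restriction to the image is stationary;
  octant V_V varies by < 10% CV on large phantoms), orientations uniform
  on the sphere, diameters from a lognormal clipped to 5–9 µm (log-mean
  ln 6.8, log-sd 0.12), segment length 30 µm (the inter-branch scale).
  The intensity for a requested volume fraction comes from the Boolean
  formula `V_V = 1 − exp(−λ·E[v])` with the spherocylinder grain volume;
  requested fractions are realized within ±0.02.  Fractions above 0.5 are
  rejected as non-cast-like.
* **Macrovessels:** straight tubes > 30 µm crossing the volume, with a
  4 µm sinusoid-free wall clearance.  Case-1 interiors render at an
  intermediate level (140) between background (40) and cast (200); case-2
  interiors render background-like with a bright rim (240) of 8 µm — the
  6-cube opening in the extraction workflow destroys any thresholded rim
  thinner than ~6 voxels, so a thinner default would make hollow
  macrovessels structurally invisible to the workflow being tested.
* **Pillars and pockets:** transverse tunnels through a host vessel
  (required local thickness > tunnel diameter + 2 voxels), carved along
  the shortest foreground chord; pockets stop at the host centre.
  `pillar_study_phantom` arranges 20 µm host tubes with 10 tunnels
  (2–4 µm) and 5 pockets, pairwise > 10 µm apart, at native spacing.
* **Rendering:** per-phase mean intensities, Gaussian PSF blur (σ = 0.7
  voxel), additive Gaussian noise (σ = 8), clipped to 8 bit.  At these
  defaults direct Otsu thresholding recovers the cast at Dice ≥ 0.98.

What the phantoms do **not** emulate: the connected network topology of
real sinusoids (fibers are independent segments), phase-contrast fringes,
reconstruction artifacts, beam hardening, extravasation artifacts, or
intensity inhomogeneity.  Passing tests therefore demonstrate correctness
of the measurement chain under the stated statistical assumptions, not
robustness to all real-scan pathology.

## Problem sizes and numerical choices

Tests validate at the scales where each effect lives: topology and
Minkowski accuracy on ≤ 512³ analytic shapes; segmentation and density
recovery on 288×288×160 phantoms at the native 325 nm spacing (the
voxel-denominated 7³ median there has the same physical aggressiveness as
in a real scan; at 2× coarser spacing it alone biases V_V by −0.02…−0.04);
pillar recovery on 256³ at native spacing.  Macrovessel unit tests run at
0.65 µm spacing with the size-filter cube converted via its physical
29.9 µm edge.  Degenerate inputs raise: constant images (Otsu), empty
windows, saturated windows (V_V = 1), inverted thresholds, anisotropic
spacing, too-thin pillar hosts.

## Known limitations

* The (1 − V_V) factor in L_V is reproduced verbatim although its intent
  is unverifiable; both corrected and uncorrected values are reported.
* The size-92 opening removes components up to ~42 µm diameter (cube
  diagonal geometry), slightly more aggressive than the nominal 30 µm.
* Pillar detection on dense fiber systems can mark inter-fiber gaps of
  1–5 µm; in real sinusoidal networks such gaps are frequent, so pillar
  intensities should be read against the marker definition above, not as a
  claim of perfect specificity outside well-separated hosts.
* M on strongly anisotropic structures oriented along face diagonals
  carries a ~8% direction-quadrature residual; isotropic and axis-aligned
  structures are unbiased.
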