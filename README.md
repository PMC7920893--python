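# sinumorph

3D morphometry of the hepatic sinusoidal microvasculature in synchrotron-
microtomography (SRμCT) scans of vascular corrosion casts.

In a corrosion cast the resin-filled vessel lumen is the imaged object, so
the whole vascular bed appears as bright foreground at sub-micron voxel
spacing (natively 325 nm).  `sinumorph` implements the full measurement
chain for such volumes:

1. **Segmentation** — 7×7×7 median filter, global Otsu threshold, filling
   of enclosed holes, small-noise opening.
2. **Macrovessel exclusion** — vessels with diameter > 30 μm are extracted
   by a two-regime workflow (interior imaged foreground-like or
   background-like), and the measurement window *W* is the scan domain
   minus the macrovessels dilated by a 15 μm ball: capillary liver tissue
   only.
3. **Morphometry** of the sinusoidal system *X* (treated as a stationary
   random closed set in *W*):
   * volume density `V_V = V(X ∩ W) / V(W)`,
   * specific microvascular length `L_V = M(X) / (V(W) · π · (1 − V_V))`,
     where *M* is the integral of mean curvature estimated from 2×2×2
     voxel-configuration counts via a 13-direction discrete Crofton
     formula (for thin fibers, `M ≈ π ×` total centerline length),
   * the granulometry curve: the volume-weighted distribution of local
     thickness (largest inscribed-ball diameter), trimmed before its first
     minimum and smoothed with a cubic spline.
4. **Intussusceptive pillar detection** — pillars manifest as tunnels of
   1–5 μm inner diameter through the cast.  Candidate holes are closing
   residues in the diameter band; a candidate counts as a pillar iff its
   foreground sleeve has Euler characteristic 0 (torus-equivalent, a
   through-tunnel) rather than 1 (a blind pocket).  Counts use
   minus-sampling on a reduced window and are reported as `N`,
   `N_V = N/V(W)`, `N_V2 = N/V(X)`, `N_L = N/(L_V · V(W))`.

A seeded synthetic phantom generator (Boolean fiber systems with 5–9 μm
diameters, optional macrovessels in both imaging regimes, carved tunnels
and pockets, PSF blur and noise) provides full ground truth and replaces
beamline scans in every test.

## Worked example

```python
import sinumorph as sm

# a hollow-macrovessel phantom at native scan spacing
spec = sm.PhantomSpec(
    seed=5, dims=(288, 288, 160), spacing=0.325,
    macrovessels=(sm.MacroTubeSpec(axis=2, center_um=(46.8, 46.8),
                                   diameter_um=60.0,
                                   interior_mode="hollow_case2"),),
)
truth, gray = sm.generate_phantom(spec)

report, masks = sm.analyze_volume(gray)
print(f"V_V  = {report.V_V:.4f}")
print(f"L_V  = {report.L_V:.3e} um/um^3")
print(f"mode = {report.curve.mode_um():.2f} um")
print(f"case = {report.provenance['macro']['case']}")
```

prints (seed 5):

```
V_V  = 0.1502
L_V  = 4.860e-03 um/um^3
mode = 6.17 um
case = hollow_interior
```

The measured volume density sits within 0.01 of the phantom's ground-truth
fraction inside *W* (0.1587), the macrovessel mask overlaps the true 60 μm
tube at Dice ≈ 0.99, and the granulometry mode falls inside the simulated
5–9 μm diameter band.  `L_V` includes the
(1 − V_V) factor of its definition; the conventional uncorrected estimate `M/(π V(W))` is
reported alongside in `report.L_V_uncorrected`.

The same chain is available from the shell:

```sh
sinumorph phantom scan.tif --seed 5 --dims 192 --spacing-um 0.325
sinumorph run scan.tif --out results/
```

which writes per-volume JSON reports, granulometry and marker CSVs, and a
batch `summary.csv`.

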