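# Methods

This note documents the models behind `microzoo`: what the virtual
beamline simulates, how each planning stage works, the parameters that
matter, and the numerical choices made where the design was open.

## The virtual beamline

**Frames and conventions.** The lab frame is fixed: X along the X-ray
beam, Y vertical, Z along the horizontal spindle (rotation) axis, which
is also the microscope image's horizontal direction (column index grows
toward +Z; the loop tip points toward −Z, i.e. left).  The sample frame
rotates about Z by ω degrees and coincides with the lab frame at ω = 0.
All sample/stage coordinates are micrometres.

**Loop model.** The cryoloop is a thin elliptical annulus (default
10 µm thick, in-plane axis ratio 0.85) in a plane containing the
rotation axis, plus a stem box running to the pin side.  The silhouette
seen along the beam has an exact closed form: a pixel ray at lab (y, z)
intersects the annulus iff |z − c_z| ≤ r_out and |y − c_y| lies between
k·b_min − m and k·b_max + m, where k = |cos(φ_n + ω)| is the
foreshortening of the in-plane axis, b_min/b_max are the in-plane chord
limits at that z and m is the projected half-thickness of the slab.
Rendering is therefore analytic and fast; no rasterised geometry is
splatted.  The silhouette area has period 180° with a sharp unique
minimum where the loop plane contains the beam; the maximum (the face
angle) is slightly flat-topped because the projected ring side-wall
grows just off-face, exactly as for a physical annulus.  Image noise is
additive Gaussian (default σ 2 grey levels on a background of 40 with
loop contrast 130), seeded per capture.

**Crystals and diffraction response.** Crystals are axis-aligned boxes
in the sample frame with a scalar `diffraction_power`: the expected
number of low-resolution spots when the beam footprint is fully inside
the crystal.  A raster grid's expected score is the sum over crystals of
power × (area fraction of the top-hat footprint whose rays, extruded
along the beam at ω, intersect the box).  Because the box's projection
along the beam is a rectangle, this fraction factorises into two 1-D
interval overlaps and is exact.  Realised counts are Poisson draws.
The test suite checks the factorisation against an independent
ray-sampling oracle (0.05–0.1 µm sampling, 2-D slab intersection tests)
over random configurations.

**What the simulator does not model.** No Bragg geometry or Ewald
sphere: synthetic detector frames place Gaussian spots at chosen radii
and derive d-spacings purely from radial position under the flat
detector geometry.  No refraction, ice or LCP texture in the microscope
images; no detector panel gaps.  Consequently, passing tests demonstrate
that the *decision logic* is correct given spot counts and silhouettes
with realistic noise statistics — they do not certify the vision stack
against real microscope imagery or real diffraction patterns.

## Loop centering

Binarisation is Gaussian blur (σ 2 px) of the background-subtracted
frame followed by a threshold — Otsu's value by default, floored at 10
grey levels so residual noise on an object-free frame never reads as
foreground (without the floor, Otsu happily splits pure noise and the
"loop not found" path can never trigger).

The search step inspects ω ∈ {0°, 45°, 90°, 135°}; if no frame shows at
least 20 true pixels the stage translates 1.5 × the image width along
the rotation axis toward the tip side and re-inspects, at most twice.
Tip centering matches the leftmost true pixel's column to the beam
column and the centre of gravity row to the beam row, sequentially at
0°, 45°, 90°; the 0°/90° vertical corrections address orthogonal
sample-frame components, so the noise-free sequence converges exactly
(the whole silhouette, not only the loop head, feeds the centre of
gravity).

The face-angle fit solves N(θ) = A + B·cos(2(θ − φ)) by least squares
on the four counts (the design is orthogonal, so the closed form is the
least-squares solution); the face angle is the minimising angle + 90°,
reduced to [0, 180), with ties broken toward the smaller angle and a
degenerate (B ≈ 0) fit rejected.  Because the true silhouette
modulation is |cos|-shaped rather than a pure second harmonic, the
four-point fit carries an intrinsic bias of up to ≈1.5°, comfortably
inside the ±3° recovery band the tests enforce.

The raster area is the bounding rectangle of true pixels divided by the
beam size (⌈width/beam⌉ grids; grid step = beam size).  A user loop
size caps the horizontal extent measured from the tip, after which the
stage moves half that size to the left so the scanned stretch brackets
the beam position; the vertical range always comes from the found edge.

## Spot finding and scoring

Spot detection follows the radial-background hit-finder family:
per-radial-bin background statistics, SNR thresholding (default 6),
8-connected agglomeration and pixel-count gating (3–100 px).  One
deliberate numerical choice: the *initial* background pass uses the
per-bin median and 1.4826 × MAD rather than mean/σ, because a handful
of bright spot pixels in one bin inflates the plain variance enough
that mean + 6σ exceeds the peaks and the exclusion iteration never
starts; two refinement passes with mean/σ over unflagged pixels follow.
Radial bins are 1 px wide; all constants are keyword parameters.  The
implementation is verified against a pure-Python O(N²) oracle of the
same definition.

A frame's score is the number of spots at d ≥ 5 Å.  The 5 Å cutoff is
the crystal-presence signal of choice because ice rings (≈3.7 Å) and
lipid-phase rings (≈4.5 Å) fall below it and cannot masquerade as
crystal diffraction.  Heat maps store integer scores with a stage-
coordinate map and round-trip losslessly through a tab-separated
summary file (1-based grid indices, coordinates at 0.1 µm precision).
Grid selection for small-wedge work is greedy by descending score
inside the good-spot window (default 15–100; above 100 the grid is
neglected as multi-lattice/salt) with a minimum mutual distance.

## Scheme planning

Segmentation repeatedly takes the best unassigned grid above threshold
and flood-fills its 8-connected above-threshold neighbourhood — chosen
over 4-connectivity because "surrounding" grids include diagonals; the
result provably equals connected-component labelling and is emitted in
descending peak-score order.  One shared threshold (default: the
good-spot window minimum) serves both segmentation and selection.

Region edges along the rotation axis are the extreme-column members
(ties: higher score, then lower row).  The heat map fixes an edge only
to its grid column, so before the vertical scan each edge is localised
by a fine-beam 1-D scan along the axis (2 µm steps over ± one grid
step); the vertical scan then runs at the wedge-end angle — face ±
total/2, clamped to ±90° past 180° total — and the best-scoring
position (ties: lower index) becomes the 3-D vector endpoint.  On
noise-free synthetics this recovers endpoints within one grid step per
axis; an all-below-threshold scan raises an edge-not-found condition
that callers treat as "crystal lost", skip and log.

Categorisation is a single pass over regions (overlap sets are not
re-evaluated after removals): no axis overlap → helical full candidate;
overlapped but vertically clear of *every* overlapping neighbour by ≥
multiplier × vertical beam size (default 3, gap measured between
cell-edge intervals, zero when they overlap) → partial helical
candidate; otherwise clustered.  Size gates then demote candidates
shorter than the minimum helical size (default 20 µm) to small wedges
and longer than the maximum (default 100 µm) to clustered — applied to
full candidates as well as partial ones, since an isolated 5 µm crystal
cannot support helical collection either.  Clustered regions are
collected as small wedges on the stride-2 sub-lattice anchored at the
best grid, so no two collection points are 8-adjacent.  The assignment
is a total function of the region set, independent of input order.

The serial-rotation planner derives frames per line =
⌈loop length / scan step⌉, total oscillation per line = frames ×
rotation width per frame, and tiles the vertical extent with scan
lines.

## Dose model

A transparent thin-crystal absorption model replaces any external dose
engine: dose [Gy] = fluence × E_photon × (µ_en/ρ), with fluence = flux
× transmission × time / beam area.  Defaults: µ_en/ρ = 0.25 m²/kg (an
aqueous protein crystal near 12.4 keV, interpolated from tabulated
water values), density 1200 kg/m³ (metadata only — energy per unit mass
needs no density in the thin-sample limit), top-hat beam.
Photoelectron escape from micron-scale irradiated volumes is explicitly
not modelled; an empirical damage-propagation length can instead smear
any computed profile with a Gaussian of that σ (support extended by 6σ
so the integral is conserved; σ = 0 is the identity).

Translating schemes accumulate per-frame top-hat footprints along the
travel axis on a 0.1 µm sampling (difference-array cumulative sum); the
interior plateau equals the per-frame dose × ⌈beam width / per-frame
translation⌉, and the peak is cross-checked against a direct per-frame
accumulation oracle to < 1 %.  Because the model is linear in time,
transmission and flux, inverting it for a budget is exact: the
suggested plan re-estimates to the budget to machine precision (a
minimum-exposure floor, when set, raises an error naming the binding
constraint).  The default budget is 10 MGy per wedge.

## Orchestration

Plan rows follow the standard parameter sheet (mode, puck/pin range,
total oscillation and width per wedge, beam size, dose budget, camera
distance, loop size, good-spot window, per-loop collection cap) with
the sheet's example column as defaults; CSV headers or JSON keys are
accepted, and validation errors name the row and field.  Raster timing
is step × frame rate (10 µm at 50 Hz → 500 µm s⁻¹), acquisition is
serpentine, and the 2 ms trigger-jitter bound is reported in the log as
a ≤ 1 µm positional error at default speed — no real-time behaviour is
modelled.  Collection against the virtual beamline emits per-frame
metadata only; full frame rendering exists separately for spot-finder
tests.  A pin whose loop is not found yields a `no_loop` record and the
run continues; a crystal lost at the vertical-scan stage is recorded
with `edge_not_found` and skipped.  The stage position of the last
found loop seeds the next pin of the same puck.  Reports are JSON and
round-trip to identical records.

## Study conditions for tests

The synthetic study conditions are fixed once: microscope 288 × 384 px
at 4 µm/px (a ≈1.5 × 1.2 mm field), loops with outer radii 220–300 µm,
raster beam 10 × 15 µm, crystal diffraction power 50 expected spots,
Poisson spot noise, Gaussian image noise σ 2.  Recovery suites use 50
random noise-free samples (tip within one grid step, face angle within
±3°, helical endpoints within one grid step per axis); oracle suites
use 200 random heat maps, 20 detector frames and 50 dose
configurations.  These sizes keep the full test run within a few
seconds while exercising every decision path.

## Known limitations

* The vision stack is validated only against the analytic silhouette
  model; real loop imagery (ice, fibres, off-plane bends) will need a
  retuned binarisation front end.
* Quasi-3D centering at ±20° recovers the depth coordinate only
  approximately by construction; the exact recovery guarantees hold for
  the ±90° full-helical geometry.
* The dose model ignores elemental composition, attenuation through
  crystal depth and photoelectron escape; absolute doses are
  order-of-magnitude realistic (≈5 MGy s⁻¹ at 10¹⁰ ph µm⁻² s⁻¹,
  12.4 keV) but not a replacement for a full dose simulation.
* Categorisation does not re-examine overlaps after removing clustered
  crystals, and touching crystals with indistinguishable heat-map
  signatures segment as one region.
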