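# microzoo

Hardware-free automation core for **protein microcrystallography data
collection**: the decision-making layer of a goniometer-based beamline —
cryoloop centering from on-axis microscope images, raster-scan spot
scoring, crystal segmentation, per-crystal collection-scheme selection
and dose-budgeted exposure planning — runnable entirely against a
simulated ("virtual") beamline.

It is aimed at people who build or study beamline automation: every
stage that normally needs a goniometer, a microscope and an area
detector is served here by a synthetic sample model with known ground
truth, so the planning logic can be developed, regression-tested and
benchmarked on a desk.

## What it computes

For each mounted sample the pipeline runs the standard unattended
sequence:

1. **Loop centering** — background-subtract, blur and binarize the
   microscope frame; if nothing is visible, translate the horizontal
   axis by 1.5 × the image width (at most twice) and look again.  The
   loop tip (leftmost silhouette pixel) is matched to the beam
   horizontally and the silhouette centre of gravity to the beam height,
   at ω = 0°, 45°, 90°.
2. **Face angle** — the silhouette pixel count N(θ) at θ = 0°, 45°, 90°,
   135° is fitted to N = A + B·cos(2(θ − φ)); the loop face is
   perpendicular to the beam 90° away from the fitted minimising angle.
3. **Raster scan** — the silhouette's circumscribing rectangle is divided
   by the beam size (n = ⌈length / beam⌉ grids per axis; grid step =
   beam size; scan speed = step × frame rate, e.g. 10 µm × 50 Hz =
   500 µm s⁻¹).  Each grid's diffraction frame is scored by the number
   of **low-resolution spots up to 5 Å** — a cutoff that keeps ice-ring
   (≈3.7 Å) and lipid-ring (≈4.5 Å) artifacts out of the count.
4. **Crystal segmentation and scheme selection** — 8-connected grids
   above threshold form one crystal.  Crystals are assigned to exactly
   one of: *helical full rotation* (no overlap with another crystal
   along the rotation axis), *partial helical* (overlapped, but
   vertically clear of every overlapping neighbour by ≥ 3 vertical beam
   widths), *small wedge* (shorter along the axis than the minimum
   helical size) or *clustered* (too close vertically, or longer than
   the maximum helical size; collected as stride-2 small wedges).
   Helical vectors come from fine-beam edge refinement plus vertical
   diffraction scans at the wedge-end angles: for a 40° wedge the edges
   are scanned at −20°/+20° from the face angle, clamping at ±90° when
   the total oscillation exceeds 180°.
5. **Dose budgeting** — a thin-crystal absorption model,
   dose = fluence × E_photon × (µ_en/ρ), linear in flux, transmission
   and time, inverted exactly so each wedge's peak dose meets the user
   budget (default 10 MGy).  Translating schemes (helical, serial
   rotation) accumulate overlapping top-hat footprints along the travel
   axis.

## Worked example

Run the mixed scheme on the built-in nine-crystal scenario (one isolated
crystal, two vertically separated overlappers, two tiny crystals, a
tight cluster of three and one oversized crystal):

```python
from microzoo import orchestrator as oz, virtual_beamline as vb

sample = vb.scenario_fig4()
result = oz.run_sample(oz.ZooParams(mode="mixed"), sample, seed=1)
print(f"face angle: {result.centering.face_angle:.1f} deg")
print(f"heat map: {result.heatmap.n_v} x {result.heatmap.n_h} grids, "
      f"max score {int(result.heatmap.scores.max())}")
for asg in result.assignments:
    print(f"  crystal {asg.region.size_along_axis:5.0f} um along axis -> "
          f"{asg.category.value} ({asg.wedge_total_osc:.0f} deg wedge)")
```

prints

```
face angle: 180.0 deg
heat map: 47 x 60 grids, max score 71
  crystal    60 um along axis -> clustered (5 deg wedge)
  crystal    60 um along axis -> clustered (5 deg wedge)
  crystal   130 um along axis -> clustered (5 deg wedge)
  crystal    60 um along axis -> helical_full (60 deg wedge)
  crystal    80 um along axis -> partial_helical (40 deg wedge)
  crystal    80 um along axis -> partial_helical (40 deg wedge)
  crystal    60 um along axis -> clustered (5 deg wedge)
  crystal    10 um along axis -> small_wedge (5 deg wedge)
  crystal    10 um along axis -> small_wedge (5 deg wedge)
```

The ground-truth face angle of this sample is 0° (≡ 180°); the 130 µm
crystal exceeds the 100 µm helical maximum, the 10 µm crystals fall
below the 20 µm minimum, and the three crystals stacked closer than
three beam heights are collected as clustered small wedges — one
assignment per crystal, as designed.  The resulting helical full wedge
is 60° centred on the face angle with an exposure meeting the 10 MGy
budget exactly (`18.65 ms/frame, 10.0 MGy` for the default beam).

The same functionality is exposed on the command line:

```bash
microzoo dose --scheme helical --budget 8 --n-frames 400 --vector-length 150
microzoo run --plan plan.csv --sample sample.json --out report.json --seed 7
```

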