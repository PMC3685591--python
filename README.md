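# thermocover

Automatic quality control of fractional-laser skin treatments from
infrared thermograms.

During an ablative fractional-laser procedure the operator applies the
laser head repeatedly over the treatment field; every application leaves a
square footprint of skin elevated by about 2.5 °C over the ~33 °C
baseline, visible to a thermal camera for many minutes. An ideal
procedure tiles the field exactly. In practice the operator leaves gaps
(harmless, but the area must be re-treated) or overlaps neighbouring
applications (a double irradiation dose, which can damage tissue).

`thermocover` measures both mistakes fully automatically from a single
temperature matrix. Writing `L_R` for the treated-region mask, `L_i` for
the footprint of pulse *i* and `L_Z` for the mask of pixels covered by two
or more footprints, it reports

- **δ_o** — undertreatment: the percentage of `L_R` pixels covered by no
  footprint, `δ_o = |{p ∈ L_R : count(p) = 0}| / |L_R| · 100%`;
- **δ_z** — double dose: `δ_z = |L_Z ∩ L_R| / |L_R| · 100%`,

where `count(p)` is the per-pixel coverage count (so the definitions stay
exact even for triple overlaps).

The pipeline has two stages:

1. **Treated-region extraction** — nearest-neighbour upsampling (no new
   temperature values), 3×3 median filtering, grayscale morphology that
   globalizes the lattice of warm footprints into one field, binarization
   at a constant threshold `p_r` (°C above the pre-treatment skin level),
   connected-component labeling, largest cluster kept.
2. **Pulse geometry and coverage** — Canny edges of the region, Radon
   transform over [0°, 90°), the sharpest projection peak gives the common
   grid rotation α\* (mod 90°, since a square grid is 90°-symmetric);
   marker-controlled watershed on the detrended temperature topography
   separates individual footprints; each is approximated by a rotated
   square of a shared robustly-estimated side; per-pixel coverage counts
   yield δ_o and δ_z.

No clinical thermograms are distributed, so the package includes a
first-class synthetic-thermogram generator (`thermocover.synthetic`) with
pixel-exact ground truth: square plateaus with a radial falloff and soft
penumbra edges, Gaussian sensor noise, and the first-order step response
T(t) = T₀ + ΔT·(1 − e^(−t/τ)) for frame sequences.

## Worked example

```python
import thermocover as tc

scene = tc.grid_scene(
    n_rows=3, n_cols=4, side_px=34, gap_px=2, angle_deg=8.0,
    shape=(240, 320), dropout=((1, 1), (1, 2)),
    shifts={(0, 1): (6.0, 0.0)}, noise_sd_c=0.05, seed=1,
)
image, truth = tc.generate_scene(scene)
report = tc.analyze_image(image, tc.RunConfig.for_pulse_side(34, 2, shape=scene.shape))
```

Running `python examples/analyze_thermogram.py` (the same scene) prints

```
detected pulses : 10 (true 10)
grid angle      : 8.0 deg (true 8.0)
delta_o (no dose): 24.47 %  (true 25.37 %)
delta_z (double) : 0.67 %  (true 0.88 %)
```

Two of twelve grid positions were skipped and one pulse was shifted onto
its neighbour; the pipeline recovers the pulse count, the grid angle, and
both coverage errors to within about one percentage point of the
generator's pixel-counted truth. The other scripts in `examples/`
demonstrate scene simulation and I/O, the threshold-sensitivity sweep,
and the first-order timing model with the valid analysis window
(10 s – 180 s after the last pulse).

A thin CLI wraps the same library for batch use:

```sh
thermocover simulate --scene scene.yaml --out frames/
thermocover analyze frames/*.csv --config cfg.yaml --out results/
thermocover sweep frames/frame.csv --pr-range 1.3:2.2:0.1 --out sweep.csv
```

`analyze` writes one JSON coverage report per image (percentages, pixel
ledger, run-length-encoded masks, full parameter echo) plus a batch
summary with the mean ± SD of both errors.

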