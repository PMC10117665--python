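# droptrap

Hydrodynamic trapping and mobility scoring of zebrafish larvae in
vibrated-droplet recirculating flows.

A larva confined in a millimetre-scale droplet on a vibrating substrate
sits in a steady recirculating flow. In the four-cell pattern the flow near
the fish is a planar straining field (u, v) = (ε̇x, −ε̇y) with a stagnation
point at the centre: outflow along the "source" axis, inflow along the
upstream "sink-feeding" axis. Treating the fish as a slender rod (length L,
radius a) in Stokes flow, the viscous torque about the stagnation point is

    T(θ) = −(8πμε̇/c) (L³/3) sin 2θ,    c = 2 ln(L/a) − 1,

with exactly two equilibria per 180°: the upstream heading θ = 90°
(unstable) and the flow-aligned heading θ = 180° (stable). A passive —
anesthetized or motor-impaired — fish is therefore swept into alignment
with the inflow, while an actively swimming fish must fight to hold the
upstream heading. The body angle thus becomes a mobility readout. The
package closes the loop with an active-rod model
θ̇ = −ε̇ sin 2θ + A sin(90° − θ) + noise, whose self-righting activity A has
a sharp bifurcation at A_crit = 2ε̇, plus the imaging side: synthetic
tracer/fish video rendering, centroid detection and linking, track-based
velocimetry, recirculation-pattern classification, circular statistics,
mobility classification, and the chance-alignment probability
p = (w/360)ⁿ·(360/w) (4.8×10⁻⁵ for five fish in one 30° window).

Intended for quantitative behaviour people who want a tested, fully
synthetic sandbox of the droplet-trap assay: every input is generated with
known ground truth, so each stage is verifiable end to end.

## Layout

- `src/droptrap/` — the library: `flow`, `slender_body`, `swimmer`,
  `tracking`, `mobility`, `synth`, `io`, `cli`.
- `analysis/01…05_*.py` — numbered drivers that run the study and write
  small tables under `results/`.
- `docs/methods.md` — models, parameter choices, numerics, limitations.

## Worked example

Simulate a default cohort (five fish each: untreated type_i, anesthetized
type_ii, recovering type_iii) and score it:

```sh
droptrap simulate --seed 1 --out runs/cohort
droptrap analyze runs/cohort --out runs/analysis
```

or equivalently `python analysis/05_mobility_study.py`, which prints:

```
    fish_id     type  ...  circ_mean_deg  resultant_length  source_deviation_deg      class
  type_i_00   type_i  ...          89.95             0.992                  0.05     intact
  ...
 type_ii_00  type_ii  ...           0.54             0.987                 89.46  disrupted
  ...
type_iii_00 type_iii  ...          75.59             0.821                 14.41 recovering
  ...

intact cohort alignment p-value (30-degree window): 4.823e-05
```

Reading it: each fish's heading time series is reduced to a circular mean
and resultant length R. The untreated fish hold the upstream heading
(mean ≈ 90°, R ≈ 0.99 — the tight 80–100° band), the anesthetized fish are
trapped on the flow axis (mean ≈ 0°/180°), and the recovering fish scatter
around 90° with visibly lower concentration (R ≈ 0.83). All five intact
means fall inside one 30° window, and the probability of that happening by
chance for independent uniform headings is (30/360)⁵ × 12 ≈ 4.8×10⁻⁵. The
recovery table in the same run shows the folded angle of each type_iii fish
climbing from ≈7° to ≈85° across the 20-minute activity ramp, crossing the
45° midpoint after ≈4–5 minutes.

The other drivers exercise the remaining stages: `01` classifies the
one/two/four-cell flow fields from sampled velocity grids, `02` prints the
drag coefficients and verifies the torque quadrature against the closed
form (agreement to ~1e−15 relative), `03` measures the activity bifurcation
(1.994 vs the analytic 2.0) and the estimator's unbiasedness, and `04`
validates the imaging round trip (100% of rendered tracers recovered within
0.5 px; the reconstructed velocity grid classifies as four-cell).

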