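# projep — 3D projection electrophoresis: design physics, simulation, and volumetric immunoblot analysis

Projection electrophoresis is a single-cell immunoblotting format in which
hundreds of cells, isolated in a microwell array stippled into the face of
a polyacrylamide gel block, are lysed simultaneously and their proteins
electrophoresed *into* the gel along the z-axis. The xy position of a band
encodes the originating microwell; its z position encodes protein size.
Because every lane shares one gel, the whole array separates in under a
minute, and lane density is limited only by how far protein bands spread
laterally by diffusion before photocapture.

`projep` is a Python package for people designing or analyzing such
devices. It implements:

* **Design physics** (`projep.physics`) — diffusional band broadening
  σ²(t) = σ₀² + 2Dt, Gaussian lane-crosstalk rules, lane density,
  separation resolution
  R_s = Δμ·E·t / (2(σ₁+σ₂)),
  and the Péclet trade-off Pe = t_overlap / t_{R_s=1} between lane
  spacing and separation quality; Stokes–Einstein, Ogston-partition, and
  in-gel hindrance estimators calibrated to the built-in transport table;
  least-squares extraction of mobilities and diffusivities from measured
  migration and band-width series.
* **Lysate-dilution simulation** (`projep.diffusion`) — an axisymmetric
  (r, z) finite-volume diffusion solver with size-exclusion partition
  interfaces, modeling how a cell's protein dilutes out of its microwell
  during lysis and electrophoresis.
* **Synthetic data** (`projep.synth`) — a ground-truth generator for
  volumetric separation stacks (3D Gaussian bands, lognormal abundance,
  microwell occupancy statistics, bleed-through, noise), live-cell
  images, and lysis time-lapse movies.
* **Volumetric lane analysis** (`projep.analysis`) — per-slice
  segmentation, centroid linking through z, background-subtracted
  z-intensity profiles, Gaussian peak fits with R² > 0.7 and SNR > 3
  quality control, lateral band-width fits, gel summaries, live-cell ↔
  band correspondence, and lysis kinetics.
* **Diffusional-PSF deconvolution** (`projep.decon`) — the point-source
  diffusion kernel (σ = √(2Dt)) and "no-neighbors" per-slice
  Richardson–Lucy/Wiener restoration with before/after metrics.
* **IO and CLI** (`projep.io`, `projep.cli`) — OME-TIFF stack reading and
  writing, YAML configuration, JSON run manifests, and a `projep`
  command-line tool (`design`, `simulate-dilution`, `synth`, `analyze`,
  `deconvolve`, `report`).

## Worked example

Generate a synthetic two-channel separation gel, analyze it, and compare
against the generator's ground truth:

```python
from projep import synth, analysis

params = synth.SynthesisParams(seed=11)        # 4x4 wells, 200 um pitch
layout = synth.make_layout(params)             # occupancy + band truth
stack = synth.render_stack(layout, params)     # (100, 400, 400, 2) voxels

records, tracks = analysis.analyze_stack(stack)
print(len(tracks), "lanes,", int(records.qc_pass.sum()), "records pass QC")
print(records[["channel", "mu_um", "sigma_z_um"]].groupby("channel").median())
```

prints

```
8 lanes, 16 records pass QC
            mu_um  sigma_z_um
channel
ch_actinin  164.0        23.5
ch_gapdh    346.0        31.5
```

All 8 occupied wells are found (no false lanes in the 8 empty wells), and
the median migration depths and band widths match the generator's truth
(z = 346 µm, σ_z = 31.6 µm for the fast channel; z = 164 µm, σ_z = 23.5 µm
for the slow one) to a fraction of a voxel.

On the design side, the Péclet number at the 200 µm / 60 V/cm design
point:

```python
from projep import physics as ph

ova = ph.ProteinSpecies(name="OVA", mass_kda=42.7, d_gel={7.0: 16.8}, mobility=3.5e-5)
bsa = ph.ProteinSpecies(name="BSA", mass_kda=66.5, d_gel={7.0: 13.1}, mobility=2.7e-5)
cond = ph.SeparationConditions(field_v_per_cm=60.0, ep_time_s=20.0, sigma0_um=16.0)
print(round(ph.peclet(bsa, ova, 200.0, cond), 2))   # 0.93
```

i.e. the time until the fastest-diffusing band bleeds into a neighboring
lane is about equal to the time needed to fully resolve the BSA/OVA pair
— the device operates at Pe ≈ 1.

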