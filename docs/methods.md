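# Methods

This note documents the models implemented in `projep`, their
assumptions, the defaults that matter, and the numerical choices — in the
spirit of a statistics package's model documentation. Every number quoted
here is computed by the test suite or by `scripts/acceptance.py`.

## Design physics

**Band broadening.** A protein band injected with Gaussian width σ₀
spreads purely diffusively: σ²(t) = σ₀² + 2Dt, identically in z and in
the xy plane (the electric field translates bands in z but does not
deform them in this model). Joule heating, stacking at the
solution/gel interface, and field nonuniformity are outside the model.
The injected width σ₀ is not directly measurable; for design
calculations we take σ₀ = half the microwell diameter (16 µm for a 32-µm
well), which treats the well as a top-hat injector of that scale. It is
exposed as `SeparationConditions.sigma0_um` because empirical intercepts
of σ²-vs-t fits disagree between proteins (one of the printed ladder
fits even has a negative intercept, which `fit_band_broadening` flags
as non-physical rather than inverting).

**Lane crosstalk.** With Gaussian bands, the mass a lane loses beyond
half the well pitch on both sides is `2·Φc(pitch/2σ)`: 0.27% at a
6σ pitch and 4.6% at 4σ. These two design rules, together with lane
density (1000/pitch)² per mm², set the pitch/throughput trade-off. The
two-sided convention is the default (`sidedness="two"`); either
convention satisfies the design bounds.

**Separation resolution and Péclet number.**
R_s(t) = Δμ·E·t / (2(σ₁(t)+σ₂(t))) with each σᵢ following the
broadening law. R_s is monotone increasing, so the time to R_s = 1 is
found by bracketed Brent root-finding on (0, 10·t_overlap] with 1 ms
tolerance (a dense-grid brute-force oracle in the test suite agrees to
<1%). The Péclet number Pe = t_overlap / t_{R_s=1} uses the
faster-diffusing species of the pair and the conservative 6σ rule for
t_overlap. With the BSA/OVA pair (D = 13.1 and 16.8 µm²/s in a 7%T gel,
Δμ = 0.8×10⁻⁵ cm²/Vs, σ₀ = 16 µm) at a 200-µm pitch and 60 V/cm the
model gives Pe = 0.93: the device operates right at the
resolution-versus-crosstalk break-even point, and Pe scales linearly
with E.

**Transport coefficients.** Free-solution diffusivities come from
Stokes–Einstein, D = k_BT/(6πη r_H). Size-exclusion partitioning into
the gel uses the Ogston model k = exp(−φ(1 + r_H/a)²), and in-gel
hindered diffusion uses a stretched-exponential sieving factor

    D_gel / D_free = exp(−c(%T) · r_H^p).

The structural parameters (fiber radius a, volume fractions φ, hindrance
coefficients c and exponent p) are not independently measurable here;
they are least-squares calibrated, once, to the package's built-in
transport table of three well-characterized proteins (TurboGFP, BSA,
HER2) at 7%T and 20%T. The calibration reproduces all six partition
coefficients and all six in-gel diffusivities to better than 1%
(asserted at 5% in the tests), with a ≈ 0.65 nm, φ₇ ≈ 0.034,
φ₂₀ ≈ 0.155, p ≈ 0.59. `c(%T)` and `φ(%T)` interpolate linearly through
the origin between the calibrated densities; densities above 20%T
extrapolate with an `ExtrapolationWarning`. The tabulated free-solution
D values are treated as authoritative inputs, not recomputation targets:
they are mutually consistent with Stokes–Einstein radius ratios but
correspond to an unstated temperature/viscosity combination between 4 °C
and 25 °C.

## Lysate-dilution solver

The dilution of a single cell's protein out of its microwell is modeled
as reaction-free diffusion in an axisymmetric (r, z) domain: a
separation-gel slab with the microwell recess on the axis, the cell as a
cylinder of uniform concentration (default 2 µM) filling the well, an
optional thin fluid film on the gel face, and an optional dense lysis-gel
lid. Partitioning at gel/solution interfaces imposes c_gel = k·c_solution
with flux continuity. The solver works in the chemical-potential variable
w = c/k, which is continuous across interfaces:

    k ∂w/∂t = (1/r)∂/∂r(r·Dk·∂w/∂r) + ∂/∂z(Dk·∂w/∂z),

discretized by a conservative finite-volume scheme with harmonic-mean
D·k face conductances and integrated by backward Euler (unconditionally
stable, non-negativity-preserving; default Δt = 25 ms, default grid
spacing 2 µm, 1 µm for the headline run). One sparse LU factorization per
schedule stage serves all of its time steps. Closed-box mass is conserved
to machine precision and the uniform-medium solution matches the
analytic 3D Gaussian kernel to <2% L2 (both asserted). The
lysis → electrophoresis transition follows the instantaneous-injection
simplification: after the lysis stage all partition coefficients become 1
and all regions take the separation-gel diffusivity.

Boundary conditions default to an open (Dirichlet c = 0) frame at the
domain edge; the axis is a symmetry boundary. The default geometry has no
lysis-gel lid: the domain's top edge sits at the gel face, so the well
mouth is an absorbing boundary — the most strongly diluting defensible
configuration. A 20%T lid (`lid_gel_um > 0`) with its tiny partition
coefficient instead traps protein near the well; that variant retains
~19% of the in-well signal after 25 s, close to experimentally observed
values.

**A hard bound worth knowing.** The headline dilution metric — the
z-integrated intensity remaining within the well footprint, as a
fraction of its initial value — has a physical floor under this model:
even if the entire domain were free solution (D = 66.1 µm²/s for
TurboGFP), lateral spreading over 25 s leaves ≈4.2% inside a 16-µm
footprint in a closed domain (point-source closed form: 3.8%); gel
sieving only raises this. With the absorbing-mouth geometry, the solver
converges to ≈4.9% as the grid is refined (5.48 / 5.15 / 4.98% at
h = 2 / 1 / 0.5 µm). Reported simulated dilutions substantially below
this bound imply effectively faster transport (for instance,
25 °C free-solution diffusivities reproduce ≈2.4%) or a different metric
(the mass remaining in the well *cavity* is ≈3.3% here). The acceptance
script reports the faithful value (≈5.1% at h = 1 µm).

## Synthetic-data generator

`stack_synth` emulates the experiments end to end with known ground
truth. Defaults are the measured device statistics: 200 µm pitch, 43%
well occupancy, 10% doublets among occupied wells, 5 µm z-slice spacing
(2 µm xy pixels), E = 40 V/cm for 10 s plus 15 s of post-EP diffusion,
σ₀ = 12.5 µm (half a 25-µm single-cell well). The default two-species
panel has mobilities chosen to place bands at 346 and 164 µm — the
observed depth regime of a fast 37-kDa and a slow 100-kDa target — with
in-gel diffusivities 16.8 and 7.9 µm²/s, giving σ_xy ≈ 32 µm for the
fast channel after 25 s total in-gel time. Per-cell abundance is
lognormal with CV 0.3 (per-cell copy-number distributions are otherwise
unconstrained; this is a stand-in, not an inference). Bands render as
separable anisotropic 3D Gaussians whose voxel sums equal the injected
amounts to <1%.

Noise is additive Gaussian with sd = 2% of the brightest voxel, on top
of a flat baseline of 5% of the brightest voxel (camera offset plus gel
autofluorescence). The baseline matters: without it, clipping negative
noise at zero creates a +0.4·sd pedestal in dark regions that biases
border-background subtraction and the recovered σ_z by several percent.
An optional bleed-through matrix mixes channels (non-negative, unit
diagonal); an optional linear E-field tilt across x emulates spatial
migration nonuniformity. The tilt parameter is the full fractional
spread of E across the gel, so uniformly distributed wells acquire a
migration CV of tilt/√12.

What the generator does **not** emulate: optical PSF and depth-dependent
refractive-index distortion, tile stitching, probe-delivery chemistry,
non-Gaussian band shapes from incomplete solubilization. Pipeline
performance on these stacks therefore demonstrates correctness of the
geometry/statistics handling, not robustness to every real-world
artifact.

## Lane-analysis pipeline

Per z-slice, the summed-channel image is Gaussian-smoothed laterally
(σ = 2 px; bands are tens of pixels wide, so this suppresses voxel noise
without displacing centroids), thresholded (global Otsu, clamped above a
robust median + 5·MAD noise floor — plain Otsu on a sparse-foreground
volume can land inside the noise distribution), cleaned by morphological
open/close, hole filling, border-object and small-object removal
(< 50 µm²), and reduced to intensity-weighted centroids. Centroids are
linked slice-to-slice by Hungarian assignment with a 15 µm gate; tracks
survive dark gaps between bands; co-located tracks (within 40 µm) merge,
because one microwell yields one lane and threshold-edge blob splitting
otherwise spawns satellite fragments. Tracks spanning <10% of the stack
depth are discarded — a real diffusion-limited band spans ≥4σ_z ≈ 80 µm,
an order of magnitude above the 1–3-slice noise blips this QC removes.
(A stricter 30% span cut silently drops genuine single-band lanes and is
not used.)

Profiles sum a 102-µm square ROI per slice after background
subtraction — either the per-z mean of a 5-px frame around the ROI
(outside a thin noise ring), or a single far-field plane estimate.
Constant offsets cancel exactly; isolated-band profile integrals are
conserved to <2%. Peaks are fit by nonlinear least-squares Gaussians
with moment initialization; QC requires R² > 0.7 and SNR > 3 (both
strict), with SNR = amplitude / (2·sd of the noise-ring trace over the
peak's ±2σ z-range). Non-convergence returns a flagged failure, never an
exception. Lateral widths are Gaussian fits (with a free offset
absorbing in-ROI tails) of the summed x- and y-profiles at the peak
slice; σ_xy is their mean.

On default synthetic stacks the pipeline recovers every occupied lane
with zero false lanes, band centers to well under half a z-voxel, and
σ_z to <1% (asserted at 5%); the σ²-vs-t fit through the full pipeline
returns the generator's diffusivity within 10%.

Lysis kinetics: cells are segmented in the first movie frame by adaptive
thresholding of the 3×3-median-filtered image; the maximum and total
background-subtracted intensity in a 100-µm circle are tracked; onset is
the linearly interpolated time the chosen metric (default: maximum)
first drops below half its initial value.

## Deconvolution

The diffusional PSF is the central plane of the 3D point-source kernel,
a 2D Gaussian with σ = √(2Dt) sampled on the pixel grid and normalized
to unit sum; the optical PSF is neglected (sub-micron, versus tens of
microns of diffusion). Restoration is per-plane ("no-neighbors"):
Richardson–Lucy with 30 iterations by default (inherently non-negative),
or Wiener as an alternative; edges are reflection-padded because AUC
artefacts concentrate at borders. Blur-then-restore round trips recover
spot σ within 15% (typically <2%), shift centers by <0.5 px, and
conserve AUC within 5%; a mean |ΔAUC| above 10% raises the artefact
flag. The true restoration gain on real images depends on how well D, t,
and temperature are known — errors make the kernel mismatched and the
reported σ reduction optimistic or pessimistic accordingly.

## Problem sizes

Default test problems are deliberately modest: 4×4-well stacks
(400×400×100 voxels, two channels), reduced-domain solver runs
(150×150 µm at 2.5 µm), and 256² deconvolution planes. The acceptance
script runs the dilution solver at full 500×500 µm domain size with 1 µm
spacing. All sizes are package defaults or explicit arguments, so larger
runs are a parameter change away.
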