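# Methods

`xdip` processes single-shot coherent X-ray diffraction imaging (CXDI)
data recorded on a tandem pair of multi-panel CCD detectors: a wide-angle
detector ("octal") with a central aperture at camera length 1.6 m, and a
small-angle detector ("dual") behind the aperture at 3.2 m, shielded by a
beamstop and an aluminium attenuator.  This note documents the models,
the tunable parameters, the synthetic-data generator, and the numerical
choices; everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`.

## Geometry model

Pixel coordinates are 0-based with pixel centers at integers; `x` is the
column, `y` the row, and beam centers are fractional.  In the small-angle
(flat Ewald sphere) regime the scattering vector is linear in the pixel
offset from the direct beam,

    S = a R(Θ) (p − c),   a = Δ / (λ L),

with pixel pitch Δ (50 µm), wavelength λ = hc/E (0.22461 nm at 5.52 keV,
hc = 1.2398419 keV·nm) and camera length L.  At 1.6 m one pixel subtends
a = 1.3914×10⁻⁴ nm⁻¹; the 3.2 m detector subtends exactly half of that.
The full-period resolution keeps the exact sine, d = λ/(2 sin θ) with
2θ = atan(r/L): at the edge of a 256-px trimmed pattern (r = 128 px)
this gives 56.15 nm at the nominal 1.6 m.  Published instrument numbers
around 57.4 nm imply an effective camera length near 1.63 m; camera
length is configuration, not a constant.

Detectors are modelled as identical rectangular sensor tiles placed on a
common grid by per-tile offsets (pixels) and small rotations (mrad),
each tile divided into eight readout-port strips along its row
dimension.  Desk-scale layouts (`octal_demo`, `dual_demo`, 256×256 px
with gaps, aperture and beamstop) are used throughout the tests; a
schematic full-scale layout with real 512×1024 px tiles is provided but
never required.

### Aluminium attenuation

Transmission is T = exp(−µ(E)·t) with µ from an embedded table of total
mass-attenuation coefficients for aluminium (NIST Hubbell & Seltzer
values, 2–30 keV, log-log interpolation, ρ = 2.70 g/cm³).  This
reproduces the quoted 56%–2% range for 15–100 µm at 5.52 keV (we compute
55.3% and 1.9%) and gives 13.9% for 50 µm.  Note that beamline
transmission calculators built on Henke/CXRO optical constants run a few
percent lower in µ for Al in this range and quote 14.8% for the same
foil; the discrepancy between the two tabulation families (~3% in µ,
~0.9 percentage points in T here) is documented and the NIST table is
kept as the physically sourced choice.

## Synthetic data

The generator produces the statistical structure every stage assumes;
its defaults are the study conditions and are not tuned per test.

* **Cuboid particles** (the beam-center calibration object): the
  Fraunhofer pattern of a rectangular aperture,
  I = K sinc²(2πA Sx′) sinc²(2πB Sy′), sinc x = sin x / x, with
  half-edges A, B in nm and in-plane rotation Θ.  Evaluated in closed
  form on the detector grid.
* **Disk assemblies** (the centering benchmark object): 1–5 uniform
  disks of diameter 140 nm placed uniformly in a 500 nm square field,
  amplitude Σρₖ·area·jinc(πD|S|)·exp(2πi S·rₖ) with jinc x = 2J₁(x)/x.
  Intensity is exactly centrosymmetric (real object).  The field of
  view and disk-count range are a realistic choice for sub-µm particle
  aggregates and produce both bright single-particle patterns and weak
  multi-particle speckle.
* **Detector forward model** (`record_run`): the dual detector's
  intensities are multiplied by the attenuator transmission; Poisson
  sampling; clipping at the saturation limit (2500 photons at 5.5 keV);
  from the frame after the first saturated pixel in a readout port, a
  constant port offset (default 1.0 photon) is added to the whole port;
  Gaussian dark noise (default σ = 0.3 photons — port-dependent levels
  on real detectors are not modelled); aperture/beamstop shadow zeroed;
  the frame is split into raw per-panel stacks and written to HDF5 with
  time-tracking off, so fixed seeds give byte-identical files.  All
  randomness derives from one master seed through `SeedSequence`
  spawning (stream i → frame i, streams after the frames → darks).
* **Centering benchmark protocol** (`fig10_protocol`): n patterns of
  disk assemblies, true centers shifted uniformly within ±10 px of the
  nominal pixel, the global intensity maximum scaled to 2500 photons,
  Poisson noise, ground truth persisted as CSV.

What the generator does **not** emulate: beam-pointing jitter, membrane
or parasitic background scattering, per-pixel gain variation, ADU
conversion, and port-dependent dark levels.  Passing tests therefore
validate the algorithms under idealized detector statistics, not
calibration robustness on real instruments.

## Preprocessing

Panels are placed by nearest-pixel translation (rotations below a 2 mrad
threshold are treated as translations; calibrated accuracies are ~25 µm
and ~1 mrad), so photon counts are never interpolated and assembly
conserves total photons exactly.  Uncovered pixels and the
aperture/beamstop region are flagged `missing`, never zero-filled
silently.  Darks (100 frames by default) are averaged per pixel and
subtracted on valid pixels.

The post-saturation port offset is estimated as the histogram mode (bin
width 0.1 photon, parabolic sub-bin refinement of the peak) of the
port's high-angle edge ROI (~64×50 px ≈ 3200 px, essentially free of
diffracted photons); the mode rather than the mean makes the estimate
robust to occasional diffraction photons in the ROI.  The offset is
subtracted from all pixels of the port in every frame after the event,
re-estimated per frame by default (a per-event constant is a
configuration switch; the per-frame variant tracks drifting levels and
is idempotent to within one histogram bin).  Saturation detection uses
a small margin (2 photons) below the nominal limit to tolerate readout
noise around full scale.

Hits are sorted by the summed intensity of a user-sized square ROI
(default 512 px) around the assumed beam center, excluding masked
pixels, and partitioned into no-signal (< 100 photons by default;
the three-way split's lower threshold is not prescribed anywhere and is
configuration), below-threshold and extracted (strictly above the user
threshold) classes.

## Beam-center determination

**Model fit.**  The six parameters (K, A, B, Θ, Xc, Yc) are fitted by
damped least squares (`scipy.optimize.least_squares`, TRF with bounds
K, A, B > 0 and Θ wrapped to (−90°, 90°]).  On the small-angle frame
all six are free; on the wide-angle frame A, B are fixed to the values
just determined and (K, Θ, Xc, Yc) are refined.  With the default
`weighting="poisson"` the unweighted solution is re-solved twice with
residuals scaled by 1/√max(I_model, 1), the weights frozen per pass;
iterating frozen-weight reweighting solves the Poisson maximum-
likelihood score equation, whereas weights inside the objective bias
the fit (the optimizer inflates the model to shrink its own weights)
and unweighted fitting understates the parameter uncertainties by an
order of magnitude under photon noise.  Uncertainties are 1σ from the
unscaled inverse Fisher information (the weights already encode the
known noise variance; an empirical residual-variance factor would be
deflated by the many near-empty pixels).  sinc is evaluated through
`numpy.sinc` (series-stable at the origin).  Non-convergence is
reported on the result object, never raised.

**Symmetry score.**  Friedel symmetry of the far-field intensity of a
real object makes the pattern centrosymmetric about the direct beam.
The score of a candidate center c is

    C_sym = 1 − Σ|I₁ − I₂| / Σ(I₁ + I₂)

over pixel pairs (p, 2c − p) with p in the scored ROIs and both
partners valid; intensities are floored at zero (photon counts), so the
score lies in [0, 1], equals 1 exactly at perfect symmetry, and its
discriminating power grows with intensity.  The exact functional form
of this similarity measure is an implementation choice (the measure
need only be bounded, maximal at symmetry and intensity-weighted); it
is isolated in one function so alternatives are a one-line swap.
Default ROI placement: four 48-px squares at radius 56 px, at 0°, 45°,
90° and 135° (one half-plane, so no ROI is another's mate).  The search
is an exhaustive integer grid scan (odd window, default 3×3 wide-angle
/ 5×5 small-angle; 21×21 in the benchmark), ties broken toward the
prior, then lowest row, then lowest column; an optional paraboloid
refinement over the 3×3 neighbourhood of the argmax is provided but off
by default.

Missing pixels whose Friedel mate is measured are filled with the
mate's intensity and flagged valid-by-symmetry; pixels whose mates are
also missing stay excluded downstream.  The wide→small-angle center
prediction is a per-axis affine map with slope fixed to the
camera-length ratio and offsets fitted from ≥ 2 paired observations.

## Merging

Each missing wide-angle pixel's four corners are mapped into dual
coordinates,

    d_dual = R(ΔΘ)(d_octal − P0_octal)·(L_dual/L_octal) + P0_dual,

with ΔΘ the difference of the fitted pattern angles (fitted once per
experimental set-up, not per frame).  The dual intensity inside the
resulting quadrilateral is summed with areal weights computed by exact
convex polygon clipping (Sutherland–Hodgman against each pixel square,
shoelace areas) — no rasterization, so resampling is exact for
piecewise-constant images and conserves photons to rounding error on
fully covered regions; an independent `shapely` oracle checks this in
the tests.  Masked dual pixels contribute nothing and reduce the
per-pixel coverage; pixels below the minimum coverage (default 0.5)
stay missing.  Dual-sourced intensities are divided by the attenuator
transmission (T = 1 if no attenuator is declared).

Merge quality is monitored by a border-continuity score: the mean
absolute log ratio of mean intensities just inside vs just outside the
detector border, per azimuthal sector.  0 means continuous; a pure
scale error s scores |log s|; the accept/reject threshold is left to
the user (the pipeline default accepts everything and records the
score).

## Phase retrieval

The merged pattern is trimmed to 256×256 around the beam center and
2×2-binned to 128×128 (photon sums; binning halves the field of view
and the oversampling ratio drops fourfold, while the real-space pixel —
half the edge resolution, 28.1 nm at the nominal geometry — is
unchanged).  Any binned block containing a missing or saturated pixel
is set to zero and excluded from the Fourier constraint; excluded bins
pass the running estimate through unchanged (fully unconstrained).

The initial support is the autocorrelation of the pattern thresholded
at 0.04 of its maximum.  Phasing is hybrid input–output (β = 0.9,
random initial phases from the run seed) with shrink-wrap support
updates: Gaussian-blur the density magnitude (σ from 3 px, shrinking 1%
per update, floor 1.5 px) and threshold at 0.2 of the blurred maximum,
falling back to the previous support if empty.  The default schedule is
100 rounds of (100 HIO cycles + one support update) followed by 1000
HIO cycles with the support frozen; one run per pattern.  The density
is complex and unconstrained in sign by default (a positivity switch
exists but is off).  None of the shrink-wrap constants are prescribed
by the method's public description; the defaults here are recorded in
every run log.

A subtlety worth stating: the HIO loop variable is the *driving input*
whose off-support part carries feedback and is not physical; the
reconstruction is the Fourier-projected estimate.  Quality metrics use
both views deliberately:

* γ = (Σ_outside|ρ| / Σ_inside|ρ|) / (σ_os − 1) on the **unconstrained**
  estimate — leakage outside the support is exactly what it monitors;
  the (σ_os − 1) normalization makes a uniformly spread |ρ| score 1
  regardless of grid size.  If the oversampling ratio is not supplied
  it is estimated as grid pixels over final support pixels.
* R_F = Σ| |F_obs| − C|F_calc| | / Σ|F_obs| on the **support-masked**
  map (the unconstrained one reproduces the observed moduli by
  construction and would always score ≈ 0).  C minimizes the L1
  numerator by a bounded scalar search seeded at the closed-form
  least-squares scale; an L2-optimal C is available as an option.
  Excluded bins are omitted from both sums.

Particle sizes are measured on the density map, not the shrink-wrap
mask: the footprint is |ρ| above half its maximum (the shrink-wrap mask
is dilated by its blur by construction, ~1–2 px per side, which is a
~60% area bias for a 9-px object), and the reported edge length is the
larger extent of the footprint along its principal axes, times the
real-space pixel.

Failure modes reproduce the expected dichotomy: inputs with too little
oversampling (several particles separated by more than the field
supports) converge to expanding supports and degraded γ; the package
reports γ and R_F and leaves accept/reject thresholds to the user.

## Pipeline and reproducibility

`run_pipeline` executes preprocess → center → merge → retrieve from one
YAML configuration, isolates per-frame failures, writes per-stage CSV
diagnostics plus a JSON report, and stamps every output with the
configuration hash and master seed; re-running with identical inputs is
bit-identical, stochastic stages included.  Per-frame phasing seeds are
spawned from the master seed.

### Problem sizes

All validation runs at desk scale by design: 256×256 detector grids,
200-pattern centering benchmarks, 50-repeat fit-recovery experiments,
128×128 phasing with the full 100×100+1000 schedule.  The methods are
size-independent; the full-scale tile geometry only changes array
dimensions.

## Known limitations

* The attenuation table ships aluminium only, 2–30 keV, and sits on the
  NIST side of the Hubbell-vs-Henke tabulation discrepancy (above).
* Nearest-pixel panel placement is exact for photon bookkeeping but
  limits geometric fidelity for rotations well above ~2 mrad.
* The C_sym search is integer-grid; sub-pixel refinement is provided
  but off by default, matching the integer-grid practice it validates.
* Merging handles exactly two detectors; relative gain between panels
  is assumed calibrated away upstream.
* Phase retrieval is single-run per pattern (no multi-start averaging
  or guided reconstruction) and 2-D only.
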