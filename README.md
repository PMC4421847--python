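# xdip

Processing pipeline for single-shot coherent X-ray diffraction imaging
(CXDI) with a tandem two-detector geometry.

In XFEL-CXDI experiments, femtosecond X-ray pulses hit isolated
sub-micrometre particles and the far-field diffraction pattern of each
shot is recorded before the particle is destroyed.  To cover a wide
dynamic range, two multi-panel CCD detectors sit in tandem on the beam
axis: a wide-angle detector with a central aperture at camera length
1.6 m, and a small-angle detector behind the aperture at 3.2 m,
protected by a beamstop and an aluminium attenuator.  Thousands of
frames per run make manual processing impossible; this package provides
the four processing stages as a library plus the `xdip` command:

1. **preprocess** — assemble raw sensor panels, subtract averaged dark
   frames, correct the one-photon readout-port offset that follows
   pixel saturation, and extract "hit" frames by their small-angle ROI
   intensity sum.
2. **center** — find the direct-beam position to sub-pixel precision,
   by fitting the Fraunhofer model of a cuboid calibration particle,
   I(S) = K sinc²(2πA Sx′) sinc²(2πB Sy′), and/or by exhaustive grid
   search of the Friedel-symmetry score
   C_sym = 1 − Σ|I₁ − I₂| / Σ(I₁ + I₂) over symmetry-related ROIs;
   fill detector gaps from Friedel mates.
3. **merge** — map each wide-angle pixel's corners into small-angle
   coordinates (scale = camera-length ratio, rotation = ΔΘ between the
   fitted pattern angles), resample with exact areal weights from
   convex polygon clipping, and rescale by the attenuator transmission
   T = exp(−µ(E)t).
4. **retrieve** — trim/bin the merged pattern to 128×128, run hybrid
   input–output phasing with shrink-wrap support updates
   (100 × 100 cycles + 1000 final cycles), and report the quality
   monitors γ (support-leakage, oversampling-normalized) and R_F
   (scaled amplitude residual).

A synthetic-data module generates complete runs with the same
statistical structure — Fraunhofer patterns of cuboids and disk
assemblies, Poisson noise, 2500-photon saturation, post-saturation port
offsets, Gaussian dark noise, attenuation — so every stage is testable
without instrument data.

## Worked example

Simulate a small two-detector run of cuboid particles, process it end
to end, and look at the report:

```python
import numpy as np
from xdip import (BeamParameters, Attenuator, CuboidModel, NoiseModel,
                  record_run, render_cuboid)
from xdip.geometry import octal_demo, dual_demo
from xdip.cli import PipelineConfig, run_pipeline

det_o, det_d = octal_demo(), dual_demo()     # desk-scale 256x256 layouts
beam = BeamParameters(5.52)                  # keV
rng = np.random.default_rng(3)
pats = {"octal": [], "dual": []}
for i in range(6):
    K = float(rng.uniform(900, 2400)) if i % 3 else 25.0   # two empty shots
    m = CuboidModel(A=float(rng.uniform(100, 150)), B=float(rng.uniform(100, 150)),
                    theta=float(rng.uniform(-40, 40)), K=K)
    pats["octal"].append(render_cuboid(m, det_o, beam))
    pats["dual"].append(render_cuboid(m, det_d, beam))
record_run(pats, {"octal": det_o, "dual": det_d}, beam, NoiseModel(seed=9),
           "run.h5", "dark.h5", attenuator=Attenuator("aluminium", 50.0))

cfg = PipelineConfig(run="run.h5", dark="dark.h5", outdir="out", seed=4,
                     hit_threshold=2e4, trim=192)
report = run_pipeline(cfg)
print(report["counts"])
print(f"gamma = {report['gamma_mean']:.4f}  R_F = {report['r_factor_mean']:.4f}")
```

prints

```
{'frames': 6, 'hits': 4, 'centered': 4, 'merged': 4, 'retrieved': 4}
gamma = 0.0372  R_F = 0.2992
```

Six frames were recorded, the two near-empty shots fall below the hit
threshold, and the four hits pass centering (C_sym grid search), merging
(aperture filled from the attenuated small-angle detector, ×1/T ≈ 7.2)
and phasing with the full 100×100+1000 schedule.  The mean γ ≈ 0.04
says the retrieved densities are compact inside their supports;
R_F ≈ 0.3 is the amplitude residual of the support-masked maps against
the Poisson-noisy data.  Per-stage CSV
diagnostics and `report.json` land in `out/`, each stamped with the
configuration hash and seed; re-running is bit-identical.

The same stages are available from the shell:

```sh
xdip simulate --out run.h5 --dark dark.h5 --n-frames 6 --seed 9
xdip tamon    --run run.h5 --dark dark.h5 --out hits.h5 --threshold 2e4 --roi 128
xdip jikoku   --run hits.h5 --window 3 --out centers.csv
xdip kohmoku  --run hits.h5 --centers centers.csv --outdir merged/
xdip zocho    --pattern merged/merged_00001 --seed 7
```

## Layout

```
src/xdip/geometry.py     detector/beam model, conversions, attenuation
src/xdip/simulate.py     synthetic runs: renderers, noise, protocols
src/xdip/preprocess.py   assembly, darks, port correction, hit finding
src/xdip/center.py       Fraunhofer fit, C_sym search, symmetry fill
src/xdip/merge.py        corner mapping, areal resampling, continuity
src/xdip/retrieve.py     trim/bin, HIO + shrink-wrap, gamma, R_F
src/xdip/runfile.py      HDF5 run-file schema
src/xdip/cli.py          pipeline driver and `xdip` subcommands
docs/methods.md          models, parameters, numerical choices
```
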