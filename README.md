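# muoct

Functional microanatomy of airway epithelium from micro-OCT image
sequences.

Video-rate, micrometre-resolution optical coherence tomography of airway
epithelium shows — in a single cross-sectional image series, with no dyes
or tracer particles — the mucus layer, the periciliary liquid (PCL), the
beating cilia and the epithelial surface. One recording therefore carries
every headline metric of mucociliary clearance at once:

- **ASL depth** — airway surface liquid: air–mucus interface to the apical
  cell surface (µm);
- **PCL depth** — mucus underside to the apical surface (µm);
- **CBF** — ciliary beat frequency: the frequency of peak amplitude in the
  temporal Fourier transform of regions with oscillatory signal (Hz);
- **MCT** — mucociliary transport velocity, from tracking the bright
  inclusions naturally present in the mucus (µm/s);
- **stroke-phase structure** — decomposition of the ciliary cycle into
  effective / recovery / rest phases on an M-mode (depth × time) trace,
  using the tip-height convention that the effective stroke carries the
  tips above 5 µm and the recovery stroke holds them at 3–5 µm;
- **gland output flow** — duct lumen area × extrusion velocity (nL/min).

Because axial distances inside the liquid are imaged as optical path
length, all sub-interface depths are divided by the refractive index of
the liquid (n = 1.33) to obtain physical micrometres.

`muoct` implements this whole measurement chain as a tested Python
library plus CLI, and pairs it with a **phantom simulator** that renders
synthetic B-scan sequences — layered anatomy, optical-path stretching,
anisotropic PSF, speckle, triphasic ciliary kinematics, advected mucus
with trackable inclusions, an optional secreting gland duct — together
with the exact ground truth for every quantity the analysis estimates.
The phantom is first-class, tested code: it is what makes the analysis
verifiable in the absence of shareable raw recordings.

Who it is for: researchers quantifying mucociliary clearance in airway
cultures or ex vivo tissue (e.g. cystic fibrosis or COPD models), and
developers of OCT analysis code who need a ground-truthed test bed.

## Worked example

Simulate a 4-second phantom parameterised like healthy tracheal
epithelium (the scene defaults: ASL 9.01 µm, PCL 6.96 µm, CBF 10.55 Hz,
MCT 88.9 µm/s), then analyze the rendered TIFF stack. `demo.yaml` sets
only the field geometry:

```yaml
optics: {frame_rate: 40, n_lines: 256, field_x: 250, field_z: 30, dz: 0.5}
duration: 4.0
seed: 11
```

```sh
muoct simulate --config demo.yaml --out demo
muoct analyze --input demo/sequence.tiff --out demo/analysis
```

which prints (this run):

```
      metric region_id     value units      kind      sem  n
   asl_depth       all  8.996296    um aggregate 0.004581  5
   pcl_depth       all  6.947709    um aggregate 0.007203  5
         cbf       all 10.527408    Hz aggregate 0.000293 10
mct_velocity       all 88.899895  um/s aggregate 0.013238 10
```

ASL and PCL depths are means over 5 equally distributed lateral regions,
CBF the mean over up to 10 automatically ranked regions of ciliary
activity, and MCT the mean over the longest inclusion tracks — each
± SEM with its n; every value is within a few percent of the phantom's
ground truth (the CBF deficit of ~0.02 Hz is the residual bias of
parabolic peak interpolation between 0.25 Hz spectral bins, see
`docs/methods.md`).
`report.csv` holds the per-region and per-track values;
`analysis.log` records every parameter the run actually used.

The same operations are available as a library:

```python
from muoct import PhantomConfig, simulate_sequence, measure_cbf

seq, truth = simulate_sequence(PhantomConfig(seed=1))
print(measure_cbf(seq).aggregate)        # -> mean ~ truth.beat_frequency
```

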