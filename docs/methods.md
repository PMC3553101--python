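# Methods

This note documents the models, estimators, defaults and known
limitations behind `muoct`. It is written for someone who wants to trust
(or challenge) a number the package produced.

## Imaging model and coordinate conventions

A B-scan sequence is a `T × Z × X` intensity grid with calibration
(frame interval `dt`, lateral pitch `dx`, axial pitch `dz`, liquid
refractive index `n`). Pixel indices are 0-based; `z = 0` is the top of
the image (air side) and depth increases downward; `x` increases in the
mucus transport direction; coordinates refer to pixel centres, i.e. the
centre of axial pixel `j` sits at `(j + 0.5)·dz` image micrometres.

OCT images depth as optical path length. For a point a physical depth
`d` below the air–liquid interface, the rendered image depth is
`z_interface + n·d`; conversely every measured sub-interface span is
divided by `n` (default 1.33) to report physical micrometres
(`correct_refraction`). The correction is applied in full to both ASL
and PCL: the whole measured span lies below the air–liquid interface,
and a single index is used for mucus and PCL. The imaging axis is
assumed within ~10° of the surface normal; depths are measured along
image columns without tilt correction, which leaves a cosine error of
at most ~1.5% that we accept and do not model.

Default optics mirror a video-rate µOCT instrument: axial FWHM 1.3 µm,
lateral FWHM 2.0 µm, 40 frames/s, 512 A-lines over a 0.5 mm lateral
field. The axial pixel pitch is not dictated by those numbers; we use
`dz = 0.5` µm/px so the axial PSF is sampled at ≥ 2.6 px per FWHM
(a configuration with fewer than 2 px per FWHM is rejected). Lateral
pitch is `field_x / n_lines` ≈ 0.98 µm/px.

## The phantom

The simulator renders, per frame:

1. **Layered background** — air (0), mucus (level 0.35), PCL (0.05),
   epithelium (0.55), drawn as steps blurred by the axial PSF (erf
   profiles). The mucus underside is per-column, so effective-stroke
   cilia tips lift it locally by a configurable few hundred nanometres
   (default 300 nm within ±2 µm of a tip), mimicking tips pushing on the
   mucus blanket.
2. **Scatterers** — each drawn as an anisotropic Gaussian spot of its
   reflectivity at the optical-path-stretched depth: mucus texture
   (≈ 0.5 scatterers/µm², reflectivity ≈ 0.12) advected with the mucus;
   `n_inclusions` bright inclusions (reflectivity 0.6), each an extended
   rigid cluster of five scatterers within ~1 µm — real mucus inclusions
   are macroscopic debris larger than the PSF, which is exactly why they
   are conspicuous against speckle; cilia tip scatterers (0.55); and,
   if a gland is configured, extruded boluses rising through a dark duct
   channel. Texture scatterer centres are uniform over the full mucus
   slab so that the *expected* rendered profile falls off at the slab
   boundary with exactly the same blurred-step shape as the slab itself —
   keeping the apparent interface position identical to the declared
   ground truth.
3. **Noise** — multiplicative unit-mean gamma speckle with
   contrast = std/mean (default 0.5; shape `1/c²`), then an additive
   exponential noise floor (mean 0.02), then clipping to [0, 1].
   Reflectivity levels are scaled to leave headroom below the clip so
   bright features are not flattened.

Each output frame integrates `render_oversample = 4` sub-frame
renderings spread across the frame interval. This finite-exposure model
matters: it attenuates beat harmonics above the Nyquist frequency the
way a real camera does, so e.g. the second harmonic of a 14 Hz beat
sampled at 40 fps does not alias into the analysis band at full
strength. Speckle is drawn independently per sub-frame render — a
simplification relative to real speckle, which decorrelates only as the
scatterers move. Consequently time-averaging suppresses speckle faster
in the phantom than in reality, and test results on speckled phantoms
are in that one respect optimistic.

**Ciliary kinematics.** Each cilium beats with a triphasic cycle of
period `1/f`, with duty fractions (effective, recovery, rest) summing
to 1 (default 0.4/0.4/0.2 — the split is not well characterised in the
literature; these values give all three phases measurable duration).
During the effective stroke the tip travels a circular arc of radius
equal to the cilium length (7 µm) spanning `effective_arc_deg`
(110°) symmetrically about the vertical at uniform angular speed, so it
reaches full length at the apex and `L·cos(arc/2)` ≈ 4.0 µm at the arc
ends. The recovery stroke translates the tip backward at low height
along a piecewise-linear dip from the arc-end height to the bottom of
`recovery_height_range` (3–5 µm) and back; a constant-height recovery
would be invisible to any height-motion criterion, and the dip gives the
recovery stroke a measurable, constant |dh/dt| signature. Rest holds the
tip stationary at the pre-effective (arc start) position. Cilium bases
sit on a uniform lateral grid (default 8 µm spacing) with phases
advancing along a metachronal wave (default wavelength 40 µm) plus a
small seeded jitter, so oscillatory regions are spatially extended and
locally near-coherent, as in real epithelium.

**Ground truth** accompanies every simulation: layer depths, per-column
interface image-depths, beat frequency, per-frame stroke-phase labels
per cilium (evaluated at mid-frame times, matching the exposure centre),
transport velocity, and gland flow = lumen area × extrusion velocity ×
60/10⁶ nL/min. Identical (config, seed) gives byte-identical output.

## Layer segmentation and depth measurement

Interfaces are detected per column on a time-averaged image (default
2 s window):

- *air–mucus*: first intensity rise above the noise level (estimated
  robustly from the top image rows, which are assumed to be air;
  threshold `median + max(3σ, 5% of peak)`), refined to the nearest
  positive intensity-gradient extremum with 3-point parabolic sub-pixel
  interpolation;
- *apical surface*: the strongest positive gradient below the air edge.
  The dark-PCL → bright-epithelium transition is the most contrasted
  edge in the scene, which makes it a robust anchor;
- *mucus–PCL*: the steepest negative gradient strictly between the two.
  If no negative edge reaches 25% of the apical edge strength the mucus
  layer is judged absent and the boundary degenerates to the air
  interface, so ASL = PCL — the physically correct reading.

Profiles are median-filtered laterally (default 9 columns), the ordering
`air ≤ mucus–PCL ≤ apical` is enforced per column (violations are
flagged invalid), and an image with under 50% valid columns raises
"layers unresolved". Depths are averaged over `n_regions = 5` equal
column blocks, converted px → µm → physical µm, and aggregated as
mean ± SEM (SEM = sd/√n). On noise-free phantoms the recovered depths
are within ~0.1 µm of truth across ASL 5–15 µm / PCL 3–7 µm; the
steepest-gradient convention for the mucus underside (rather than the
dark-band onset) is an operationalisation choice with ≤ 1 px ambiguity.

## Ciliary beat frequency

"Oscillatory behaviour" is operationalised per pixel on the mean-removed
temporal spectrum: (a) the fraction of non-DC power inside the analysis
band (default 2 Hz–Nyquist) must exceed 0.5, and (b) the power within
±1 bin of the in-band peak must exceed `max(0.2, 2(ln B + 2)/B)` of the
non-DC total, where `B` is the number of non-DC bins — the second term
is the concentration a *flat* spectrum reaches by chance, which matters
for short recordings. Flagged pixels form 8-connected regions; specks
under 5 px are discarded; a component spanning most of the field
laterally (continuous ciliation) is subdivided into lateral blocks so
up to `max_regions = 10` independent regions are assessed, ranked by
band power. When layer interfaces are available the pipeline restricts
the search to the ciliary band (mucus–PCL + 1.5 µm margin, down to the
apical surface): bright inclusions recirculating through the lateral
field produce genuinely periodic mucus-band signal that is oscillation
but not ciliary activity, and the margin keeps the PSF tail of the
moving mucus band out of the search zone.

Per region, member-pixel series are mean-removed, Hann-tapered and
Fourier transformed, and their **power spectra averaged** before peak
picking. Averaging spectra rather than raw series is deliberate: pixels
within a region beat at different phases (metachrony), and a raw-series
average can cancel the oscillation entirely. The peak is the arg-max
over non-DC bins below Nyquist, refined by 3-point parabolic
interpolation (bias < 0.03 Hz at 0.25 Hz bin spacing, visible as the
~10.53 Hz readout for a 10.55 Hz phantom). A peak whose SNR (peak power
over median non-DC power) is below 2 is rejected as non-oscillatory.
Peaks at or above 72% of Nyquist are reported but flagged as potentially
aliased, with a warning — a beat at `2·f_N − f` is indistinguishable
from `f`, so a 25 Hz beat sampled at 40 fps is reported near 15 Hz and
flagged, never silently trusted. Region frequencies aggregate as
mean ± SEM.

## Mucociliary transport

Inclusions are detected per frame inside the mucus band (between the
air–mucus and mucus–PCL interfaces): the frame is band-pass filtered
with a *lateral* difference of Gaussians whose two terms share identical
axial smoothing — this cancels the bright mucus stripe (constant along
x) exactly while preserving compact lateral features — and local maxima
above `median + 2.5·scaled-MAD` of the filtered band, separated by at
least twice the lateral resolution, are kept with 3×3-centroid
sub-pixel positions. Detections within ~2.5 lateral PSF widths of the
image borders are excluded (filter boundary effects bias centroids
inward, which would flatten track slopes at field entry/exit). Two
inclusions closer than twice the lateral resolution merge into one
detection — a resolution limit, not a bug.

Linking is greedy nearest-neighbour with a distance gate (default 3× the
estimated per-frame advection step), *motion-predictive* gating once a
track has history, and tolerance for up to 2 missed frames; wrap-around
jumps longer than half the field are never linked. Track velocity is
the least-squares slope of x(t) (not endpoint displacement), positive in
the transport direction. The aggregate uses up to the 10 longest tracks
after three quality screens: minimum span 0.25 s, span at least 25% of
the longest track, and an RMS line-fit residual no worse than twice the
cohort median (ballistic motion fits a line to within localisation
noise; chains of spurious detections and identity mix-ups do not). With
10 inclusions the aggregate recovers 1.91–88.9 µm/s phantoms within
~3%.

## Stroke-phase decomposition and arc geometry

An M-mode trace (one column ± 1, depth × time) is reduced to a tip
height series: per frame, the intensity-weighted centroid of supra-noise
pixels between the mucus–PCL and apical interfaces (each trimmed by a
1.5 µm margin against PSF leakage of the bright neighbouring bands),
converted to physical µm above the apical surface. Frames are labelled
*effective* above the 5 µm threshold (treated as physical,
index-corrected height), otherwise *recovery* while |Δh| per frame
exceeds `motion_eps` (default 0.3 µm/frame; scale it with the frame
rate) and *rest* otherwise. Missing frames are interpolated; more than
20% missing raises an error.

A caveat the user should know: with the full 110° arc and 7 µm cilia,
the tip height during the outer ~10° of each end of the effective
stroke is below 5 µm (cos 55° · 7 = 4.0 µm), so the 5-µm rule itself
misattributes roughly 0.08 of the cycle from effective to recovery.
This is a property of the threshold convention, not of the estimator;
duty-recovery validation therefore uses a 90° arc (arc-end height
4.95 µm) with recovery range (3, 4.95) µm, for which the rule is
unambiguous and the recovered duty fractions land within ~0.02.

The effective-stroke arc is fitted on a time-averaged image: pixels in
the ciliary band above the 5 µm height cut form the effective-stroke
lobe (the stationary rest-position spot dwells far longer than the
swept arc and would dominate any global threshold, so the intensity
threshold — background + 20% of peak — is computed within the lobe);
the PSF-thick trace is collapsed to one intensity-weighted ridge point
per column (symmetric window about the per-column peak, so the height
cut does not bias the ridge outward), weak tail columns and
high-leverage residual outliers are dropped, and a Taubin algebraic
circle fit gives the radius — the simpler Kåsa fit shrinks the radius
of a thick ~90°-visible arc by ~20% and is not used. The subtended
angle is the 2%-trimmed angular spread of all band pixels within 1 µm
of the fitted circle, measured about the fitted centre; ring membership
restores the sub-5 µm arc ends while excluding mid-recovery signal. On
the noise-free reference phantom this yields radius 7.2 µm and ~115°
for a true 7 µm / 110° stroke.

## Gland flow

Output flow is `area × velocity × 60 / 10⁶` nL/min (1 nL = 10⁶ µm³),
exactly bilinear in its inputs. Lumen area is pixel-counted on an
en-face slab image (largest supra-threshold connected component ×
pixel area; no shape assumption). Extrusion velocity is measured like
MCT but axially: an axial difference of Gaussians (shared lateral
smoothing cancels structure constant along z, i.e. the duct walls),
tracking, and |slope of z(t)|/n per track — axial image distances are
optical path — with the same cohort-residual screening. Whether the
velocity is taken inside the duct or on the emerging plume is the
caller's choice of box.

## Problem sizes and determinism

Tests and the acceptance script run on reduced fields (typically
60–250 µm × 26–45 µm at native pixel pitch, 0.5–4 s at 40–200 frames/s),
chosen so every estimator still sees ≥ 2 beat periods, ≥ 5 depth
regions and ≥ 5 usable tracks; results at these sizes are
representative because all scales that matter (PSF, layer thicknesses,
beat amplitude, per-frame advection step) are unchanged. All randomness
flows from explicit integer seeds through `numpy` generators: equal
(config, seed) reproduces sequences byte-for-byte and analysis reports
byte-for-byte.

## What passing tests do and do not show

The phantom shares the analysis chain's geometric and statistical
assumptions: flat layered anatomy, a single refractive index below the
interface, uniform transport velocity, frame-uncorrelated speckle,
tip-only cilia scattering with constant reflectivity (if tip
reflectivity varies across the stroke in reality, the phase
decomposition's intensity weighting would shift), and periodic lateral
wrap-around of mucus contents. Recovery of ground truth therefore
validates the estimators' correctness and calibration handling — not
robustness to tilted or folded epithelium, peristaltic or sheared flow,
layered index variation, motion artefacts, or operator-dependent ROI
choices in real recordings.
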