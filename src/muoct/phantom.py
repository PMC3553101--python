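"""Synthetic B-scan sequence simulator with exact ground truth.

The phantom emulates what a micro-OCT cross-section of airway epithelium
looks like: from top to bottom an air gap with no signal, a bright
heterogeneous mucus layer carrying trackable inclusions and advected
laterally by mucociliary transport, a dark periciliary liquid (PCL) band in
which bright cilia tips beat with a triphasic cycle, and a bright epithelial
monolayer.  Optionally a gland duct crosses the epithelium and extrudes
scatterers upward at a configurable velocity.

Optical realism is limited to what the downstream analysis assumes:

* every scatterer below the air-liquid interface is rendered at an image
  depth of ``n_liquid`` times its physical depth (optical path stretching),
* the point-spread function is an anisotropic Gaussian (axial/lateral FWHM
  configurable, defaults 1.3 um / 2.0 um),
* multiplicative unit-mean gamma speckle plus an additive noise floor,
* each frame integrates several sub-frame renderings, emulating the finite
  exposure of a frame (this is what suppresses beat harmonics above the
  Nyquist frequency in real video-rate data).

Every simulated sequence is paired with a :class:`GroundTruth` giving the
true layer depths, beat frequency, per-frame stroke-phase labels, transport
velocity, interface positions and (if present) gland output flow, so every
downstream measurement can be validated against exact truth.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter
from scipy.special import erf

from .errors import ConfigError
from .imgio import BScanSequence

PHASE_LABELS = ("effective", "recovery", "rest")

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OpticsConfig:
    """Imaging-system geometry and sampling.

    Defaults follow the instrument settings of a video-rate micro-OCT
    system: 1.3 um axial and 2.0 um lateral FWHM resolution, 40 frames/s,
    512 A-lines covering a 0.5 mm lateral field, and n = 1.33 for the
    liquid layers.  The axial pixel pitch ``dz`` (0.5 um/px default) must
    sample the axial PSF at two or more pixels per FWHM.
    """

    axial_fwhm: float = 1.3
    lateral_fwhm: float = 2.0
    frame_rate: float = 40.0
    n_lines: int = 512
    field_x: float = 500.0
    field_z: float = 500.0
    dz: float = 0.5
    n_liquid: float = 1.33

    def __post_init__(self) -> None:
        if self.axial_fwhm <= 0 or self.lateral_fwhm <= 0:
            raise ConfigError("PSF FWHMs must be positive")
        if self.frame_rate <= 0:
            raise ConfigError("frame_rate must be positive")
        if self.n_lines < 1 or self.field_x <= 0 or self.field_z <= 0:
            raise ConfigError("field geometry must be positive")
        if self.dz > self.axial_fwhm / 2:
            raise ConfigError(
                f"dz = {self.dz} um undersamples the axial PSF; "
                f"need dz <= axial_fwhm/2 = {self.axial_fwhm / 2} um"
            )
        if self.n_liquid < 1:
            raise ConfigError("n_liquid must be >= 1")

    @property
    def dx(self) -> float:
        """Lateral pixel pitch, um/px."""
        return self.field_x / self.n_lines

    @property
    def nx(self) -> int:
        return self.n_lines

    @property
    def nz(self) -> int:
        return int(round(self.field_z / self.dz))

    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate

    @property
    def sigma_z(self) -> float:
        """Axial PSF sigma in um."""
        return self.axial_fwhm * _FWHM_TO_SIGMA

    @property
    def sigma_x(self) -> float:
        """Lateral PSF sigma in um."""
        return self.lateral_fwhm * _FWHM_TO_SIGMA


@dataclass(frozen=True)
class GlandConfig:
    """A single submucosal gland duct extruding mucus upward.

    ``lumen_area`` is the duct's en-face cross-sectional area (um^2) and
    ``extrusion_velocity`` the longitudinal speed (um/s) of the extruded
    contents; together they imply an output flow of
    ``area * velocity * 60 / 1e6`` nL/min.
    """

    lumen_area: float
    extrusion_velocity: float
    duct_x_frac: float = 0.75      # lateral position of the duct, fraction of field
    duct_width: float = 6.0        # um, rendered width of the duct channel
    duct_depth: float = 20.0       # um, physical length of the duct below the apical surface
    scatterer_spacing: float = 4.0  # um between extruded mucus boluses

    def __post_init__(self) -> None:
        if self.lumen_area < 0 or self.extrusion_velocity < 0:
            raise ConfigError("gland lumen_area and extrusion_velocity must be non-negative")

    @property
    def flow_nl_min(self) -> float:
        """Output flow in nL/min (1 nL = 1e6 um^3)."""
        return self.lumen_area * self.extrusion_velocity * 60.0 / 1e6


@dataclass(frozen=True)
class PhantomConfig:
    """Scene parameters for one simulated culture/tissue preparation.

    Depths are physical micrometres (the renderer applies the optical-path
    stretch).  Defaults reproduce the conditions reported for healthy
    ex vivo trachea: ~9 um airway surface liquid over a ~7 um periciliary
    layer, cilia of length 7 um sweeping a 110 degree effective arc at
    ~10.5 Hz with recovery-stroke tips confined to 3-5 um above the apical
    surface, and mucus transported at ~89 um/s carrying a handful of bright
    inclusions.
    """

    optics: OpticsConfig = field(default_factory=OpticsConfig)
    duration: float = 4.0          # s of video to simulate

    # layered anatomy (physical um)
    asl_depth: float = 9.01        # air-mucus interface to apical cell surface
    pcl_depth: float = 6.96        # mucus underside to apical cell surface
    air_gap: float = 4.0           # image um of air above the liquid surface

    # ciliary kinematics
    cilium_length: float = 7.0
    recovery_height_range: tuple[float, float] = (3.0, 5.0)
    effective_arc_deg: float = 110.0
    beat_frequency: float = 10.55  # Hz
    duty: tuple[float, float, float] = (0.4, 0.4, 0.2)  # effective, recovery, rest
    cilia_spacing: Optional[float] = 8.0   # um between cilium bases; None disables cilia
    metachronal_wavelength: Optional[float] = 40.0  # um; None = all cilia in phase
    phase_jitter: float = 0.02     # sd of random per-cilium phase offset, cycles
    allow_aliasing: bool = False   # permit beat_frequency >= Nyquist (aliasing tests)

    # mucus transport
    mucus_velocity: float = 88.9   # um/s in +x
    n_inclusions: int = 8
    inclusion_reflectivity: float = 0.6
    mucus_lift_nm: float = 300.0   # underside lift near effective-phase tips

    # reflectivity levels and texture (scaled to leave headroom below the
    # clip level so speckle and bright scatterers are not flattened)
    mucus_level: float = 0.35
    pcl_level: float = 0.05
    epi_level: float = 0.55
    tip_reflectivity: float = 0.55
    mucus_scatterer_density: float = 0.5   # texture scatterers per um^2 of mucus
    mucus_scatterer_reflectivity: float = 0.12

    # noise
    speckle_contrast: float = 0.5  # std/mean of multiplicative speckle; 0 disables
    noise_floor: float = 0.02      # mean of additive background noise; 0 disables

    gland: Optional[GlandConfig] = None
    render_oversample: int = 4     # sub-frame renders averaged per frame
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.pcl_depth <= self.asl_depth):
            raise ConfigError("require 0 < pcl_depth <= asl_depth")
        if self.cilia_spacing is not None and self.cilium_length > self.pcl_depth + 1.0:
            raise ConfigError("cilium_length exceeds pcl_depth by more than 1 um")
        d = np.asarray(self.duty, dtype=float)
        if d.size != 3 or np.any(d < 0) or abs(d.sum() - 1.0) > 1e-9:
            raise ConfigError("duty must be three non-negative fractions summing to 1")
        if self.beat_frequency <= 0:
            raise ConfigError("beat_frequency must be positive")
        nyq = self.optics.frame_rate / 2.0
        if self.beat_frequency >= nyq and not self.allow_aliasing:
            raise ConfigError(
                f"beat_frequency {self.beat_frequency} Hz is at/above Nyquist "
                f"({nyq} Hz); set allow_aliasing=True if intended"
            )
        lo, hi = self.recovery_height_range
        if not (0 < lo <= hi):
            raise ConfigError("recovery_height_range must be 0 < low <= high")
        if self.render_oversample < 1:
            raise ConfigError("render_oversample must be >= 1")
        if self.speckle_contrast < 0 or self.noise_floor < 0:
            raise ConfigError("noise parameters must be non-negative")

    # -- derived geometry -------------------------------------------------
    @property
    def mucus_thickness(self) -> float:
        """Physical mucus-layer thickness, um (zero = PCL touches air)."""
        return self.asl_depth - self.pcl_depth

    @property
    def beat_period(self) -> float:
        return 1.0 / self.beat_frequency

    def cilium_bases(self) -> np.ndarray:
        """Lateral base positions of the cilia, um."""
        if self.cilia_spacing is None or self.cilia_spacing <= 0:
            return np.empty(0)
        return np.arange(self.cilia_spacing / 2.0, self.optics.field_x, self.cilia_spacing)

    def cilium_phase_offsets(self) -> np.ndarray:
        """Per-cilium phase offsets in cycles (metachronal gradient + jitter).

        Deterministic in (seed, geometry): the random jitter uses its own
        seeded stream so the offsets do not depend on draw order elsewhere.
        """
        bases = self.cilium_bases()
        if bases.size == 0:
            return bases
        if self.metachronal_wavelength:
            offsets = bases / self.metachronal_wavelength
        else:
            offsets = np.zeros_like(bases)
        if self.phase_jitter > 0:
            rng = np.random.default_rng([self.seed, 0x5EED])
            offsets = offsets + rng.normal(0.0, self.phase_jitter, bases.size)
        return np.mod(offsets, 1.0)


# ---------------------------------------------------------------------------
# ciliary kinematics
# ---------------------------------------------------------------------------

def cilium_tip_position(
    config: PhantomConfig, cilium_index: int, t: float
) -> tuple[float, float, str]:
    """Tip position and stroke-phase label of one cilium at time ``t``.

    Returns ``(x_um, height_um_above_apical, label)``.  The beat cycle is
    triphasic and periodic with period ``1/beat_frequency``:

    * *effective* — the tip lies on a circular arc of radius
      ``cilium_length`` centred at the cilium base, sweeping
      ``effective_arc_deg`` (symmetric about the vertical, so the tip
      reaches its full length at the arc apex) in the transport (+x)
      direction at uniform angular speed;
    * *recovery* — the tip translates backward (-x) at low height, its
      height dipping from the arc-end height down to the bottom of
      ``recovery_height_range`` and back (a piecewise-linear sub-mucus
      path);
    * *rest* — the tip is stationary at the pre-effective position (the
      start of the arc).
    """
    if t < 0:
        raise ConfigError("time t must be non-negative")
    f = config.beat_frequency
    bases = config.cilium_bases()
    if not 0 <= cilium_index < bases.size:
        raise ConfigError(f"cilium_index {cilium_index} out of range (n={bases.size})")
    xb = bases[cilium_index]
    offset = config.cilium_phase_offsets()[cilium_index]
    phi = (t * f + offset) % 1.0
    d_eff, d_rec, _ = config.duty
    L = config.cilium_length
    half = math.radians(config.effective_arc_deg / 2.0)
    x_start, h_start = xb - L * math.sin(half), L * math.cos(half)
    x_end = xb + L * math.sin(half)

    if d_eff > 0 and phi < d_eff:
        s = phi / d_eff
        theta = -half + s * 2.0 * half
        return xb + L * math.sin(theta), L * math.cos(theta), "effective"
    if d_rec > 0 and phi < d_eff + d_rec:
        s = (phi - d_eff) / d_rec
        x = x_end + (x_start - x_end) * s
        low = config.recovery_height_range[0]
        tri = 1.0 - abs(1.0 - 2.0 * s)  # 0 -> 1 -> 0
        h = h_start + (low - h_start) * tri
        return x, h, "recovery"
    return x_start, h_start, "rest"


# ---------------------------------------------------------------------------
# scene construction
# ---------------------------------------------------------------------------

@dataclass
class Scene:
    """Everything the renderer needs to draw one instant of the phantom.

    ``scatterers`` has columns (x um, physical depth um below the
    air-liquid interface, reflectivity).  Layer boundaries are physical
    depths below the interface; ``mucus_bottom`` is per rendered column so
    the local lift of the mucus underside by effective-stroke cilia tips is
    representable.
    """

    scatterers: np.ndarray            # (N, 3): x, depth, reflectivity
    mucus_bottom: np.ndarray          # (nx,) physical depth of the mucus underside
    apical_depth: float               # physical depth of the apical cell surface
    air_gap: float                    # image um of air above the liquid surface
    mucus_level: float
    pcl_level: float
    epi_level: float
    speckle_contrast: float
    noise_floor: float
    n_inclusion_scatterers: int       # how many rows of `scatterers` are inclusions
    gland: Optional[GlandConfig] = None


def _static_mucus_texture(config: PhantomConfig) -> np.ndarray:
    """Reference (t = 0) texture scatterer positions inside the mucus slab.

    Scatterer centres are uniform over the full slab, right up to its
    boundaries: the expectation of the rendered texture then falls off at
    the boundary with exactly the same blurred-step profile as the slab
    itself, so the apparent interface position is not biased by texture.
    """
    thick = config.mucus_thickness
    if thick <= 0.5 or config.mucus_scatterer_density <= 0:
        return np.empty((0, 3))
    rng = np.random.default_rng([config.seed, 0x7E47])
    n = int(round(config.mucus_scatterer_density * config.optics.field_x * thick))
    x = rng.uniform(0.0, config.optics.field_x, n)
    depth = rng.uniform(0.0, thick, n)
    refl = config.mucus_scatterer_reflectivity * rng.uniform(0.5, 1.5, n)
    return np.column_stack([x, depth, refl])


def _static_inclusions(config: PhantomConfig) -> np.ndarray:
    """Reference positions of the bright trackable inclusions.

    Each inclusion is an extended rigid body: a central scatterer carrying
    ``inclusion_reflectivity`` plus a few dimmer satellites within ~1 um,
    advected together.  Real mucus inclusions are macroscopic debris
    larger than the PSF, which is what makes them conspicuous against the
    speckle grain.
    """
    thick = config.mucus_thickness
    if config.n_inclusions <= 0 or thick <= 1.0:
        return np.empty((0, 3))
    rng = np.random.default_rng([config.seed, 0x1C75])
    x = rng.uniform(0.0, config.optics.field_x, config.n_inclusions)
    depth = rng.uniform(0.25 * thick, 0.75 * thick, config.n_inclusions)
    rows = []
    n_sat = 4
    for xi, di in zip(x, depth):
        rows.append((xi, di, config.inclusion_reflectivity))
        sx = rng.normal(0.0, 0.8, n_sat)
        sz = rng.normal(0.0, 0.35, n_sat)
        for j in range(n_sat):
            rows.append(
                (xi + sx[j], float(np.clip(di + sz[j], 0.2, thick - 0.2)),
                 0.5 * config.inclusion_reflectivity)
            )
    return np.asarray(rows)


def build_scene(config: PhantomConfig, t: float) -> Scene:
    """Assemble the scatterer set and layer geometry at time ``t``.

    The mucus slab (texture + inclusions) is advected by
    ``mucus_velocity * t`` with periodic wrap-around, cilia tips follow
    :func:`cilium_tip_position`, gland contents are extruded upward, and
    the mucus underside is raised by ``mucus_lift_nm`` within +/-2 um of
    any cilium currently in its effective stroke.
    """
    if t < 0:
        raise ConfigError("time t must be non-negative")
    opt = config.optics
    fx = opt.field_x
    parts = []

    # advected mucus contents
    shift = config.mucus_velocity * t
    texture = _static_mucus_texture(config)
    if texture.size:
        texture = texture.copy()
        texture[:, 0] = np.mod(texture[:, 0] + shift, fx)
        parts.append(texture)
    inclusions = _static_inclusions(config)
    n_incl = inclusions.shape[0]
    if inclusions.size:
        inclusions = inclusions.copy()
        inclusions[:, 0] = np.mod(inclusions[:, 0] + shift, fx)
        parts.append(inclusions)

    # cilia tips
    bases = config.cilium_bases()
    lift_centres = []
    tips = []
    for i in range(bases.size):
        x, h, label = cilium_tip_position(config, i, t)
        if 0.0 <= x < fx:
            tips.append((x, config.asl_depth - h, config.tip_reflectivity))
        if label == "effective":
            lift_centres.append(x)
    if tips:
        parts.append(np.asarray(tips))

    # gland duct contents, moving upward (depth decreasing) and wrapping
    if config.gland is not None:
        g = config.gland
        gx = g.duct_x_frac * fx
        n_s = max(2, int(round(g.duct_depth / g.scatterer_spacing)))
        rng = np.random.default_rng([config.seed, 0x91A2])
        s0 = rng.uniform(0.0, g.duct_depth, n_s)
        xoff = rng.uniform(-g.duct_width / 3.0, g.duct_width / 3.0, n_s)
        s = np.mod(s0 - g.extrusion_velocity * t, g.duct_depth)
        depth = config.asl_depth + 1.0 + s
        refl = np.full(n_s, 0.5)
        parts.append(np.column_stack([gx + xoff, depth, refl]))

    scatterers = np.vstack(parts) if parts else np.empty((0, 3))

    # per-column mucus underside with local lift near effective tips
    x_cols = (np.arange(opt.nx) + 0.5) * opt.dx
    mucus_bottom = np.full(opt.nx, config.mucus_thickness)
    if config.mucus_thickness > 0 and config.mucus_lift_nm > 0:
        lift = config.mucus_lift_nm / 1000.0
        for xc in lift_centres:
            mucus_bottom[np.abs(x_cols - xc) <= 2.0] = config.mucus_thickness - lift

    return Scene(
        scatterers=scatterers,
        mucus_bottom=mucus_bottom,
        apical_depth=config.asl_depth,
        air_gap=config.air_gap,
        mucus_level=config.mucus_level,
        pcl_level=config.pcl_level,
        epi_level=config.epi_level,
        speckle_contrast=config.speckle_contrast,
        noise_floor=config.noise_floor,
        n_inclusion_scatterers=n_incl,
        gland=config.gland,
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def image_depth(physical_depth: float | np.ndarray, air_gap: float, n_liquid: float):
    """Image (optical-path) depth of a point below the air-liquid interface."""
    return air_gap + n_liquid * np.asarray(physical_depth)


def _soft_edge(z_um: np.ndarray, zb, sigma: float) -> np.ndarray:
    """Unit step at boundary image-depth ``zb`` blurred by the axial PSF."""
    return 0.5 * (1.0 + erf((z_um[:, None] - np.asarray(zb)[None, :]) / (sigma * math.sqrt(2.0))))


def render_frame(
    scene: Scene, optics: OpticsConfig, rng: Optional[np.random.Generator] = None
) -> np.ndarray:
    """Render one Z x X intensity frame from a scene.

    The layered background (air / mucus / PCL / epithelium, and the gland
    duct channel if present) is drawn as axially PSF-blurred steps; each
    scatterer is an anisotropic Gaussian spot of its reflectivity.  All
    sub-interface depths are stretched by ``n_liquid``.  Multiplicative
    unit-mean gamma speckle and an additive exponential noise floor are
    applied, then intensities are clipped to [0, 1].
    """
    nz, nx = optics.nz, optics.nx
    z_um = (np.arange(nz) + 0.5) * optics.dz
    n = optics.n_liquid
    sig_z, sig_x = optics.sigma_z, optics.sigma_x

    # background layers via blurred steps (per-column boundary depths)
    z_surface = np.full(nx, scene.air_gap)
    z_mucus_bottom = image_depth(scene.mucus_bottom, scene.air_gap, n)
    z_apical = np.full(nx, image_depth(scene.apical_depth, scene.air_gap, n))
    img = scene.mucus_level * _soft_edge(z_um, z_surface, sig_z)
    img += (scene.pcl_level - scene.mucus_level) * _soft_edge(z_um, z_mucus_bottom, sig_z)
    img += (scene.epi_level - scene.pcl_level) * _soft_edge(z_um, z_apical, sig_z)
    if scene.gland is not None:
        g = scene.gland
        gx = g.duct_x_frac * optics.field_x
        x_cols = (np.arange(nx) + 0.5) * optics.dx
        duct_cols = np.abs(x_cols - gx) <= g.duct_width / 2.0
        if duct_cols.any():
            duct_level = 0.12
            z_top = z_apical[duct_cols]
            z_bot = image_depth(scene.apical_depth + g.duct_depth, scene.air_gap, n)
            channel = _soft_edge(z_um, z_top, sig_z) - _soft_edge(
                z_um, np.full(duct_cols.sum(), z_bot), sig_z
            )
            img[:, duct_cols] += (duct_level - scene.epi_level) * channel

    # scatterers: bilinear sub-pixel deposit, then PSF blur
    if scene.scatterers.size:
        sc = scene.scatterers
        zc = image_depth(sc[:, 1], scene.air_gap, n) / optics.dz - 0.5
        xc = sc[:, 0] / optics.dx - 0.5
        keep = (zc > -1) & (zc < nz) & (xc > -1) & (xc < nx)
        zc, xc, amp = zc[keep], xc[keep], sc[keep, 2]
        spot = np.zeros((nz, nx))
        z0 = np.floor(zc).astype(int)
        x0 = np.floor(xc).astype(int)
        fz, fx_ = zc - z0, xc - x0
        # peak-normalise so a deposited unit delta blurs to peak ~ reflectivity
        norm = 2.0 * math.pi * (sig_z / optics.dz) * (sig_x / optics.dx)
        for dz_i, wz in ((0, 1.0 - fz), (1, fz)):
            for dx_i, wx in ((0, 1.0 - fx_), (1, fx_)):
                zi, xi = z0 + dz_i, x0 + dx_i
                ok = (zi >= 0) & (zi < nz) & (xi >= 0) & (xi < nx)
                np.add.at(spot, (zi[ok], xi[ok]), amp[ok] * wz[ok] * wx[ok] * norm)
        img += gaussian_filter(spot, sigma=(sig_z / optics.dz, sig_x / optics.dx))

    if scene.speckle_contrast > 0:
        if rng is None:
            raise ConfigError("rng required when speckle_contrast > 0")
        k = 1.0 / scene.speckle_contrast**2
        img = img * rng.gamma(k, 1.0 / k, size=img.shape)
    if scene.noise_floor > 0:
        if rng is None:
            raise ConfigError("rng required when noise_floor > 0")
        img = img + scene.noise_floor * rng.exponential(1.0, size=img.shape)

    return np.clip(img, 0.0, 1.0)


# ---------------------------------------------------------------------------
# ground truth and full simulation
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Exact values of every quantity the analysis pipeline estimates.

    Interface depths are in image micrometres (optical path, matching what
    a detector sees); layer depths are physical micrometres.  Stroke-phase
    labels are evaluated at mid-frame times for each cilium.
    """

    asl_depth: float
    pcl_depth: float
    beat_frequency: float
    mucus_velocity: float
    air_mucus: np.ndarray            # per-column image um
    mucus_pcl: np.ndarray
    apical: np.ndarray
    phase_labels: np.ndarray         # (n_cilia, T) of {effective, recovery, rest}
    cilium_bases: np.ndarray
    gland_flow: Optional[float] = None   # nL/min

    def duty_observed(self, cilium: int = 0) -> dict[str, float]:
        """Fraction of frames spent in each phase for one cilium."""
        labels = self.phase_labels[cilium]
        return {lab: float(np.mean(labels == lab)) for lab in PHASE_LABELS}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "asl_depth": self.asl_depth,
            "pcl_depth": self.pcl_depth,
            "beat_frequency": self.beat_frequency,
            "mucus_velocity": self.mucus_velocity,
            "air_mucus": self.air_mucus.tolist(),
            "mucus_pcl": self.mucus_pcl.tolist(),
            "apical": self.apical.tolist(),
            "phase_labels": self.phase_labels.tolist(),
            "cilium_bases": self.cilium_bases.tolist(),
            "gland_flow": self.gland_flow,
        }
        Path(path).write_text(json.dumps(payload) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            asl_depth=d["asl_depth"],
            pcl_depth=d["pcl_depth"],
            beat_frequency=d["beat_frequency"],
            mucus_velocity=d["mucus_velocity"],
            air_mucus=np.asarray(d["air_mucus"]),
            mucus_pcl=np.asarray(d["mucus_pcl"]),
            apical=np.asarray(d["apical"]),
            phase_labels=np.asarray(d["phase_labels"]),
            cilium_bases=np.asarray(d["cilium_bases"]),
            gland_flow=d["gland_flow"],
        )


def simulate_sequence(config: PhantomConfig) -> tuple[BScanSequence, GroundTruth]:
    """Simulate a full B-scan sequence and its ground truth.

    Frame count is ``floor(duration * frame_rate)``.  Each frame averages
    ``render_oversample`` sub-frame renderings spread over the frame
    interval (finite exposure).  Identical (config, seed) gives
    byte-identical output.
    """
    opt = config.optics
    n_frames = int(math.floor(config.duration * opt.frame_rate))
    if n_frames < 1:
        raise ConfigError("duration shorter than one frame interval")
    if config.duration < 2.0 * config.beat_period:
        warnings.warn(
            "duration covers fewer than two beat periods; CBF will be unresolvable",
            stacklevel=2,
        )
    rng = np.random.default_rng(config.seed)
    K = config.render_oversample
    frames = np.empty((n_frames, opt.nz, opt.nx), dtype=np.float32)
    for j in range(n_frames):
        acc = np.zeros((opt.nz, opt.nx))
        for m in range(K):
            t = (j + (m + 0.5) / K) * opt.dt
            acc += render_frame(build_scene(config, t), opt, rng)
        frames[j] = (acc / K).astype(np.float32)

    seq = BScanSequence(frames=frames, dt=opt.dt, dx=opt.dx, dz=opt.dz, n_liquid=opt.n_liquid)

    bases = config.cilium_bases()
    mid_times = (np.arange(n_frames) + 0.5) * opt.dt
    labels = np.empty((bases.size, n_frames), dtype=object)
    for i in range(bases.size):
        for j, t in enumerate(mid_times):
            labels[i, j] = cilium_tip_position(config, i, t)[2]

    nx = opt.nx
    truth = GroundTruth(
        asl_depth=config.asl_depth,
        pcl_depth=config.pcl_depth,
        beat_frequency=config.beat_frequency,
        mucus_velocity=config.mucus_velocity,
        air_mucus=np.full(nx, config.air_gap),
        mucus_pcl=np.full(nx, image_depth(config.mucus_thickness, config.air_gap, opt.n_liquid)),
        apical=np.full(nx, image_depth(config.asl_depth, config.air_gap, opt.n_liquid)),
        phase_labels=labels,
        cilium_bases=bases,
        gland_flow=None if config.gland is None else config.gland.flow_nl_min,
    )
    return seq, truth


# ---------------------------------------------------------------------------
# en-face gland lumen (synthetic slab for the lumen-area test)
# ---------------------------------------------------------------------------

def render_en_face_lumen(
    lumen_area: float,
    dx: float = 1.0,
    dy: float = 1.0,
    margin: float = 6.0,
    level: float = 0.8,
    noise: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Render a single-slab en-face view of a circular duct lumen.

    Returns ``(image, true_area_um2)``.  The disc is anti-aliased by 4x4
    sub-pixel coverage so thresholding at half-level recovers the area to a
    small fraction of the perimeter pixel count.
    """
    if lumen_area <= 0:
        raise ConfigError("lumen_area must be positive")
    r = math.sqrt(lumen_area / math.pi)
    half = r + margin
    nx = int(math.ceil(2 * half / dx))
    ny = int(math.ceil(2 * half / dy))
    sub = 4
    ys = (np.arange(ny * sub) + 0.5) * dy / sub - half
    xs = (np.arange(nx * sub) + 0.5) * dx / sub - half
    fine = (ys[:, None] ** 2 + xs[None, :] ** 2) <= r * r
    cov = fine.reshape(ny, sub, nx, sub).mean(axis=(1, 3))
    img = level * cov
    if noise > 0:
        rng = np.random.default_rng(seed)
        img = np.clip(img + rng.normal(0.0, noise, img.shape), 0.0, 1.0)
    return img, math.pi * r * r


# ---------------------------------------------------------------------------
# declarative config files
# ---------------------------------------------------------------------------

def config_from_dict(d: dict) -> PhantomConfig:
    d = dict(d)
    if "optics" in d and d["optics"] is not None:
        d["optics"] = OpticsConfig(**d["optics"])
    if "gland" in d and d["gland"] is not None:
        d["gland"] = GlandConfig(**d["gland"])
    for key in ("duty", "recovery_height_range"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    return PhantomConfig(**d)


def config_from_yaml(path: str | Path) -> PhantomConfig:
    """Load a :class:`PhantomConfig` from a nested key/value YAML file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


def config_to_yaml(config: PhantomConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_plain(asdict(config)), sort_keys=False))
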