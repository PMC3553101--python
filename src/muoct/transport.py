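"""Mucociliary transport velocimetry and gland extrusion flow.

Mucociliary transport (MCT) velocity is measured label-free by following
the bright inclusions naturally present in the mucus: per frame, inclusions
are detected as local intensity maxima inside the mucus band (between the
air-mucus and mucus-PCL interfaces), linked frame-to-frame by greedy
nearest-neighbour association with a distance gate, and each track's
velocity taken as the slope of a least-squares line through its lateral
position over time.  The 5-10 longest tracks are aggregated as
mean +/- SEM.

Gland output flow is the product of the duct's en-face luminal
cross-sectional area and the longitudinal extrusion velocity of its
contents (measured the same way as MCT, but axially):
``flow [nL/min] = area [um^2] * velocity [um/s] * 60 / 1e6``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .errors import TrackError
from .imgio import AggregateResult, BScanSequence, aggregate
from .layers import InterfaceSet


@dataclass
class Spot:
    """A detected inclusion in one frame (sub-pixel position, um)."""

    x: float
    z: float
    intensity: float


@dataclass
class Track:
    """A linked inclusion trajectory."""

    track_id: int
    t: np.ndarray               # s
    x: np.ndarray               # um (lateral)
    z: np.ndarray               # um (axial, image coordinates)

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def span(self) -> float:
        return float(self.t[-1] - self.t[0]) if self.n_samples else 0.0

    def residual(self, axis: str = "x") -> float:
        """RMS residual (um) of the least-squares line through the track.

        Genuine advected material moves ballistically and fits a line to
        within the localisation noise; chains of spurious or mixed-identity
        detections do not.
        """
        if self.n_samples < 3:
            return float("inf")
        coord = self.x if axis == "x" else self.z
        coeff = np.polyfit(self.t, coord, 1)
        resid = coord - np.polyval(coeff, self.t)
        return float(np.sqrt(np.mean(resid**2)))

    @property
    def fit_residual(self) -> float:
        return self.residual("x")


def detect_inclusions(
    frame: np.ndarray,
    interfaces: InterfaceSet,
    dx: float,
    dz: float,
    lateral_fwhm: float = 2.0,
    axial_fwhm: float = 1.3,
    k_mad: float = 2.5,
) -> list[Spot]:
    """Detect bright inclusions inside the mucus band of one frame.

    The frame is first band-pass filtered with a difference of Gaussians
    matched to the PSF spot size, which suppresses the slowly varying
    mucus background and de-emphasises speckle grain relative to genuine
    bright inclusions.  Local maxima of the filtered image within the
    mucus band exceeding (median + ``k_mad`` * scaled MAD) of the filtered
    band intensity, separated laterally by at least twice the lateral
    resolution, are kept; positions are refined to sub-pixel precision by
    a 3x3 intensity centroid.  An empty list is a valid result.
    """
    raw = np.asarray(frame, dtype=float)
    nz, nx = raw.shape
    sig_x = max(0.7, lateral_fwhm / 2.3548 / dx)
    sig_z = max(0.7, axial_fwhm / 2.3548 / dz)
    # lateral-only difference of Gaussians: the identical axial smoothing in
    # both terms cancels the bright mucus stripe (constant along x) exactly,
    # leaving compact lateral features such as inclusions
    smooth = ndimage.gaussian_filter(raw, (sig_z, sig_x))
    frame = smooth - ndimage.gaussian_filter(raw, (sig_z, 2.5 * sig_x))
    z_um = (np.arange(nz) + 0.5) * dz
    band = np.zeros((nz, nx), dtype=bool)
    for c in range(nx):
        if not interfaces.valid[c]:
            continue
        top, bot = interfaces.air_mucus[c], interfaces.mucus_pcl[c]
        if bot - top < dz:  # mucus layer absent in this column
            continue
        band[:, c] = (z_um > top + 0.5 * dz) & (z_um < bot - 0.5 * dz)
    if not band.any():
        return []
    vals = frame[band]
    med = float(np.median(vals))
    mad = float(1.4826 * np.median(np.abs(vals - med)))
    # floor keeps a featureless band (mad ~ 0) from promoting float dust
    thr = med + max(k_mad * mad, 1e-6)

    sep_px = max(3, int(round(2.0 * lateral_fwhm / dx)) | 1)
    footprint = np.ones((3, sep_px), dtype=bool)
    local_max = frame == ndimage.maximum_filter(frame, footprint=footprint, mode="nearest")
    # the filter's boundary handling pulls centroids inward near the
    # lateral edges, which would flatten track slopes at entry/exit
    edge = int(math.ceil(2.5 * sig_x)) + 1
    band[:, :edge] = False
    band[:, nx - edge:] = False
    cand = np.column_stack(np.nonzero(local_max & band & (frame > thr)))

    # greedy pruning by brightness with the minimum-separation rule
    order = np.argsort(frame[cand[:, 0], cand[:, 1]])[::-1]
    kept: list[tuple[int, int]] = []
    min_sep = 2.0 * lateral_fwhm
    for i in order:
        zi, xi = cand[i]
        if all(abs((xi - xk) * dx) >= min_sep or abs((zi - zk) * dz) >= 2.0 * dz * 3
               for zk, xk in kept):
            kept.append((zi, xi))

    spots = []
    for zi, xi in kept:
        z0, z1 = max(0, zi - 1), min(nz, zi + 2)
        x0, x1 = max(0, xi - 1), min(nx, xi + 2)
        patch = frame[z0:z1, x0:x1] - med
        patch = np.clip(patch, 0.0, None)
        w = patch.sum()
        if w <= 0:
            continue
        zz, xx = np.mgrid[z0:z1, x0:x1]
        spots.append(
            Spot(
                x=float(((patch * xx).sum() / w + 0.5) * dx),
                z=float(((patch * zz).sum() / w + 0.5) * dz),
                intensity=float(frame[zi, xi]),
            )
        )
    return spots


def link_tracks(
    spots_per_frame: Sequence[Sequence[Spot]],
    max_step: float,
    dt: float,
    field_x: Optional[float] = None,
    memory: int = 1,
) -> list[Track]:
    """Greedy nearest-neighbour frame-to-frame linking with a distance gate.

    Each active track is extended by its nearest unassigned spot in the
    next frame within ``max_step`` um (widened proportionally after missed
    frames); a track survives up to ``memory`` consecutive missed frames
    before terminating.  Jumps longer than half the lateral field
    (wrap-around of advected material) are never linked.
    """
    if len(spots_per_frame) < 3:
        raise TrackError("linking requires at least 3 frames")
    gate = max_step
    if field_x is not None:
        gate = min(gate, field_x / 2.0)

    active: list[list] = []   # [id, [(t, x, z), ...], misses]
    done: list[list] = []
    next_id = 0
    for fi, spots in enumerate(spots_per_frame):
        t = fi * dt
        taken = np.zeros(len(spots), dtype=bool)
        survivors = []
        for tr in active:
            _, samples, misses = tr
            t_last, lx, lz = samples[-1]
            # once a track has history, gate around the extrapolated position
            if len(samples) >= 2:
                recent = samples[-min(5, len(samples)):]
                dt_r = recent[-1][0] - recent[0][0]
                vx = (recent[-1][1] - recent[0][1]) / dt_r if dt_r > 0 else 0.0
                vz = (recent[-1][2] - recent[0][2]) / dt_r if dt_r > 0 else 0.0
                px, pz = lx + vx * (t - t_last), lz + vz * (t - t_last)
            else:
                px, pz = lx, lz
            this_gate = gate * (1 + 0.5 * misses)
            if field_x is not None:
                this_gate = min(this_gate, field_x / 2.0)
            best, best_d = -1, this_gate
            for si, sp in enumerate(spots):
                if taken[si]:
                    continue
                d = math.hypot(sp.x - px, sp.z - pz)
                if d <= best_d:
                    best, best_d = si, d
            if best >= 0:
                taken[best] = True
                samples.append((t, spots[best].x, spots[best].z))
                tr[2] = 0
                survivors.append(tr)
            elif misses < memory:
                tr[2] = misses + 1
                survivors.append(tr)
            else:
                done.append(tr)
        active = survivors
        for si, sp in enumerate(spots):
            if not taken[si]:
                active.append([next_id, [(t, sp.x, sp.z)], 0])
                next_id += 1
    done.extend(active)

    tracks = []
    for tid, samples, _ in done:
        arr = np.asarray(samples)
        tracks.append(Track(track_id=tid, t=arr[:, 0], x=arr[:, 1], z=arr[:, 2]))
    tracks.sort(key=lambda tr: tr.n_samples, reverse=True)
    return tracks


def track_velocity(track: Track, axis: str = "x") -> float:
    """Velocity of a track as the least-squares slope of position vs time.

    Positive along +x (the transport direction) for ``axis="x"``; use
    ``axis="z"`` for axial (extrusion) motion, positive with increasing
    image depth.  Requires at least 3 samples.
    """
    if track.n_samples < 3:
        raise TrackError(f"track {track.track_id} has fewer than 3 samples")
    coord = track.x if axis == "x" else track.z
    slope = np.polyfit(track.t, coord, 1)[0]
    return float(slope)


@dataclass
class MctResult:
    """Mucociliary transport velocities and their aggregate."""

    tracks: list[Track]
    velocities: np.ndarray
    aggregate: Optional[AggregateResult]


def measure_mct(
    seq: BScanSequence,
    interfaces: InterfaceSet,
    n_tracks: int = 10,
    max_step: Optional[float] = None,
    lateral_fwhm: float = 2.0,
    min_tracks: int = 5,
    min_span: float = 0.25,
    max_residual: float = 1.0,
) -> MctResult:
    """MCT velocity from the ``n_tracks`` longest inclusion tracks.

    ``max_step`` (the linking gate, um/frame) defaults to three times the
    median frame-to-frame nearest-neighbour displacement estimated from
    the first frames — i.e. triple the expected per-frame advection step.
    Tracks must span at least ``min_span`` seconds and fit a straight
    line to within ``max_residual`` um RMS (which rejects chains of
    spurious speckle detections); fewer than ``min_tracks`` accepted
    tracks yields a warning, zero an empty result.
    """
    spots_per_frame = [
        detect_inclusions(seq.frames[j], interfaces, seq.dx, seq.dz, lateral_fwhm)
        for j in range(seq.n_frames)
    ]
    field_x = seq.frames.shape[2] * seq.dx

    if max_step is None:
        steps = []
        for a, b in zip(spots_per_frame[:-1], spots_per_frame[1:]):
            for sp in a:
                if b:
                    steps.append(min(math.hypot(sp.x - q.x, sp.z - q.z) for q in b))
        max_step = max(3.0 * float(np.median(steps)), 3.0 * seq.dx) if steps else 5.0 * seq.dx

    tracks = link_tracks(spots_per_frame, max_step=max_step, dt=seq.dt, field_x=field_x,
                         memory=2)
    usable = [tr for tr in tracks
              if tr.n_samples >= 3 and tr.span >= min_span
              and tr.fit_residual <= max_residual]
    if usable:
        # prefer inclusions followed for a substantial stretch: slope
        # noise scales steeply with track brevity
        span_cut = max(min_span, 0.25 * max(tr.span for tr in usable))
        long_enough = [tr for tr in usable if tr.span >= span_cut]
        if len(long_enough) >= min_tracks:
            usable = long_enough
        # a track whose line fit is much worse than its cohort's has mixed
        # identities somewhere along the way
        med_resid = float(np.median([tr.fit_residual for tr in usable]))
        clean = [tr for tr in usable if tr.fit_residual <= max(2.0 * med_resid, 0.3)]
        if len(clean) >= min(min_tracks, len(usable)):
            usable = clean
    usable = usable[:n_tracks]
    if not usable:
        warnings.warn("no usable inclusion track; empty MCT result", stacklevel=2)
        return MctResult(tracks=[], velocities=np.empty(0), aggregate=None)
    if len(usable) < min_tracks:
        warnings.warn(
            f"only {len(usable)} usable tracks (fewer than {min_tracks})", stacklevel=2
        )
    velocities = np.asarray([track_velocity(tr) for tr in usable])
    return MctResult(tracks=usable, velocities=velocities, aggregate=aggregate(velocities))


# ---------------------------------------------------------------------------
# gland extrusion
# ---------------------------------------------------------------------------

@dataclass
class GlandMeasurement:
    """Gland duct luminal area, extrusion velocity and output flow."""

    lumen_area: float           # um^2
    extrusion_velocity: float   # um/s
    flow: float                 # nL/min


def lumen_area(
    en_face: np.ndarray, threshold: float, dx: float = 1.0, dy: float = 1.0
) -> float:
    """Luminal area (um^2) of the largest supra-threshold component.

    Pixel counting (no shape assumption): the largest connected component
    of ``en_face > threshold`` times the pixel area ``dx * dy``.
    """
    mask = np.asarray(en_face) > threshold
    labels, n = ndimage.label(mask)
    if n == 0:
        raise TrackError("no supra-threshold component in the en-face image")
    counts = np.bincount(labels.ravel())[1:]
    return float(counts.max()) * dx * dy


def gland_flow(lumen_area_um2: float, extrusion_velocity: float) -> float:
    """Output flow in nL/min: ``area * velocity * 60 / 1e6`` (1 nL = 1e6 um^3)."""
    if lumen_area_um2 < 0 or extrusion_velocity < 0:
        raise ValueError("lumen area and extrusion velocity must be non-negative")
    return lumen_area_um2 * extrusion_velocity * 60.0 / 1e6


def measure_extrusion_velocity(
    seq: BScanSequence,
    box: tuple[int, int, int, int],
    k_mad: float = 2.5,
    max_step: Optional[float] = None,
    n_tracks: int = 10,
) -> AggregateResult:
    """Longitudinal extrusion speed inside a duct region of interest.

    ``box`` is (z0, z1, x0, x1) in pixels.  Bright moving scatterers in
    the box are detected and linked exactly like mucus inclusions; the
    magnitude of each track's axial slope is refraction-corrected (axial
    image distances are optical path) and aggregated.
    """
    z0, z1, x0, x1 = box
    sig_z = max(0.7, 1.3 / 2.3548 / seq.dz)
    sig_x = max(0.7, 2.0 / 2.3548 / seq.dx)
    spots_per_frame: list[list[Spot]] = []
    for j in range(seq.n_frames):
        sub = seq.frames[j, z0:z1, x0:x1].astype(float)
        # axial difference of Gaussians: identical lateral smoothing in both
        # terms cancels structure constant along z (duct walls, epithelium
        # columns), keeping the compact extruded scatterers
        dog = ndimage.gaussian_filter(sub, (sig_z, sig_x)) - ndimage.gaussian_filter(
            sub, (2.5 * sig_z, sig_x)
        )
        med = float(np.median(dog))
        mad = float(1.4826 * np.median(np.abs(dog - med)))
        thr = med + k_mad * mad
        local_max = dog == ndimage.maximum_filter(dog, size=(5, 3), mode="nearest")
        nz_b = dog.shape[0]
        spots = []
        for zi, xi in np.column_stack(np.nonzero(local_max & (dog > thr))):
            # spots clipped at the box edges have biased centroids and
            # would flatten the fitted slope at track ends
            if zi < 3 or zi >= nz_b - 3:
                continue
            xl, xr = max(xi - 1, 0), min(xi + 2, dog.shape[1])
            patch = np.clip(dog[zi - 1 : zi + 2, xl:xr] - med, 0.0, None)
            zz_loc = np.arange(zi - 1, zi + 2, dtype=float)[:, None]
            w = patch.sum()
            z_sub = float((patch * zz_loc).sum() / w) if w > 0 else float(zi)
            spots.append(
                Spot(
                    x=(x0 + xi + 0.5) * seq.dx,
                    z=(z0 + z_sub + 0.5) * seq.dz,
                    intensity=float(dog[zi, xi]),
                )
            )
        spots_per_frame.append(spots)

    if max_step is None:
        max_step = 6.0 * seq.dz
    tracks = link_tracks(spots_per_frame, max_step=max_step, dt=seq.dt)
    # prefer tracks followed for a substantial fraction of the duct
    # transit; short fragments have noisy slopes
    min_samples = max(12, int(round(0.75 / seq.dt)))
    usable = [tr for tr in tracks if tr.n_samples >= min_samples]
    if not usable:
        usable = [tr for tr in tracks if tr.n_samples >= 12]
    if not usable:
        raise TrackError("no trackable scatterer in the duct box")
    # discard tracks whose axial line fit is much worse than the cohort's
    # (identity hand-offs between successive extruded boluses)
    med_resid = float(np.median([tr.residual("z") for tr in usable]))
    clean = [tr for tr in usable if tr.residual("z") <= max(2.0 * med_resid, 0.3)]
    if clean:
        usable = clean
    usable = usable[:n_tracks]
    speeds = [abs(track_velocity(tr, axis="z")) / seq.n_liquid for tr in usable]
    return aggregate(speeds)
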