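"""Layer segmentation and ASL/PCL depth morphometry.

A time-averaged B-scan of airway epithelium shows, from the top: dark air,
a bright heterogeneous mucus band, a dark periciliary liquid (PCL) band,
and a bright epithelial monolayer.  The airway surface liquid (ASL) depth
is the distance from the air-mucus interface to the apical cell surface;
the PCL depth is the distance from the mucus underside to the apical
surface.  Both spans lie below the air-liquid interface, so measured
optical-path thicknesses are divided by the liquid refractive index
(n = 1.33 by default) to obtain physical depths.

Interface detection is per image column: the air-mucus interface is found
where intensity first rises above the noise level scanning downward and is
refined to the nearest intensity-gradient extremum (sub-pixel, parabolic);
the apical surface is the strongest positive gradient below it (dark PCL
to bright epithelium, the most contrasted edge in the scene); the
mucus-PCL interface is the steepest negative gradient between the two
(bright mucus to dark PCL), degenerating to the air interface when no
mucus band exists.  Detected profiles are median filtered laterally, and
the physical ordering air_mucus <= mucus_pcl <= apical is enforced per
column.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d, median_filter

from .errors import LayerError
from .imgio import AggregateResult, BScanSequence, aggregate


def time_average(seq: BScanSequence, window: float) -> np.ndarray:
    """Pixel-wise mean image over the first ``window`` seconds.

    Averages ``floor(window / dt)`` frames.  ``window`` must be at least
    one frame interval and no longer than the sequence.
    """
    if window < seq.dt:
        raise ValueError(f"window {window} s is shorter than one frame interval ({seq.dt} s)")
    n = int(math.floor(window / seq.dt + 1e-9))
    if n > seq.n_frames:
        raise ValueError(
            f"window {window} s exceeds sequence duration {seq.duration} s"
        )
    return seq.frames[:n].mean(axis=0)


def correct_refraction(optical_thickness, n_liquid: float):
    """Convert an optical-path thickness (image um) to physical um.

    Distances measured below the air-liquid interface are stretched by the
    liquid's refractive index; dividing by ``n_liquid`` undoes this.
    """
    optical_thickness = np.asarray(optical_thickness, dtype=float)
    if np.any(optical_thickness < 0):
        raise ValueError("optical thickness must be non-negative")
    if n_liquid < 1:
        raise ValueError("n_liquid must be >= 1")
    out = optical_thickness / n_liquid
    return float(out) if out.ndim == 0 else out


@dataclass
class InterfaceSet:
    """Per-column interface depths in image micrometres.

    Columns failing detection or the ordering invariant are flagged in
    ``valid`` and their depths set to NaN.
    """

    air_mucus: np.ndarray
    mucus_pcl: np.ndarray
    apical: np.ndarray
    valid: np.ndarray
    dz: float

    @property
    def n_columns(self) -> int:
        return self.air_mucus.size

    @property
    def valid_fraction(self) -> float:
        return float(np.mean(self.valid))


def _parabolic_refine(y: np.ndarray, j: int) -> float:
    """Sub-pixel extremum location of y around index j (vertex of parabola)."""
    if j <= 0 or j >= y.size - 1:
        return float(j)
    denom = y[j - 1] - 2.0 * y[j] + y[j + 1]
    if denom == 0:
        return float(j)
    delta = 0.5 * (y[j - 1] - y[j + 1]) / denom
    return float(j) + float(np.clip(delta, -0.5, 0.5))


def _fill_invalid(profile: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Interpolate over invalid columns so lateral smoothing stays local."""
    if valid.all():
        return profile
    out = profile.copy()
    idx = np.arange(profile.size)
    out[~valid] = np.interp(idx[~valid], idx[valid], profile[valid])
    return out


def detect_interfaces(
    image: np.ndarray,
    dz: float,
    smoothing: int = 9,
    k_sigma: float = 3.0,
    min_valid_frac: float = 0.5,
    axial_presmooth: float = 1.0,
) -> InterfaceSet:
    """Segment the air-mucus, mucus-PCL and apical interfaces of an image.

    Parameters
    ----------
    image:
        2-D (Z x X) intensity image, typically a time average.
    dz:
        Axial pixel pitch in um/px; returned depths are image um.
    smoothing:
        Width (columns) of the lateral median filter applied to each
        detected profile.
    k_sigma:
        Noise threshold multiplier for the first-rise criterion at the
        air-mucus interface.
    min_valid_frac:
        Minimum fraction of columns that must resolve all three
        interfaces; below this a :class:`LayerError` is raised.

    Notes
    -----
    When no bright mucus band exists above the PCL (mucus layer absent),
    the mucus-PCL interface degenerates to the air interface so that
    ASL = PCL, which is the physically correct reading.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("detect_interfaces expects a 2-D image")
    nz, nx = image.shape
    if nz < 8:
        raise LayerError("image too shallow to contain three resolvable bands")

    # noise statistics from the top (air) rows; robust to a few outliers
    top = image[: max(3, min(4, nz // 4))].ravel()
    mu_n = float(np.median(top))
    sigma_n = float(1.4826 * np.median(np.abs(top - mu_n)))
    peak = float(image.max())
    if peak - mu_n < max(6.0 * sigma_n, 0.05):
        raise LayerError("layers unresolved: insufficient image contrast")
    threshold = mu_n + max(k_sigma * sigma_n, 0.05 * (peak - mu_n))

    air = np.full(nx, np.nan)
    mpc = np.full(nx, np.nan)
    api = np.full(nx, np.nan)
    valid = np.zeros(nx, dtype=bool)

    for c in range(nx):
        p = gaussian_filter1d(image[:, c], axial_presmooth)
        g = np.gradient(p)
        above = np.nonzero(p > threshold)[0]
        if above.size == 0:
            continue
        j = int(above[0])
        lo, hi = max(j - 4, 1), min(j + 5, nz - 1)
        j_air = lo + int(np.argmax(g[lo:hi]))
        g_air = g[j_air]
        if g_air <= 0:
            continue
        z_air = _parabolic_refine(g, j_air)

        # apical surface: the strongest positive gradient well below the
        # air edge (the dark-PCL -> bright-epithelium transition, the most
        # contrasted edge in the scene and hence a robust anchor)
        lo3 = min(j_air + 4, nz - 2)
        seg = g[lo3 : nz - 1]
        if seg.size == 0:
            continue
        j_api = lo3 + int(np.argmax(seg))
        if g[j_api] <= 0:
            continue
        z_api = _parabolic_refine(g, j_api)

        # mucus underside: steepest negative gradient strictly between the
        # air edge and the apical surface; when no negative edge of
        # meaningful strength exists the mucus layer is absent and the
        # boundary degenerates to the air interface (ASL = PCL)
        lo2, hi2 = j_air + 2, j_api - 1
        degenerate = hi2 <= lo2
        if not degenerate:
            seg = g[lo2:hi2]
            j_mpc = lo2 + int(np.argmin(seg))
            degenerate = g[j_mpc] > -0.25 * g[j_api]
        z_mpc = z_air if degenerate else _parabolic_refine(g, j_mpc)

        if not (z_air <= z_mpc + 1e-9 and z_mpc <= z_api + 1e-9):
            continue
        air[c], mpc[c], api[c] = z_air, z_mpc, z_api
        valid[c] = True

    if valid.mean() < min_valid_frac:
        raise LayerError(
            f"layers unresolved: only {valid.sum()}/{nx} columns yielded "
            "an ordered interface triple"
        )

    # lateral median smoothing of each profile (in pixel units)
    if smoothing > 1:
        for prof in (air, mpc, api):
            filled = _fill_invalid(prof, valid)
            prof[:] = median_filter(filled, size=smoothing, mode="nearest")
        # re-assert ordering after smoothing
        bad = ~((air <= mpc + 1e-9) & (mpc <= api + 1e-9))
        valid &= ~bad

    to_um = lambda px: (px + 0.5) * dz  # pixel centres
    out = InterfaceSet(
        air_mucus=to_um(air), mucus_pcl=to_um(mpc), apical=to_um(api), valid=valid, dz=dz
    )
    out.air_mucus[~valid] = np.nan
    out.mucus_pcl[~valid] = np.nan
    out.apical[~valid] = np.nan
    return out


@dataclass
class DepthMeasurement:
    """ASL and PCL depths per lateral region, with mean +/- SEM aggregates.

    Depths are physical micrometres (refraction-corrected).
    """

    region_bounds: list[tuple[int, int]]
    asl_values: np.ndarray
    pcl_values: np.ndarray
    asl: AggregateResult
    pcl: AggregateResult


def measure_depths(
    interfaces: InterfaceSet,
    n_liquid: float,
    n_regions: int = 5,
) -> DepthMeasurement:
    """ASL and PCL depth at ``n_regions`` equally distributed regions.

    The image width is split into ``n_regions`` equal column blocks; in
    each, ASL is the mean over valid columns of (apical - air_mucus) and
    PCL the mean of (apical - mucus_pcl), converted from image to physical
    micrometres via :func:`correct_refraction`.  Regions with no valid
    column are omitted (with a warning) and ``n`` reduced accordingly.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    nx = interfaces.n_columns
    edges = np.linspace(0, nx, n_regions + 1).astype(int)
    bounds, asl_vals, pcl_vals = [], [], []
    for r in range(n_regions):
        c0, c1 = edges[r], edges[r + 1]
        sel = interfaces.valid[c0:c1]
        if not sel.any():
            warnings.warn(f"region {r} has no valid columns; omitted", stacklevel=2)
            continue
        asl_opt = np.nanmean(interfaces.apical[c0:c1] - interfaces.air_mucus[c0:c1])
        pcl_opt = np.nanmean(interfaces.apical[c0:c1] - interfaces.mucus_pcl[c0:c1])
        bounds.append((int(c0), int(c1)))
        asl_vals.append(correct_refraction(asl_opt, n_liquid))
        pcl_vals.append(correct_refraction(pcl_opt, n_liquid))
    if not asl_vals:
        raise LayerError("no region yielded a depth measurement")
    return DepthMeasurement(
        region_bounds=bounds,
        asl_values=np.asarray(asl_vals),
        pcl_values=np.asarray(pcl_vals),
        asl=aggregate(asl_vals),
        pcl=aggregate(pcl_vals),
    )
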