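"""Ciliary beating: oscillatory regions, beat frequency, stroke phases.

Ciliary beat frequency (CBF) is the frequency of peak amplitude in the
temporal Fourier transform of image regions exhibiting oscillatory
behaviour.  "Oscillatory" is operationalised per pixel as (a) a dominant
fraction of non-DC temporal power inside the analysis band and (b) that
power concentrated at a spectral peak rather than spread broadband (which
distinguishes beating cilia from flowing-speckle mucus).  Flagged pixels
are grouped into 8-connected regions and up to ``max_regions`` regions,
ranked by band power, are assessed.

Per region, the temporal power spectra of the member pixels (Hann-tapered,
mean-removed) are averaged and the peak located over the non-DC bins below
the Nyquist frequency, then refined by three-point parabolic interpolation.
Averaging *spectra* rather than the raw time series keeps the oscillation
from cancelling when pixels within a region beat at different phases
(metachrony), which is the norm in real epithelium.

The stroke cycle is decomposed on an M-mode (depth x time) trace: the tip
height above the apical surface is the intensity-weighted centroid of the
supra-apical signal (refraction-corrected), labelled *effective* above a
5 um threshold, otherwise *recovery* while the height changes faster than
``motion_eps`` per frame and *rest* when it does not.  The effective-stroke
arc seen in time-averaged images is quantified by an algebraic
least-squares circle fit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .errors import ArcError, DynamicsError
from .imgio import AggregateResult, BScanSequence, aggregate

#: peak frequencies at or above this fraction of Nyquist are flagged as
#: potentially aliased (an out-of-band beat at 2*Nyquist - f is
#: indistinguishable from f)
ALIASING_GUARD_FRACTION = 0.72


@dataclass
class OscillatoryRegion:
    """A connected group of pixels flagged as oscillating."""

    pixels: np.ndarray          # (N, 2) array of (z, x) indices
    band_power: float
    bbox: tuple[int, int, int, int]  # z0, z1, x0, x1 (half-open)

    @property
    def n_pixels(self) -> int:
        return self.pixels.shape[0]


@dataclass
class SpectralPeak:
    """Location of the dominant temporal-frequency peak of a region."""

    frequency: float            # Hz, after parabolic refinement
    power: float
    snr: float                  # peak power / median non-DC power
    bin_index: int              # pre-interpolation DFT bin of the peak
    aliased: bool = False
    region: Optional[OscillatoryRegion] = None


@dataclass
class CbfResult:
    """Per-region beat-frequency peaks and their mean +/- SEM aggregate."""

    peaks: list[SpectralPeak]
    aggregate: Optional[AggregateResult]

    @property
    def frequencies(self) -> np.ndarray:
        return np.asarray([p.frequency for p in self.peaks])


def _band_edges(band, nyquist: float, df: float) -> tuple[float, float]:
    lo, hi = band if band is not None else (0.0, None)
    lo = max(lo, 0.5 * df)  # always exclude DC
    hi = nyquist if hi is None else min(hi, nyquist)
    if hi <= lo:
        raise ValueError(f"empty analysis band ({lo}, {hi}) Hz")
    return lo, hi


def oscillatory_mask(
    seq: BScanSequence,
    band: tuple[float, Optional[float]] = (2.0, None),
    power_frac: float = 0.5,
    peak_conc: float = 0.2,
    max_regions: int = 10,
    min_pixels: int = 5,
    z_range: Optional[tuple[float, float]] = None,
) -> tuple[np.ndarray, list[OscillatoryRegion]]:
    """Flag oscillating pixels and group them into connected regions.

    A pixel is flagged when the fraction of its non-DC temporal power
    inside ``band`` exceeds ``power_frac`` and the power within +/-1 bin of
    its in-band spectral peak exceeds ``peak_conc`` of the total non-DC
    power.  Returns the binary mask and up to ``max_regions`` 8-connected
    regions ordered by descending band power; isolated specks smaller than
    ``min_pixels`` are discarded, and a connected component spanning most
    of the field laterally (continuous ciliation) is subdivided into
    lateral blocks so that up to ``max_regions`` independent regions of
    ciliary activity are assessed.  Finding no region is not an error (a
    warning is issued and an empty list returned).

    ``z_range`` (image um, ``(top, bottom)``) optionally restricts the
    search axially.  The analysis pipeline passes the mucus-underside-to-
    apical band here: bright inclusions advected through the field can
    produce genuinely periodic intensity in the mucus band (transit and
    recirculation periodicity), which is oscillation but not ciliary
    activity — the restriction keeps the assessed regions ciliary.
    """
    lo, hi = _band_edges(band, seq.nyquist, 1.0 / seq.duration)
    if seq.duration < 2.0 / lo:
        raise ValueError("sequence too short to resolve the low edge of the band")
    x = seq.frames - seq.frames.mean(axis=0, keepdims=True)
    spec = np.abs(np.fft.rfft(x, axis=0)) ** 2
    freqs = np.fft.rfftfreq(seq.n_frames, seq.dt)
    nondc = spec[1:]
    total = nondc.sum(axis=0)
    total = np.where(total > 0, total, np.inf)
    in_band = (freqs[1:] >= lo) & (freqs[1:] <= hi)
    if not in_band.any():
        raise ValueError("analysis band contains no DFT bins")
    band_power = nondc[in_band].sum(axis=0)
    frac = band_power / total

    band_spec = np.where(in_band[:, None, None], nondc, 0.0)
    pk = np.argmax(band_spec, axis=0)
    z_idx, x_idx = np.indices(pk.shape)
    conc = band_spec[pk, z_idx, x_idx].astype(float)
    for off in (-1, 1):
        nb = np.clip(pk + off, 0, nondc.shape[0] - 1)
        conc = conc + nondc[nb, z_idx, x_idx]
    conc = conc / total

    # white-noise null: a flat spectrum over B bins concentrates roughly
    # (ln B + 2)/B of its power at the peak +/- 1 bins, so short recordings
    # need a proportionally higher concentration threshold
    n_bins = int(nondc.shape[0])
    conc_null = 2.0 * (math.log(n_bins) + 2.0) / n_bins
    mask = (frac > power_frac) & (conc > max(peak_conc, conc_null))
    if z_range is not None:
        z = seq.z_um
        rows = (z >= z_range[0]) & (z < z_range[1])
        mask &= rows[:, None]
    labels, n_lab = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    nx = mask.shape[1]
    block_w = max(8, int(math.ceil(nx / max_regions)))
    regions: list[OscillatoryRegion] = []
    for lab in range(1, n_lab + 1):
        zz, xx = np.nonzero(labels == lab)
        if zz.size < min_pixels:
            continue
        # wide components (continuously ciliated field) become lateral blocks
        x_lo = int(xx.min())
        n_blocks = max(1, int(math.ceil((xx.max() + 1 - x_lo) / block_w)))
        for b in range(n_blocks):
            sel = (xx >= x_lo + b * block_w) & (xx < x_lo + (b + 1) * block_w)
            if sel.sum() < min_pixels:
                continue
            zs, xs = zz[sel], xx[sel]
            regions.append(
                OscillatoryRegion(
                    pixels=np.column_stack([zs, xs]),
                    band_power=float(band_power[zs, xs].sum()),
                    bbox=(int(zs.min()), int(zs.max()) + 1, int(xs.min()), int(xs.max()) + 1),
                )
            )
    regions.sort(key=lambda r: r.band_power, reverse=True)
    regions = regions[:max_regions]
    if not regions:
        warnings.warn("no oscillatory region found", stacklevel=2)
    return mask, regions


def region_cbf(
    seq: BScanSequence,
    region: OscillatoryRegion | np.ndarray,
    band: Optional[tuple[float, Optional[float]]] = None,
    snr_min: float = 2.0,
) -> Optional[SpectralPeak]:
    """Beat frequency of one region from its averaged temporal power spectrum.

    Member-pixel time series are mean-removed, Hann-tapered and Fourier
    transformed; their power spectra are averaged and the arg-max located
    over the non-DC bins up to the Nyquist frequency (or within ``band``
    if given).  The peak is refined by three-point parabolic interpolation
    around the peak bin.  Returns ``None`` (with a warning) when the
    region carries no oscillatory power or the peak's SNR (peak power over
    median non-DC power) falls below ``snr_min`` — a flat or drifting
    spectrum, not a beat.
    Peaks close to Nyquist are flagged ``aliased`` and a warning issued,
    since a beat above Nyquist would fold back onto the same bin.
    """
    pixels = region.pixels if isinstance(region, OscillatoryRegion) else np.asarray(region)
    if pixels.size == 0:
        raise ValueError("region is empty")
    T = seq.n_frames
    series = seq.frames[:, pixels[:, 0], pixels[:, 1]].astype(float)
    series = series - series.mean(axis=0, keepdims=True)
    window = np.hanning(T)[:, None]
    power = np.abs(np.fft.rfft(series * window, axis=0)) ** 2
    power = power.mean(axis=1)
    freqs = np.fft.rfftfreq(T, seq.dt)

    lo, hi = _band_edges(band, seq.nyquist, 1.0 / seq.duration)
    searchable = (freqs >= lo) & (freqs <= hi) & (freqs > 0) & (freqs < seq.nyquist)
    if not searchable.any() or power[searchable].max() <= 0:
        warnings.warn("region has no oscillatory power; no peak reported", stacklevel=2)
        return None
    idx = np.nonzero(searchable)[0]
    j = int(idx[np.argmax(power[idx])])

    nondc = power[1:]
    med = float(np.median(nondc[nondc > 0])) if np.any(nondc > 0) else 0.0
    snr = float(power[j] / med) if med > 0 else math.inf
    if snr < snr_min:
        warnings.warn(
            "spectral peak SNR below threshold; rejected as non-oscillatory",
            stacklevel=2,
        )
        return None

    # three-point parabolic refinement on the power spectrum
    df = freqs[1] - freqs[0]
    if 0 < j < power.size - 1:
        denom = power[j - 1] - 2.0 * power[j] + power[j + 1]
        delta = 0.0 if denom == 0 else 0.5 * (power[j - 1] - power[j + 1]) / denom
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    freq = (j + delta) * df

    aliased = freq >= ALIASING_GUARD_FRACTION * seq.nyquist
    if aliased:
        warnings.warn(
            f"peak at {freq:.2f} Hz is close to Nyquist ({seq.nyquist:.2f} Hz); "
            "the true beat frequency may be aliased from above Nyquist",
            stacklevel=2,
        )
    reg = region if isinstance(region, OscillatoryRegion) else None
    return SpectralPeak(frequency=float(freq), power=float(power[j]), snr=snr,
                        bin_index=j, aliased=aliased, region=reg)


def measure_cbf(
    seq: BScanSequence,
    max_regions: int = 10,
    band: tuple[float, Optional[float]] = (2.0, None),
    power_frac: float = 0.5,
    peak_conc: float = 0.2,
    snr_min: float = 2.0,
    z_range: Optional[tuple[float, float]] = None,
) -> CbfResult:
    """CBF over up to ``max_regions`` oscillatory regions, mean +/- SEM.

    ``z_range`` restricts the region search axially (see
    :func:`oscillatory_mask`); pass the ciliary band when layer
    interfaces are available.
    """
    _, regions = oscillatory_mask(
        seq, band=band, power_frac=power_frac, peak_conc=peak_conc,
        max_regions=max_regions, z_range=z_range,
    )
    peaks = []
    for reg in regions:
        pk = region_cbf(seq, reg, band=band, snr_min=snr_min)
        if pk is not None:
            peaks.append(pk)
    if not peaks:
        warnings.warn("no accepted CBF peak; empty result", stacklevel=2)
        return CbfResult(peaks=[], aggregate=None)
    return CbfResult(peaks=peaks, aggregate=aggregate([p.frequency for p in peaks]))


# ---------------------------------------------------------------------------
# M-mode and stroke-phase decomposition
# ---------------------------------------------------------------------------

@dataclass
class MModeTrace:
    """A depth x time slice of the sequence at one lateral position."""

    data: np.ndarray            # (Z, T)
    x: int                      # source column (px)
    dt: float
    dz: float
    n_liquid: float

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    @property
    def z_um(self) -> np.ndarray:
        return (np.arange(self.data.shape[0]) + 0.5) * self.dz


def extract_mmode(seq: BScanSequence, x: int, half_width: int = 1) -> MModeTrace:
    """M-mode trace at column ``x``, averaged over ``+/- half_width`` columns."""
    nx = seq.frames.shape[2]
    if not 0 <= x < nx:
        raise ValueError(f"column {x} outside image width {nx}")
    c0, c1 = max(0, x - half_width), min(nx, x + half_width + 1)
    data = seq.frames[:, :, c0:c1].mean(axis=2).T  # (Z, T)
    return MModeTrace(data=np.ascontiguousarray(data), x=x, dt=seq.dt, dz=seq.dz,
                      n_liquid=seq.n_liquid)


@dataclass
class PhaseSegmentation:
    """Per-frame stroke-phase labels and the tip-height series behind them."""

    labels: np.ndarray          # (T,) of {"effective", "recovery", "rest"}
    height: np.ndarray          # (T,) tip height, physical um above apical
    duty: dict[str, float]
    height_threshold: float
    motion_eps: float


def segment_phases(
    mmode: MModeTrace,
    apical_z_um: float,
    height_threshold: float = 5.0,
    motion_eps: float = 0.3,
    top_z_um: Optional[float] = None,
    intensity_frac: float = 0.3,
    max_missing_frac: float = 0.2,
    edge_margin_um: float = 1.5,
) -> PhaseSegmentation:
    """Decompose an M-mode ciliary signal into effective/recovery/rest.

    Per frame, the tip height is the intensity-weighted centroid depth of
    supra-noise pixels between ``top_z_um`` (e.g. the mucus-PCL interface;
    the top of the trace if omitted) and the apical surface at
    ``apical_z_um`` (image um), converted to physical um above the apical
    surface.  Frames are labelled *effective* when the height exceeds
    ``height_threshold`` (physical um, default 5), otherwise *recovery*
    when the height changes by more than ``motion_eps`` um/frame (central
    difference) and *rest* when it does not.

    ``edge_margin_um`` trims the band below ``top_z_um`` and above
    ``apical_z_um`` so the PSF-blurred tails of the bright mucus and
    epithelium bands do not bias the centroid.

    Raises :class:`DynamicsError` when more than ``max_missing_frac`` of
    frames carry no supra-noise signal in the band.
    """
    z = mmode.z_um
    rows = z < apical_z_um - edge_margin_um
    if top_z_um is not None:
        rows &= z > top_z_um + edge_margin_um
    if not rows.any():
        raise DynamicsError("no rows between the top bound and the apical surface")
    band = mmode.data[rows]                       # (Zb, T)
    zb = z[rows]
    lo, hi = float(band.min()), float(band.max())
    if hi <= lo:
        raise DynamicsError("cilia not tracked: band has no intensity variation")
    thr = lo + intensity_frac * (hi - lo)

    T = band.shape[1]
    height = np.full(T, np.nan)
    for t in range(T):
        v = band[:, t] - thr
        v[v < 0] = 0.0
        w = v.sum()
        if w <= 0:
            continue
        zc = float((v * zb).sum() / w)
        height[t] = (apical_z_um - zc) / mmode.n_liquid

    missing = np.isnan(height)
    if missing.mean() > max_missing_frac:
        raise DynamicsError(
            f"cilia not tracked: no supra-noise signal in {missing.mean():.0%} of frames"
        )
    if missing.any():  # interpolate isolated dropouts so labelling is continuous
        idx = np.arange(T)
        height[missing] = np.interp(idx[missing], idx[~missing], height[~missing])

    dh = np.zeros(T)
    if T > 1:
        dh[1:-1] = (height[2:] - height[:-2]) / 2.0
        dh[0] = height[1] - height[0]
        dh[-1] = height[-1] - height[-2]

    labels = np.empty(T, dtype=object)
    eff = height > height_threshold
    rec = ~eff & (np.abs(dh) > motion_eps)
    labels[eff] = "effective"
    labels[rec] = "recovery"
    labels[~eff & ~rec] = "rest"
    duty = {lab: float(np.mean(labels == lab)) for lab in ("effective", "recovery", "rest")}
    return PhaseSegmentation(labels=labels, height=height, duty=duty,
                             height_threshold=height_threshold, motion_eps=motion_eps)


# ---------------------------------------------------------------------------
# effective-stroke arc geometry
# ---------------------------------------------------------------------------

@dataclass
class StrokeArc:
    """Fitted effective-stroke arc: radius, angular extent, circle centre."""

    radius: float               # physical um
    angle_deg: float            # subtended angle of supra-threshold points
    center: tuple[float, float]  # (x um, height um above apical)
    n_points: int


def fit_circle(points: np.ndarray) -> tuple[float, float, float]:
    """Algebraic least-squares circle fit (Taubin SVD form).

    ``points`` is (N, 2) of (x, y).  Returns (xc, yc, radius).  The
    Taubin estimator is essentially unbiased for thick or partial arcs,
    unlike the simpler Kasa fit which shrinks the radius.  Raises
    :class:`ArcError` for degenerate (e.g. collinear) inputs, whose
    fitted radius diverges.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ArcError("circle fit requires at least 3 points")
    x0, y0 = pts.mean(axis=0)
    u, v = pts[:, 0] - x0, pts[:, 1] - y0
    w = u * u + v * v
    wm = float(w.mean())
    if wm <= 0:
        raise ArcError("circle fit degenerate (coincident points)")
    Z0 = (w - wm) / (2.0 * math.sqrt(wm))
    _, _, vt = np.linalg.svd(np.column_stack([Z0, u, v]), full_matrices=False)
    a0, a1, a2 = vt[2]
    a0 = a0 / (2.0 * math.sqrt(wm))
    a3 = -wm * a0
    span = float(np.ptp(pts, axis=0).max())
    if abs(a0) < 1e-12 / max(span, 1.0):
        raise ArcError("circle fit degenerate (collinear points)")
    xc = -a1 / (2.0 * a0) + x0
    yc = -a2 / (2.0 * a0) + y0
    r2 = (a1 * a1 + a2 * a2 - 4.0 * a0 * a3) / (4.0 * a0 * a0)
    if r2 <= 0:
        raise ArcError("circle fit degenerate (non-positive radius)")
    radius = math.sqrt(r2)
    if span > 0 and radius > 100.0 * span:
        raise ArcError("circle fit degenerate: radius far exceeds point spread")
    return float(xc), float(yc), radius


def arc_angular_extent(
    points: np.ndarray, center: tuple[float, float], trim_percent: float = 0.0
) -> float:
    """Angular extent (degrees) of points around a circle centre.

    Angles are measured from the upward vertical through the centre, which
    suits effective-stroke arcs that straddle the vertical; the extent is
    the max-min spread, optionally with ``trim_percent`` of the angle
    distribution trimmed from each end (robust against blur tails when the
    points come from thresholded image pixels).
    """
    pts = np.asarray(points, dtype=float)
    ang = np.degrees(np.arctan2(pts[:, 0] - center[0], pts[:, 1] - center[1]))
    if trim_percent > 0:
        lo, hi = np.percentile(ang, [trim_percent, 100.0 - trim_percent])
        return float(hi - lo)
    return float(ang.max() - ang.min())


def fit_stroke_arc(
    image: np.ndarray,
    apical_z_um,
    dx: float,
    dz: float,
    n_liquid: float,
    height_min: float = 5.0,
    top_z_um=None,
    intensity_frac: float = 0.2,
    ring_tol: float = 1.0,
    min_points: int = 10,
    edge_margin_um: float = 1.5,
) -> StrokeArc:
    """Fit the effective-stroke arc in a time-averaged image.

    Supra-threshold pixels above the apical surface with physical height
    greater than ``height_min`` (the effective-stroke lobe, clear of the
    lower recovery-stroke lobes and of the stationary rest-position spot,
    whose long dwell makes it far brighter than the swept arc) are fitted
    with an algebraic circle in (x, height) coordinates, heights
    refraction-corrected.  The intensity threshold is
    ``background + intensity_frac * (peak - background)`` computed within
    the height-cut zone, so the faint swept trace is not judged against
    the bright stationary dwell spots below.  The subtended angle is then
    measured over all pixels in the band lying within ``ring_tol`` um of
    the fitted circle, which restores the shallow ends of the arc that
    the height cut removed while still excluding mid-recovery signal near
    the centre.

    ``apical_z_um`` (and optionally ``top_z_um`` to mask out the mucus
    band) may be scalars or per-column arrays in image micrometres;
    ``edge_margin_um`` trims the PSF-blurred tails of the bright bands.
    """
    image = np.asarray(image, dtype=float)
    nz, nx = image.shape
    z = (np.arange(nz) + 0.5) * dz
    x = (np.arange(nx) + 0.5) * dx
    apical = np.broadcast_to(np.asarray(apical_z_um, dtype=float), (nx,))
    zz = np.broadcast_to(z[:, None], (nz, nx))
    xx = np.broadcast_to(x[None, :], (nz, nx))
    supra = zz < apical[None, :] - edge_margin_um
    if top_z_um is not None:
        top = np.broadcast_to(np.asarray(top_z_um, dtype=float), (nx,))
        supra &= zz > top[None, :] + edge_margin_um
    if not supra.any():
        raise ArcError("no arc: no pixels above the apical surface")
    height = (apical[None, :] - zz) / n_liquid

    lobe = supra & (height > height_min)
    if not lobe.any():
        raise ArcError(f"no arc: no band pixels above {height_min} um")
    vals = image[lobe]
    background = float(np.median(vals))
    peak = float(vals.max())
    if peak <= background:
        raise ArcError("no arc: supra-apical band has no structure")
    thr = background + intensity_frac * (peak - background)
    hot = supra & (image > thr)

    fit_sel = hot & (height > height_min)
    n_hot = int(fit_sel.sum())
    if n_hot < min_points:
        raise ArcError(
            f"no arc: only {n_hot} supra-threshold pixels above {height_min} um"
        )
    # collapse the PSF-thick trace to its intensity-weighted ridge, one
    # point per column, so the circle fit sees a thin arc rather than a
    # thick annulus (which is ill-conditioned over a partial sweep)
    lobe_w = np.where(fit_sel, image - thr, 0.0)
    band_w = np.where(supra, np.clip(image - thr, 0.0, None), 0.0)
    ridge: list[tuple[float, float]] = []
    strengths: list[float] = []
    for c in range(nx):
        if not lobe_w[:, c].any():
            continue
        j = int(np.argmax(lobe_w[:, c]))
        # centroid over a symmetric window about the per-column peak,
        # allowed to dip below the height cut: a one-sided window would
        # bias the ridge outward where the blurred trace straddles the cut
        win = np.abs(z - z[j]) <= 1.25
        w = band_w[:, c] * win
        wsum = float(w.sum())
        if wsum <= 0:
            continue
        ridge.append((x[c], float((w * height[:, c]).sum() / wsum)))
        strengths.append(wsum)
    if len(ridge) < 5:
        raise ArcError("no arc: too few ridge points for a circle fit")
    # drop weak columns: past the arc ends only the PSF tail pokes above
    # the height cut, and those centroids fall off the circle
    strengths_arr = np.asarray(strengths)
    ridge_arr = np.asarray(ridge)[strengths_arr >= 0.2 * strengths_arr.max()]
    if ridge_arr.shape[0] < 5:
        raise ArcError("no arc: too few ridge points for a circle fit")
    xc, hc, radius = fit_circle(ridge_arr)
    # trim high-leverage residual outliers (PSF tails past the arc ends)
    for _ in range(2):
        resid = np.abs(np.hypot(ridge_arr[:, 0] - xc, ridge_arr[:, 1] - hc) - radius)
        keep = resid <= max(0.25, 3.0 * float(np.median(resid)))
        if keep.all() or keep.sum() < 5:
            break
        ridge_arr = ridge_arr[keep]
        xc, hc, radius = fit_circle(ridge_arr)

    pts_all = np.column_stack([xx[hot], height[hot]])
    dist = np.hypot(pts_all[:, 0] - xc, pts_all[:, 1] - hc)
    ring = pts_all[np.abs(dist - radius) <= ring_tol]
    angle = arc_angular_extent(ring, (xc, hc), trim_percent=2.0)
    return StrokeArc(radius=radius, angle_deg=angle, center=(xc, hc),
                     n_points=n_hot)
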