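"""End-to-end analysis: one loaded sequence, every functional metric.

The central design point is simultaneity: airway surface liquid depth,
periciliary liquid depth, ciliary beat frequency and mucociliary transport
velocity (plus the optional stroke-phase decomposition, effective-stroke
arc geometry and gland flow) are all measured from the *same* image
sequence, loaded once.  Stages are isolated: a failure in one stage is
recorded in the report and the remaining stages still run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from . import dynamics, imgio, layers, transport
from .errors import MuoctError
from .imgio import Report

log = logging.getLogger("muoct")


@dataclass
class AnalysisConfig:
    """Inputs and parameter overrides for a full analysis run."""

    stack_path: str
    sidecar_path: str
    out_dir: Optional[str] = None

    # layer morphometry
    time_average_window: float = 2.0   # s
    n_depth_regions: int = 5
    layer_smoothing: int = 9
    layer_k_sigma: float = 3.0

    # beat frequency
    max_cbf_regions: int = 10
    cbf_band: tuple = (2.0, None)

    # transport
    mct_n_tracks: int = 10
    mct_max_step: Optional[float] = None

    # optional stroke-phase decomposition (enabled by giving a column)
    mmode_column: Optional[int] = None
    phase_height_threshold: float = 5.0
    phase_motion_eps: float = 0.3

    # optional effective-stroke arc fit
    fit_arc: bool = False
    arc_height_min: float = 5.0

    # optional gland flow: duct pixel box + en-face lumen image
    gland_box: Optional[tuple] = None            # (z0, z1, x0, x1) px
    gland_en_face_path: Optional[str] = None
    gland_en_face_sidecar: Optional[str] = None
    gland_lumen_threshold: float = 0.4

    seed: int = 0


def run_full_analysis(config: AnalysisConfig) -> Report:
    """Run every analysis stage on one sequence and consolidate a report.

    Returns the :class:`~muoct.imgio.Report`; if ``config.out_dir`` is
    set, also writes ``report.csv`` and ``analysis.log`` there.  Stage
    errors become ``note`` rows; independent stages are unaffected.
    """
    handlers = []
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fh = logging.FileHandler(out / "analysis.log", mode="w")
        fh.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        log.addHandler(fh)
        log.setLevel(logging.INFO)
        handlers.append(fh)
    try:
        return _run(config)
    finally:
        for h in handlers:
            log.removeHandler(h)
            h.close()


def _run(config: AnalysisConfig) -> Report:
    report = Report()
    seq = imgio.load_sequence(config.stack_path, config.sidecar_path)
    log.info(
        "loaded sequence: %d frames, %dx%d px, dt=%.4fs dx=%.3fum dz=%.3fum n=%.2f",
        seq.n_frames, seq.shape[1], seq.shape[2], seq.dt, seq.dx, seq.dz, seq.n_liquid,
    )

    # ---- layer morphometry ---------------------------------------------
    interfaces = None
    try:
        window = min(config.time_average_window, seq.duration)
        avg = layers.time_average(seq, window)
        interfaces = layers.detect_interfaces(
            avg, seq.dz, smoothing=config.layer_smoothing, k_sigma=config.layer_k_sigma
        )
        depths = layers.measure_depths(interfaces, seq.n_liquid, config.n_depth_regions)
        log.info("depth parameters: window=%.2fs regions=%d smoothing=%d k_sigma=%.1f",
                 window, config.n_depth_regions, config.layer_smoothing, config.layer_k_sigma)
        for r, (a, p) in enumerate(zip(depths.asl_values, depths.pcl_values)):
            report.add_value("asl_depth", r, a, "um")
            report.add_value("pcl_depth", r, p, "um")
        report.add_aggregate("asl_depth", depths.asl, "um")
        report.add_aggregate("pcl_depth", depths.pcl, "um")
    except (MuoctError, ValueError) as exc:
        log.warning("layer stage failed: %s", exc)
        report.add_note("asl_depth", f"stage failed: {exc}")

    # ---- ciliary beat frequency ----------------------------------------
    try:
        # restrict the region search to the ciliary (sub-mucus) band when
        # the layer stage resolved it; advected mucus content can be
        # periodic without being ciliary
        # the 1.5 um margin keeps the PSF-blurred tail of the bright moving
        # mucus band out of the ciliary search zone
        z_range = None
        if interfaces is not None and interfaces.valid.any():
            z_range = (
                float(np.nanmedian(interfaces.mucus_pcl)) + 1.5,
                float(np.nanmedian(interfaces.apical)),
            )
        cbf = dynamics.measure_cbf(
            seq, max_regions=config.max_cbf_regions, band=tuple(config.cbf_band),
            z_range=z_range,
        )
        log.info("cbf parameters: max_regions=%d band=%s", config.max_cbf_regions,
                 config.cbf_band)
        for i, pk in enumerate(cbf.peaks):
            report.add_value("cbf", i, pk.frequency, "Hz")
            if pk.aliased:
                report.add_note("cbf", f"region {i}: peak near Nyquist, possibly aliased")
        if cbf.aggregate is not None:
            report.add_aggregate("cbf", cbf.aggregate, "Hz")
        else:
            report.add_note("cbf", "no oscillatory region accepted")
    except (MuoctError, ValueError) as exc:
        log.warning("CBF stage failed: %s", exc)
        report.add_note("cbf", f"stage failed: {exc}")

    # ---- mucociliary transport -----------------------------------------
    try:
        if interfaces is None:
            raise MuoctError("mucus band unavailable (layer stage failed)")
        mct = transport.measure_mct(
            seq, interfaces, n_tracks=config.mct_n_tracks, max_step=config.mct_max_step
        )
        for tr, v in zip(mct.tracks, mct.velocities):
            report.add_value("mct_velocity", tr.track_id, v, "um/s")
        if mct.aggregate is not None:
            report.add_aggregate("mct_velocity", mct.aggregate, "um/s")
        else:
            report.add_note("mct_velocity", "no usable inclusion track")
    except (MuoctError, ValueError) as exc:
        log.warning("MCT stage failed: %s", exc)
        report.add_note("mct_velocity", f"stage failed: {exc}")

    # ---- optional stroke-phase decomposition ---------------------------
    if config.mmode_column is not None:
        try:
            if interfaces is None:
                raise MuoctError("apical surface unavailable (layer stage failed)")
            c = int(config.mmode_column)
            mmode = dynamics.extract_mmode(seq, c)
            seg = dynamics.segment_phases(
                mmode,
                apical_z_um=float(interfaces.apical[c]),
                height_threshold=config.phase_height_threshold,
                motion_eps=config.phase_motion_eps,
                top_z_um=float(interfaces.mucus_pcl[c]),
            )
            for lab, frac in seg.duty.items():
                report.add_value(f"duty_{lab}", c, frac, "fraction")
        except (MuoctError, ValueError) as exc:
            log.warning("phase stage failed: %s", exc)
            report.add_note("duty_effective", f"stage failed: {exc}")

    # ---- optional effective-stroke arc ---------------------------------
    if config.fit_arc:
        try:
            if interfaces is None:
                raise MuoctError("apical surface unavailable (layer stage failed)")
            avg = layers.time_average(seq, min(config.time_average_window, seq.duration))
            arc = dynamics.fit_stroke_arc(
                avg, interfaces.apical, seq.dx, seq.dz, seq.n_liquid,
                height_min=config.arc_height_min, top_z_um=interfaces.mucus_pcl,
            )
            report.add_value("stroke_arc_radius", 0, arc.radius, "um")
            report.add_value("stroke_arc_angle", 0, arc.angle_deg, "deg")
        except (MuoctError, ValueError) as exc:
            log.warning("arc stage failed: %s", exc)
            report.add_note("stroke_arc_radius", f"stage failed: {exc}")

    # ---- optional gland flow -------------------------------------------
    if config.gland_box is not None and config.gland_en_face_path is not None:
        try:
            vel = transport.measure_extrusion_velocity(seq, tuple(config.gland_box))
            en_face_seq = imgio.load_sequence(
                config.gland_en_face_path, config.gland_en_face_sidecar
            )
            area = transport.lumen_area(
                en_face_seq.frames[0], config.gland_lumen_threshold,
                dx=en_face_seq.dx, dy=en_face_seq.dz,
            )
            flow = transport.gland_flow(area, vel.mean)
            report.add_value("gland_lumen_area", 0, area, "um^2")
            report.add_value("gland_extrusion_velocity", 0, vel.mean, "um/s")
            report.add_value("gland_flow", 0, flow, "nL/min")
        except (MuoctError, ValueError) as exc:
            log.warning("gland stage failed: %s", exc)
            report.add_note("gland_flow", f"stage failed: {exc}")

    if config.out_dir:
        report.to_csv(Path(config.out_dir) / "report.csv")
    return report
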