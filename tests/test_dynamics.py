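"""Ciliary dynamics tests: CBF spectra, M-mode phases, arc geometry."""

import math

import numpy as np
import pytest

from muoct.dynamics import (
    MModeTrace,
    arc_angular_extent,
    extract_mmode,
    fit_circle,
    fit_stroke_arc,
    measure_cbf,
    oscillatory_mask,
    region_cbf,
    segment_phases,
)
from muoct.errors import ArcError, DynamicsError
from muoct.imgio import BScanSequence
from muoct.layers import detect_interfaces, time_average
from muoct.phantom import OpticsConfig, PhantomConfig, simulate_sequence


def _single_pixel_seq(series: np.ndarray, dt: float = 0.025) -> BScanSequence:
    return BScanSequence(series.reshape(-1, 1, 1).astype(np.float32),
                         dt=dt, dx=1.0, dz=0.5)


def _brute_force_peak_bin(series: np.ndarray) -> int:
    """Independent oracle: naive O(N^2) DFT magnitude scan, Hann-tapered."""
    y = series - series.mean()
    y = y * np.hanning(y.size)
    n = y.size
    best_bin, best_mag = 1, -1.0
    for k in range(1, n // 2):  # non-DC bins strictly below Nyquist
        re = sum(y[j] * math.cos(-2 * math.pi * k * j / n) for j in range(n))
        im = sum(y[j] * math.sin(-2 * math.pi * k * j / n) for j in range(n))
        mag = re * re + im * im
        if mag > best_mag:
            best_bin, best_mag = k, mag
    return best_bin


ONE_PIXEL = np.array([[0, 0]])


class TestRegionCbf:
    def test_pure_cosine_recovered_to_hundredth_of_hz(self):
        t = np.arange(160) * 0.025
        seq = _single_pixel_seq(0.5 + 0.2 * np.cos(2 * np.pi * 10.0 * t))
        pk = region_cbf(seq, ONE_PIXEL)
        assert pk is not None
        assert pk.frequency == pytest.approx(10.0, abs=0.05)
        assert pk.bin_index == 40  # 10 Hz at df = 0.25 Hz

    def test_peak_bin_matches_brute_force_dft_scan(self):
        rng = np.random.default_rng(123)
        for _ in range(25):
            f = rng.uniform(1.0, 18.0)
            t = np.arange(96) * 0.025
            series = (0.4 + 0.3 * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
                      + 0.05 * rng.standard_normal(96))
            seq = _single_pixel_seq(series)
            pk = region_cbf(seq, ONE_PIXEL)
            assert pk is not None
            assert pk.bin_index == _brute_force_peak_bin(series)

    def test_constant_region_has_no_peak(self):
        seq = _single_pixel_seq(np.full(160, 0.4))
        with pytest.warns(UserWarning):
            assert region_cbf(seq, ONE_PIXEL) is None

    def test_near_nyquist_peak_flagged_as_aliased(self):
        t = np.arange(160) * 0.025
        seq = _single_pixel_seq(0.5 + 0.2 * np.cos(2 * np.pi * 15.0 * t))
        with pytest.warns(UserWarning, match="alias"):
            pk = region_cbf(seq, ONE_PIXEL)
        assert pk is not None and pk.aliased


class TestOscillatoryMask:
    def test_cilia_regions_lie_in_the_pcl_band(self, small_optics):
        cfg = PhantomConfig(optics=small_optics, duration=4.0, beat_frequency=10.0,
                            mucus_velocity=0.0, n_inclusions=0, seed=6)
        seq, truth = simulate_sequence(cfg)
        mask, regions = oscillatory_mask(seq)
        assert regions
        z_lo = truth.mucus_pcl[0] / seq.dz - 1
        z_hi = truth.apical[0] / seq.dz + 1
        pix = np.vstack([r.pixels for r in regions])
        in_band = (pix[:, 0] >= z_lo) & (pix[:, 0] <= z_hi)
        assert in_band.mean() > 0.8

    def test_static_phantom_yields_no_regions(self, small_optics):
        """No beating anywhere: speckle alone must not masquerade as cilia."""
        cfg = PhantomConfig(optics=small_optics, duration=2.0, cilia_spacing=None,
                            n_inclusions=0, mucus_velocity=0.0, seed=2)
        seq, _ = simulate_sequence(cfg)
        with pytest.warns(UserWarning, match="no oscillatory region"):
            _, regions = oscillatory_mask(seq, band=(2.0, None))
        assert not regions

    def test_z_range_restricts_the_search(self, std_phantom):
        _, seq, truth = std_phantom
        zr = (float(truth.mucus_pcl[0]), float(truth.apical[0]))
        _, regions = oscillatory_mask(seq, z_range=zr)
        pix = np.vstack([r.pixels for r in regions])
        z_um = (pix[:, 0] + 0.5) * seq.dz
        assert z_um.min() >= zr[0] and z_um.max() < zr[1]


class TestMeasureCbf:
    def test_uniform_phantom_recovers_frequency(self, std_phantom):
        _, seq, truth = std_phantom
        zr = (float(truth.mucus_pcl[0]), float(truth.apical[0]))
        res = measure_cbf(seq, z_range=zr)
        assert res.aggregate is not None
        assert res.aggregate.mean == pytest.approx(truth.beat_frequency, abs=0.25)
        assert res.aggregate.n <= 10

    def test_max_regions_one_equals_single_peak(self, std_phantom):
        _, seq, truth = std_phantom
        zr = (float(truth.mucus_pcl[0]), float(truth.apical[0]))
        res = measure_cbf(seq, max_regions=1, z_range=zr)
        assert len(res.peaks) == 1
        assert res.aggregate.mean == res.peaks[0].frequency

    def test_mixed_frequency_patches_stay_separate(self, small_optics):
        """8 and 12 Hz patches report near 8 and 12, never their mean."""
        seqs = []
        for f, seed in ((8.0, 1), (12.0, 2)):
            cfg = PhantomConfig(optics=small_optics, duration=4.0, beat_frequency=f,
                                mucus_velocity=0.0, n_inclusions=0, seed=seed)
            seqs.append(simulate_sequence(cfg)[0])
        frames = np.concatenate([s.frames for s in seqs], axis=2)
        seq = BScanSequence(frames, dt=seqs[0].dt, dx=seqs[0].dx, dz=seqs[0].dz,
                            n_liquid=seqs[0].n_liquid)
        res = measure_cbf(seq)
        freqs = res.frequencies
        assert np.all((np.abs(freqs - 8.0) < 0.5) | (np.abs(freqs - 12.0) < 0.5))
        assert np.any(np.abs(freqs - 8.0) < 0.5) and np.any(np.abs(freqs - 12.0) < 0.5)


class TestMMode:
    def test_static_slice_is_constant_in_time(self, quiet_phantom):
        _, seq, _ = quiet_phantom
        mm = extract_mmode(seq, 50)
        assert np.allclose(mm.data, mm.data[:, :1], atol=1e-7)

    def test_out_of_range_column_rejected(self, quiet_phantom):
        _, seq, _ = quiet_phantom
        with pytest.raises(ValueError):
            extract_mmode(seq, seq.frames.shape[2])

    def test_width_one_sequence_is_its_own_mmode(self):
        frames = np.random.default_rng(0).random((10, 8, 1)).astype(np.float32)
        seq = BScanSequence(frames, dt=0.025, dx=1.0, dz=0.5)
        mm = extract_mmode(seq, 0)
        np.testing.assert_allclose(mm.data, frames[:, :, 0].T)

    def test_beating_column_carries_the_beat_frequency(self, std_phantom):
        """Tip-band pixels of an M-mode column oscillate at the beat rate."""
        _, seq, truth = std_phantom
        mm = extract_mmode(seq, 50)
        band_rows = np.nonzero(
            (mm.z_um > truth.mucus_pcl[0]) & (mm.z_um < truth.apical[0])
        )[0]
        pixels = np.column_stack([band_rows, np.full(band_rows.size, 50)])
        pk = region_cbf(seq, pixels)
        assert pk is not None
        assert pk.frequency == pytest.approx(truth.beat_frequency, abs=0.25)


def _mmode_from_heights(h_um, apical_z=20.0, dz=0.5, n_liquid=1.0, dt=0.005):
    """Synthesise an M-mode with a bright 1-px tip at given physical heights."""
    T = len(h_um)
    nz = int(round(apical_z / dz)) + 10
    data = np.zeros((nz, T))
    for t, h in enumerate(h_um):
        z = apical_z - n_liquid * h
        data[int(round(z / dz - 0.5)), t] = 1.0
    return MModeTrace(data=data, x=0, dt=dt, dz=dz, n_liquid=n_liquid)


class TestSegmentPhases:
    def test_square_wave_duty_recovered(self):
        h = np.tile(np.r_[np.full(10, 7.0), np.full(10, 4.0)], 8)
        mm = _mmode_from_heights(h)
        seg = segment_phases(mm, apical_z_um=20.0, motion_eps=0.5, edge_margin_um=0.5)
        assert seg.duty["effective"] == pytest.approx(0.5, abs=2 / 20)

    def test_constant_low_height_is_all_rest(self):
        mm = _mmode_from_heights(np.full(60, 3.0))
        seg = segment_phases(mm, apical_z_um=20.0, edge_margin_um=0.5)
        assert seg.duty["rest"] == 1.0

    def test_labels_exactly_consistent_with_threshold_rule(self):
        rng = np.random.default_rng(5)
        h = 3.0 + 4.5 * rng.random(80)
        mm = _mmode_from_heights(h)
        seg = segment_phases(mm, apical_z_um=20.0, motion_eps=0.3, edge_margin_um=0.5)
        np.testing.assert_array_equal(seg.labels == "effective", seg.height > 5.0)

    def test_no_signal_raises(self):
        mm = MModeTrace(data=np.zeros((40, 50)), x=0, dt=0.005, dz=0.5, n_liquid=1.0)
        with pytest.raises(DynamicsError):
            segment_phases(mm, apical_z_um=15.0)

    def test_phantom_duty_recovered_noise_free(self):
        """Dense in-phase cilia; 90 deg arc keeps the true phases separable
        by the 5-um threshold rule."""
        opt = OpticsConfig(frame_rate=200.0, n_lines=40, field_x=40.0, field_z=26.0, dz=0.5)
        cfg = PhantomConfig(
            optics=opt, duration=4.0, asl_depth=11.0, pcl_depth=8.5,
            effective_arc_deg=90.0, recovery_height_range=(3.0, 4.95),
            beat_frequency=2.5, duty=(0.4, 0.4, 0.2), cilia_spacing=1.5,
            metachronal_wavelength=None, phase_jitter=0.0,
            mucus_velocity=0.0, n_inclusions=0, speckle_contrast=0.0,
            noise_floor=0.0, render_oversample=2, seed=3,
        )
        seq, truth = simulate_sequence(cfg)
        ifs = detect_interfaces(time_average(seq, 1.0), seq.dz)
        c = 20
        seg = segment_phases(
            extract_mmode(seq, c), apical_z_um=float(ifs.apical[c]),
            motion_eps=0.05, top_z_um=float(ifs.mucus_pcl[c]),
        )
        for lab, want in zip(("effective", "recovery", "rest"), cfg.duty):
            assert seg.duty[lab] == pytest.approx(want, abs=0.05)


class TestArcGeometry:
    def test_exact_semicircle_to_numerical_precision(self):
        th = np.linspace(-np.pi / 2, np.pi / 2, 91)
        pts = np.column_stack([5.0 * np.sin(th) + 2.0, 5.0 * np.cos(th) - 1.0])
        xc, yc, r = fit_circle(pts)
        assert (xc, yc, r) == pytest.approx((2.0, -1.0, 5.0), abs=1e-9)
        assert arc_angular_extent(pts, (xc, yc)) == pytest.approx(180.0, abs=1e-9)

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.arange(10.0), 2.0 * np.arange(10.0)])
        with pytest.raises(ArcError):
            fit_circle(pts)

    def test_phantom_arc_radius_and_angle(self):
        opt = OpticsConfig(frame_rate=40.0, n_lines=64, field_x=60.0, field_z=30.0, dz=0.5)
        cfg = PhantomConfig(
            optics=opt, duration=4.0, asl_depth=11.0, pcl_depth=9.0,
            cilia_spacing=60.0, metachronal_wavelength=None, phase_jitter=0.0,
            mucus_velocity=0.0, n_inclusions=0, speckle_contrast=0.0,
            noise_floor=0.0, seed=5,
        )
        seq, _ = simulate_sequence(cfg)
        avg = time_average(seq, 4.0)
        ifs = detect_interfaces(avg, seq.dz)
        arc = fit_stroke_arc(avg, ifs.apical, seq.dx, seq.dz, seq.n_liquid,
                             top_z_um=ifs.mucus_pcl)
        assert arc.radius == pytest.approx(7.0, abs=0.5)
        assert arc.angle_deg == pytest.approx(110.0, abs=10.0)

    def test_featureless_band_has_no_arc(self, quiet_phantom):
        _, seq, _ = quiet_phantom
        avg = time_average(seq, 0.5)
        ifs = detect_interfaces(avg, seq.dz)
        with pytest.raises(ArcError):
            fit_stroke_arc(avg, ifs.apical, seq.dx, seq.dz, seq.n_liquid,
                           top_z_um=ifs.mucus_pcl)
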