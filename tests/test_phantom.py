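"""Simulator unit tests: kinematics, scene assembly, rendering, truth."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from muoct.errors import ConfigError
from muoct.phantom import (
    GlandConfig,
    OpticsConfig,
    PhantomConfig,
    Scene,
    build_scene,
    cilium_tip_position,
    config_from_yaml,
    config_to_yaml,
    render_frame,
    simulate_sequence,
)


def _kinematics_config(**overrides) -> PhantomConfig:
    base = dict(
        optics=OpticsConfig(frame_rate=200.0, n_lines=64, field_x=60.0, field_z=30.0, dz=0.5),
        beat_frequency=10.0,
        duty=(0.4, 0.4, 0.2),
        metachronal_wavelength=None,
        phase_jitter=0.0,
        pcl_depth=7.5,
        asl_depth=10.5,
    )
    base.update(overrides)
    return PhantomConfig(**base)


class TestCiliumKinematics:
    @given(t=st.floats(0.0, 5.0, allow_nan=False))
    def test_trajectory_is_periodic(self, t):
        cfg = _kinematics_config()
        a = cilium_tip_position(cfg, 2, t)
        b = cilium_tip_position(cfg, 2, t + cfg.beat_period)
        assert a[2] == b[2]
        assert a[0] == pytest.approx(b[0], abs=1e-9)
        assert a[1] == pytest.approx(b[1], abs=1e-9)

    def test_effective_arc_geometry(self):
        """Tip reaches full length at the arc apex and L*cos(arc/2) at the ends."""
        cfg = _kinematics_config(cilium_length=7.0, effective_arc_deg=110.0)
        base_x = cfg.cilium_bases()[1]
        # exact mid-stroke time: phi = 0.2 of a 0.4-duty stroke at 10 Hz
        x, h, lab = cilium_tip_position(cfg, 1, 0.02)
        assert lab == "effective"
        assert h == pytest.approx(7.0, abs=1e-9)
        assert x == pytest.approx(base_x, abs=1e-9)
        x0, h0, lab0 = cilium_tip_position(cfg, 1, 0.0)
        assert lab0 == "effective"
        assert h0 == pytest.approx(7.0 * math.cos(math.radians(55.0)), abs=1e-9)

    def test_duty_schedule_matches_brute_force_sampling(self):
        """Labels sampled at 1 kHz over one period follow the duty split."""
        cfg = _kinematics_config()
        labels = [cilium_tip_position(cfg, 0, k / 1000.0)[2] for k in range(100)]
        counts = {lab: labels.count(lab) for lab in ("effective", "recovery", "rest")}
        assert counts == {"effective": 40, "recovery": 40, "rest": 20}

    def test_recovery_moves_backward_at_low_height(self):
        cfg = _kinematics_config()
        xs, hs = [], []
        for t in np.linspace(0.041, 0.079, 9):
            x, h, lab = cilium_tip_position(cfg, 0, float(t))
            assert lab == "recovery"
            xs.append(x)
            hs.append(h)
        assert all(np.diff(xs) < 0)  # opposite to transport
        lo, hi = cfg.recovery_height_range
        assert min(hs) >= lo - 1e-9 and max(hs) <= hi + 1e-9

    def test_rest_is_stationary_at_pre_effective_position(self):
        cfg = _kinematics_config()
        p1 = cilium_tip_position(cfg, 0, 0.085)
        p2 = cilium_tip_position(cfg, 0, 0.095)
        assert p1 == p2
        start = cilium_tip_position(cfg, 0, 0.0)
        assert p1[0] == pytest.approx(start[0]) and p1[1] == pytest.approx(start[1])

    def test_invalid_inputs_rejected(self):
        cfg = _kinematics_config()
        with pytest.raises(ConfigError):
            cilium_tip_position(cfg, 0, -0.1)
        with pytest.raises(ConfigError):
            _kinematics_config(beat_frequency=0.0)
        with pytest.raises(ConfigError):
            _kinematics_config(beat_frequency=-3.0)


class TestConfigValidation:
    def test_layer_ordering_enforced(self):
        with pytest.raises(ConfigError):
            PhantomConfig(asl_depth=5.0, pcl_depth=6.0)

    def test_duty_must_sum_to_one(self):
        with pytest.raises(ConfigError):
            PhantomConfig(duty=(0.5, 0.4, 0.2))

    def test_nyquist_guard_on_beat_frequency(self):
        opt = OpticsConfig(frame_rate=40.0)
        with pytest.raises(ConfigError):
            PhantomConfig(optics=opt, beat_frequency=25.0)
        cfg = PhantomConfig(optics=opt, beat_frequency=25.0, allow_aliasing=True)
        assert cfg.beat_frequency == 25.0

    def test_psf_sampling_guard(self):
        with pytest.raises(ConfigError):
            OpticsConfig(dz=1.0, axial_fwhm=1.3)

    def test_yaml_roundtrip(self, tmp_path):
        cfg = PhantomConfig(
            optics=OpticsConfig(frame_rate=32.0, n_lines=64, field_x=60.0, field_z=30.0),
            gland=GlandConfig(lumen_area=250.0, extrusion_velocity=100.0),
            seed=9,
        )
        path = tmp_path / "phantom.yaml"
        config_to_yaml(cfg, path)
        assert config_from_yaml(path) == cfg


class TestSceneAssembly:
    def test_zero_velocity_scene_is_static(self):
        cfg = _kinematics_config(mucus_velocity=0.0, cilia_spacing=None, n_inclusions=4)
        s0 = build_scene(cfg, 0.0)
        s1 = build_scene(cfg, 1.0)
        np.testing.assert_array_equal(s0.scatterers, s1.scatterers)

    def test_advection_shifts_by_exactly_v_dt(self):
        cfg = _kinematics_config(
            mucus_velocity=10.0, cilia_spacing=None, n_inclusions=5,
            mucus_scatterer_density=0.0,
        )
        dt = 0.05
        x0 = build_scene(cfg, 0.0).scatterers[:, 0]
        x1 = build_scene(cfg, dt).scatterers[:, 0]
        shift = np.mod(x1 - x0, cfg.optics.field_x)
        np.testing.assert_allclose(shift, 10.0 * dt, atol=1e-9)

    def test_inclusion_count_is_conserved_under_wrap(self):
        cfg = _kinematics_config(mucus_velocity=50.0, cilia_spacing=None, n_inclusions=7)
        for t in (0.0, 0.7, 1.3, 2.9):
            sc = build_scene(cfg, t).scatterers
            n_bright = int(np.sum(sc[:, 2] == cfg.inclusion_reflectivity))
            assert n_bright == 7


def _bare_scene(optics, scatterers) -> Scene:
    """A scene with no layered background: isolates scatterer rendering."""
    return Scene(
        scatterers=np.asarray(scatterers, dtype=float),
        mucus_bottom=np.zeros(optics.nx),
        apical_depth=1e6,  # push every layer edge far out of the frame
        air_gap=4.0,
        mucus_level=0.0,
        pcl_level=0.0,
        epi_level=0.0,
        speckle_contrast=0.0,
        noise_floor=0.0,
        n_inclusion_scatterers=0,
    )


class TestRendering:
    def test_optical_path_stretching(self):
        """A scatterer 9.01 um below the interface renders at 11.98 um (n = 1.33)."""
        opt = OpticsConfig(frame_rate=40.0, n_lines=40, field_x=40.0, field_z=30.0, dz=0.5)
        frame = render_frame(_bare_scene(opt, [[20.0, 9.01, 0.6]]), opt)
        z_um = (np.arange(opt.nz) + 0.5) * opt.dz
        profile = frame[:, 20]
        centroid = float((profile * z_um).sum() / profile.sum())
        assert centroid == pytest.approx(4.0 + 1.33 * 9.01, abs=opt.dz / 4)

    def test_unit_index_renders_physical_depth(self):
        opt = OpticsConfig(frame_rate=40.0, n_lines=40, field_x=40.0, field_z=30.0,
                           dz=0.5, n_liquid=1.0)
        frame = render_frame(_bare_scene(opt, [[20.0, 9.01, 0.6]]), opt)
        z_um = (np.arange(opt.nz) + 0.5) * opt.dz
        profile = frame[:, 20]
        centroid = float((profile * z_um).sum() / profile.sum())
        assert centroid == pytest.approx(4.0 + 9.01, abs=opt.dz / 4)

    def test_empty_noise_free_scene_is_black(self):
        opt = OpticsConfig(frame_rate=40.0, n_lines=40, field_x=40.0, field_z=30.0, dz=0.5)
        frame = render_frame(_bare_scene(opt, np.empty((0, 3))), opt)
        assert np.all(frame == 0.0)

    def test_speckle_requires_rng(self):
        opt = OpticsConfig(frame_rate=40.0, n_lines=40, field_x=40.0, field_z=30.0, dz=0.5)
        scene = _bare_scene(opt, np.empty((0, 3)))
        scene.speckle_contrast = 0.5
        with pytest.raises(ConfigError):
            render_frame(scene, opt)


class TestSimulateSequence:
    def test_deterministic_for_fixed_seed(self, small_optics):
        cfg = PhantomConfig(optics=small_optics, duration=0.5, seed=42)
        seq_a, truth_a = simulate_sequence(cfg)
        seq_b, truth_b = simulate_sequence(cfg)
        assert seq_a.frames.tobytes() == seq_b.frames.tobytes()
        np.testing.assert_array_equal(truth_a.phase_labels, truth_b.phase_labels)

    def test_frame_count_rounds_down(self, small_optics):
        cfg = PhantomConfig(optics=small_optics, duration=4.0, seed=0)
        seq, _ = simulate_sequence(cfg)
        assert seq.n_frames == 160

    def test_short_duration_warns(self, small_optics):
        cfg = PhantomConfig(optics=small_optics, duration=0.1, beat_frequency=12.0, seed=0)
        with pytest.warns(UserWarning, match="beat periods"):
            simulate_sequence(cfg)

    def test_ground_truth_interfaces_follow_config(self, quiet_phantom):
        cfg, _, truth = quiet_phantom
        n = cfg.optics.n_liquid
        assert truth.air_mucus[0] == pytest.approx(cfg.air_gap)
        assert truth.mucus_pcl[0] == pytest.approx(cfg.air_gap + n * (9.0 - 7.0))
        assert truth.apical[0] == pytest.approx(cfg.air_gap + n * 9.0)

    def test_ground_truth_json_roundtrip(self, tmp_path, quiet_phantom):
        from muoct.phantom import GroundTruth

        _, _, truth = quiet_phantom
        p = tmp_path / "truth.json"
        truth.to_json(p)
        back = GroundTruth.from_json(p)
        assert back.asl_depth == truth.asl_depth
        np.testing.assert_allclose(back.apical, truth.apical)


class TestGlandTruth:
    def test_flow_formula_is_exact(self):
        g = GlandConfig(lumen_area=250.0, extrusion_velocity=100.0)
        assert g.flow_nl_min == pytest.approx(1.5, abs=1e-12)

    def test_flow_in_simulated_truth(self, small_optics):
        opt = OpticsConfig(frame_rate=40.0, n_lines=100, field_x=100.0, field_z=45.0, dz=0.5)
        cfg = PhantomConfig(
            optics=opt, duration=0.2,
            gland=GlandConfig(lumen_area=250.0, extrusion_velocity=100.0), seed=0,
        )
        _, truth = simulate_sequence(cfg)
        assert truth.gland_flow == pytest.approx(250.0 * 100.0 * 60.0 / 1e6, abs=1e-12)
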