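"""Transport operations and full-run physics of the Monte Carlo engine."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemophoton import _kernels
from hemophoton.engine import (
    EngineConfig,
    PhotonPacket,
    absorb,
    detect_boundary_crossing,
    hg_cosines,
    hg_scatter,
    launch_photon,
    move_photon,
    reflect_or_refract,
    reflectance,
    roulette,
    run,
    sample_step,
)
from hemophoton._kernels import C_MM_NS
from hemophoton.phantoms import MUSCLE, VoxelGrid, build_slab
from hemophoton.tissue_optics import BloodState, OpticalProperties

MATCHED_ABSORBER = {"muscle": OpticalProperties(1.0, 0.0, 0.0, 1.0)}


def _packet(direction=(0, 0, 1), position=(0, 0, 0)):
    return PhotonPacket(position=np.array(position, float), direction=direction)


class TestStepSampling:
    def test_closed_form(self):
        assert sample_step(2.0, np.exp(-1.0)) == pytest.approx(0.5)

    def test_limit_xi_to_one(self):
        assert sample_step(2.0, 1.0) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sample_step(0.0, 0.5)
        with pytest.raises(ValueError):
            sample_step(1.0, 0.0)

    def test_mean_free_path(self):
        # E[step] = 1/mu_t; Monte Carlo oracle on the engine's own stream
        steps = _kernels.sample_steps(1.0, 10**6, 123)
        assert steps.mean() == pytest.approx(1.0, abs=0.01)


class TestMove:
    def test_axial_move(self):
        p = move_photon(_packet(), 1.0, n_medium=1.0)
        assert np.allclose(p.position, [0, 0, 1])
        assert p.path_length == pytest.approx(1.0)

    def test_time_uses_medium_speed(self):
        p = move_photon(_packet(), 1.0, n_medium=1.5)
        assert p.elapsed_time == pytest.approx(1.5 / C_MM_NS)

    def test_two_half_steps_equal_one(self):
        a = move_photon(move_photon(_packet(), 0.5, 1.4), 0.5, 1.4)
        b = move_photon(_packet(), 1.0, 1.4)
        assert np.allclose(a.position, b.position)
        assert a.elapsed_time == pytest.approx(b.elapsed_time, abs=1e-12)

    def test_time_accumulation_matches_sum(self, rng):
        # elapsed_time == sum(step_i n_i / c) to 1e-12 ns per interaction
        p = _packet()
        steps = rng.uniform(0.01, 1.0, size=1000)
        ns = rng.uniform(1.0, 1.6, size=1000)
        for s, n in zip(steps, ns):
            move_photon(p, s, n)
        assert p.elapsed_time == pytest.approx(np.sum(steps * ns) / C_MM_NS, abs=1e-9)


class TestBoundaryDetection:
    @pytest.fixture()
    def two_layer(self):
        return build_slab([("fat", 1.0), ("muscle", 1.0)], lateral_mm=5.0, pitch=0.5)

    def test_axial_crossing_at_interface(self, two_layer):
        # fat occupies z in [1, 2); muscle [2, 3): interface plane z = 2
        rec = detect_boundary_crossing(two_layer, (2.4, 2.4, 1.2), (0, 0, 1), 5.0)
        assert rec is not None
        assert rec["point"][2] == pytest.approx(2.0)
        assert np.allclose(rec["normal"], [0, 0, -1])

    def test_oblique_crossing_matches_ray_plane_solution(self, two_layer):
        u = np.array([1.0, 0.0, 1.0]) / np.sqrt(2)
        start = np.array([1.2, 2.4, 1.3])
        rec = detect_boundary_crossing(two_layer, start, u, 5.0)
        d_analytic = (2.0 - start[2]) / u[2]
        assert rec["distance"] == pytest.approx(d_analytic)
        assert np.allclose(rec["point"], start + u * d_analytic)

    def test_no_material_change_returns_none(self, two_layer):
        assert detect_boundary_crossing(two_layer, (2.4, 2.4, 1.2), (0, 0, 1), 0.2) is None


class TestReflectance:
    def test_matched_media_at_normal_incidence(self):
        for model in ("as_printed", "schlick_direct", "fresnel_exact"):
            assert reflectance(0.0, 1.4, 1.4, model) == pytest.approx(0.0)

    def test_r0_value(self):
        r0 = ((1.37 - 1.44) / (1.37 + 1.44)) ** 2
        assert r0 == pytest.approx(6.205e-4, rel=1e-3)
        assert reflectance(0.0, 1.37, 1.44, "schlick_direct") == pytest.approx(r0)
        assert reflectance(0.0, 1.37, 1.44, "as_printed") == pytest.approx(r0**2)

    def test_grazing_limit(self):
        for model in ("as_printed", "schlick_direct", "fresnel_exact"):
            assert reflectance(np.pi / 2, 1.0, 1.4, model) == pytest.approx(1.0, abs=1e-9)

    def test_total_internal_reflection(self):
        theta = np.arcsin(1.0 / 1.5) + 0.05
        for model in ("as_printed", "schlick_direct", "fresnel_exact"):
            assert reflectance(theta, 1.5, 1.0, model) == 1.0

    def test_fresnel_normal_incidence_exact(self):
        expected = ((1.0 - 1.5) / (1.0 + 1.5)) ** 2
        assert reflectance(0.0, 1.0, 1.5, "fresnel_exact") == pytest.approx(expected)

    def test_invalid_angle_rejected(self):
        with pytest.raises(ValueError):
            reflectance(2.0, 1.0, 1.4)


class TestReflectRefract:
    def test_normal_incidence_transmission_unchanged(self):
        p = reflect_or_refract(_packet((0, 0, 1)), (0, 0, -1), 1.0, 1.5, R=0.0, xi=0.5)
        assert np.allclose(p.direction, [0, 0, 1])

    def test_specular_reflection(self):
        p = reflect_or_refract(_packet((0, 0, 1)), (0, 0, -1), 1.0, 1.5, R=1.0, xi=0.0)
        assert np.allclose(p.direction, [0, 0, -1])

    def test_snell_angle(self):
        theta_i = np.deg2rad(30)
        u = (np.sin(theta_i), 0.0, np.cos(theta_i))
        p = reflect_or_refract(_packet(u), (0, 0, -1), 1.0, 1.5, R=0.0, xi=0.5)
        theta_t = np.arcsin(np.sin(theta_i) / 1.5)
        assert np.arccos(p.direction[2]) == pytest.approx(theta_t)


class TestAbsorbScatterRoulette:
    def test_pure_absorber_kills_in_one_interaction(self):
        p = _packet()
        dw = absorb(p, 1.0, 1.0)
        assert dw == pytest.approx(1.0)
        assert p.weight == pytest.approx(0.0)

    def test_no_absorption(self):
        p = _packet()
        assert absorb(p, 0.0, 2.0) == 0.0
        assert p.weight == 1.0

    def test_albedo_arithmetic(self):
        p = _packet()
        assert absorb(p, 0.1, 1.0) == pytest.approx(0.1)

    def test_hg_isotropic_median(self):
        assert hg_cosines(0.0, 0.5) == pytest.approx(0.0)

    @pytest.mark.parametrize("g", [0.0, 0.5, 0.75, 0.92, 0.995])
    def test_hg_mean_cosine_equals_g(self, g):
        cos = _kernels.sample_hg_cosines(g, 10**6, 77)
        se = cos.std() / 1000.0
        assert abs(cos.mean() - g) < 3.0 * max(se, 1e-9)

    def test_scatter_preserves_unit_norm(self, rng):
        p = _packet((0.3, -0.4, 0.866))
        for _ in range(2000):
            hg_scatter(p, 0.9, rng.random(), rng.random())
            assert np.linalg.norm(p.direction) == pytest.approx(1.0, abs=1e-9)

    def test_roulette_branches(self):
        p = _packet()
        p.weight = 5e-4
        roulette(p, xi=0.05, cutoff=1e-3, rc=10.0)
        assert p.weight == pytest.approx(5e-3)
        p.weight = 5e-4
        roulette(p, xi=0.5, cutoff=1e-3, rc=10.0)
        assert p.weight == 0.0 and not p.alive

    def test_roulette_is_unbiased(self, rng):
        # E[post-weight] = pre-weight: unbiasedness oracle
        pre = 5e-4
        post = np.where(rng.random(10**6) <= 0.1, 10.0 * pre, 0.0)
        assert post.mean() == pytest.approx(pre, rel=5e-3)


class TestLaunch:
    def test_pencil_source(self):
        g = build_slab([("muscle", 1.0)], lateral_mm=2.0, pitch=0.5)
        p = launch_photon((1.0, 1.0, 1.2), (0, 0, 2.0), g)
        assert p.weight == 1.0
        assert np.allclose(p.direction, [0, 0, 1])
        assert p.material == MUSCLE

    def test_zero_direction_rejected(self):
        with pytest.raises(ValueError):
            launch_photon((0, 0, 0), (0, 0, 0))

    def test_launch_outside_grid_is_out(self):
        g = build_slab([("muscle", 1.0)], lateral_mm=2.0, pitch=0.5)
        p = launch_photon((-5.0, 0.0, 0.0), (0, 0, 1), g)
        assert p.out and not p.alive


class TestFullRun:
    def _slab_run(self, n_photons=100_000, seed=3, **cfg_kwargs):
        grid = build_slab([("muscle", 1.0)], lateral_mm=40.0, pitch=0.5)
        cfg = EngineConfig(n_photons=n_photons, seed=seed, max_time_ns=5.0, **cfg_kwargs)
        return grid, run(
            grid, BloodState(), 525.0, (10.0, 10.0, 0.5), (0, 0, 1), cfg,
            material_overrides=MATCHED_ABSORBER,
        )

    def test_ballistic_transmission_beer_lambert(self):
        # pure absorber, mu_a = 1/mm, d = 1 mm, matched n: T = e^-1
        grid, res = self._slab_run()
        nz = grid.shape[2]
        transmitted = res.exit_weight[:, :, nz // 2:].sum() / res.launched
        expected = np.exp(-1.0)
        se = np.sqrt(expected * (1 - expected) / res.launched)
        assert abs(transmitted - expected) < 3.0 * se

    def test_energy_conservation_exact(self):
        _, res = self._slab_run()
        assert abs(res.energy_balance()) < 1e-6 * res.launched

    def test_transparent_medium_all_weight_exits(self):
        grid = build_slab([("muscle", 1.0)], lateral_mm=10.0, pitch=0.5)
        cfg = EngineConfig(n_photons=5000, seed=1, max_time_ns=5.0)
        res = run(
            grid, BloodState(), 525.0, (5.0, 5.0, 0.5), (0, 0, 1), cfg,
            material_overrides={"muscle": OpticalProperties(0.0, 0.0, 0.0, 1.0)},
        )
        assert res.total_absorbed == 0.0
        assert res.total_exited == pytest.approx(res.launched)

    def test_matched_indices_no_specular_loss_at_normal_incidence(self):
        # R = 0 exactly at normal incidence for every model when n1 = n2
        grid, res = self._slab_run(n_photons=20_000)
        nz = grid.shape[2]
        backscatter = res.exit_weight[:, :, : nz // 2].sum()
        assert backscatter == 0.0  # pure absorber cannot turn photons around

    def test_same_seed_bit_identical(self):
        _, a = self._slab_run(n_photons=5000, seed=11)
        _, b = self._slab_run(n_photons=5000, seed=11)
        assert np.array_equal(a.exit_weight, b.exit_weight)
        assert np.array_equal(a.absorbed_weight, b.absorbed_weight)
        assert a.totals == b.totals

    def test_different_seed_differs(self):
        _, a = self._slab_run(n_photons=5000, seed=11)
        _, b = self._slab_run(n_photons=5000, seed=12)
        assert not np.array_equal(a.exit_weight, b.exit_weight)

    @pytest.mark.parametrize("rule", ["resample", "carry"])
    def test_step_rules_both_conserve_energy(self, rule, small_digit):
        grid, region = small_digit
        cfg = EngineConfig(n_photons=5000, seed=5, max_time_ns=2.0, step_rule=rule)
        res = run(
            grid, BloodState(), 615.0,
            (grid.shape[0] * 0.25, grid.shape[1] * 0.25, 0.75), (0, 0, 1),
            cfg, region,
        )
        assert abs(res.energy_balance()) < 1e-6 * res.launched
        assert res.total_exited > 0

    def test_missing_region_for_composite_grid_rejected(self, small_digit):
        grid, _ = small_digit
        with pytest.raises(ValueError):
            run(grid, BloodState(), 525.0, (0, 0, 0), (0, 0, 1), EngineConfig(n_photons=10))

    def test_detection_result_hdf5_roundtrip(self, tmp_path):
        _, res = self._slab_run(n_photons=2000)
        path = tmp_path / "result.h5"
        res.save(path)
        back = type(res).load(path)
        assert np.array_equal(back.exit_weight, res.exit_weight)
        assert back.totals == pytest.approx(res.totals)
        assert back.config.n_photons == res.config.n_photons


class TestConfigValidation:
    def test_invalid_cutoff(self):
        with pytest.raises(ValueError):
            EngineConfig(roulette_cutoff=1.5)

    def test_invalid_model(self):
        with pytest.raises(ValueError):
            EngineConfig(reflectance_model="mystery")

    def test_time_bins(self):
        cfg = EngineConfig(max_time_ns=1.0, time_bin_ns=0.01)
        assert cfg.n_time_bins == 100


@settings(derandomize=True, max_examples=60)
@given(
    ux=st.floats(-1, 1), uy=st.floats(-1, 1), uz=st.floats(-1, 1),
    cost=st.floats(-1, 1), phi=st.floats(0, 2 * np.pi),
)
def test_rotation_always_returns_unit_vector(ux, uy, uz, cost, phi):
    norm = np.sqrt(ux * ux + uy * uy + uz * uz)
    if norm < 1e-6:
        return
    v = _kernels.rotate_direction(ux / norm, uy / norm, uz / norm, cost, phi)
    assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-9)
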