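"""Unit-level checks of projectors, updates, and probe handling."""

import numpy as np
import pytest

from ptychokit.data_model import InvalidInputError, ProbeStack
from ptychokit.propagation import PropagatorSpec, from_detector, to_detector
from ptychokit.projection import (
    MomentumState,
    accumulate_updates,
    anneal_positions,
    apply_global_updates,
    apply_probe_support,
    batch_error,
    dm_update,
    exit_wave,
    mpie_momentum,
    orthogonalize_probe_modes,
    project_data,
    raar_update,
    rpie_object_update,
    rpie_probe_update,
)
from ptychokit.scheduler import UpdateAccumulator


def far_spec(m):
    return PropagatorSpec(regime="far_field", frame_shape=(m, m))


def random_modes(rng, k, m):
    return rng.normal(size=(k, m, m)) + 1j * rng.normal(size=(k, m, m))


class TestExitWave:
    def test_uniform_object_returns_probe(self, rng):
        probe = random_modes(rng, 2, 4)
        obj = np.ones((8, 8), dtype=complex)
        assert np.array_equal(exit_wave(obj, probe, (2, 3)), probe)

    def test_zero_probe_returns_zero(self):
        obj = np.ones((8, 8), dtype=complex)
        assert np.all(exit_wave(obj, np.zeros((1, 4, 4), complex), (0, 0)) == 0)

    def test_matches_elementwise_loop(self, rng):
        probe = random_modes(rng, 1, 8)
        obj = rng.normal(size=(16, 16)) + 1j * rng.normal(size=(16, 16))
        psi = exit_wave(obj, probe, (5, 3))
        for y in range(8):
            for x in range(8):
                assert psi[0, y, x] == pytest.approx(
                    probe[0, y, x] * obj[5 + y, 3 + x], rel=1e-12
                )

    def test_window_violation_raises(self, rng):
        probe = random_modes(rng, 1, 8)
        obj = np.ones((10, 10), dtype=complex)
        with pytest.raises(Exception, match="canvas"):
            exit_wave(obj, probe, (5, 5))


class TestProjectData:
    def test_fixed_point_when_magnitudes_match(self, rng):
        m = 16
        psi = random_modes(rng, 1, m)
        spec = far_spec(m)
        I = np.abs(to_detector(psi, spec)[0]) ** 2
        out = project_data(psi, I, np.ones((m, m)), spec)
        assert np.sqrt(np.mean(np.abs(out - psi) ** 2)) < 1e-6 * np.abs(psi).max()

    def test_all_masked_out_is_identity(self, rng):
        m = 8
        psi = random_modes(rng, 2, m)
        I = rng.uniform(1, 5, size=(m, m))
        out = project_data(psi, I, np.zeros((m, m)), far_spec(m))
        assert np.allclose(out, psi, atol=1e-12)

    def test_tiny_case_matches_hand_dft_oracle(self, rng):
        """2x2 single mode vs explicit magnitude replacement."""
        m = 2
        psi = random_modes(rng, 1, m)
        I = rng.uniform(0.5, 2.0, size=(m, m))
        spec = far_spec(m)
        out = project_data(psi, I, np.ones((m, m)), spec)
        # oracle: same propagator, scalar magnitude replacement per pixel
        Psi = to_detector(psi, spec)[0]
        replaced = np.sqrt(I) * Psi / np.abs(Psi)
        expected = from_detector(replaced[None], spec)[0]
        assert np.allclose(out[0], expected, atol=1e-10)

    def test_idempotence(self, rng):
        for m in (16, 32):
            psi = random_modes(rng, 2, m)
            I = rng.uniform(0, 3, size=(m, m))
            spec = far_spec(m)
            once = project_data(psi, I, np.ones((m, m)), spec)
            twice = project_data(once, I, np.ones((m, m)), spec)
            rms = np.sqrt(np.mean(np.abs(twice - once) ** 2))
            assert rms < 1e-6 * max(np.abs(once).max(), 1.0)

    def test_negative_intensity_rejected(self, rng):
        psi = random_modes(rng, 1, 4)
        with pytest.raises(InvalidInputError):
            project_data(psi, -np.ones((4, 4)), np.ones((4, 4)), far_spec(4))


class TestDMAndRAAR:
    def test_raar_beta_one_equals_dm_bitwise(self, rng):
        m = 8
        spec = far_spec(m)
        for _ in range(5):
            psi = random_modes(rng, 1, m)
            cons = random_modes(rng, 1, m)
            I = rng.uniform(0, 2, size=(m, m))
            mask = np.ones((m, m))
            a = dm_update(psi, I, mask, cons, spec)
            b = raar_update(psi, I, mask, cons, 1.0, spec)
            assert np.array_equal(a, b)

    def test_raar_beta_zero_returns_consistency(self, rng):
        m = 8
        psi = random_modes(rng, 1, m)
        cons = random_modes(rng, 1, m)
        I = rng.uniform(0, 2, size=(m, m))
        out = raar_update(psi, I, np.ones((m, m)), cons, 0.0, far_spec(m))
        assert np.allclose(out, cons, atol=1e-12)

    def test_raar_matches_three_term_oracle(self, rng):
        m = 4
        spec = far_spec(m)
        psi = random_modes(rng, 1, m)
        cons = random_modes(rng, 1, m)
        I = rng.uniform(0, 2, size=(m, m))
        mask = np.ones((m, m))
        beta = 0.37
        reflected = project_data(2 * cons - psi, I, mask, spec)
        expected = beta * (psi + reflected) + (1 - 2 * beta) * cons
        assert np.allclose(
            raar_update(psi, I, mask, cons, beta, spec), expected, atol=1e-12
        )

    def test_dm_fixed_point(self, rng):
        """A wavefront satisfying both constraints is unmoved."""
        m = 8
        spec = far_spec(m)
        psi = random_modes(rng, 1, m)
        I = np.abs(to_detector(psi, spec)[0]) ** 2
        out = dm_update(psi, I, np.ones((m, m)), psi, spec)
        assert np.allclose(out, psi, atol=1e-8)


class TestBatchError:
    def test_perfect_model_gives_zero(self, rng):
        m = 8
        spec = far_spec(m)
        psi = random_modes(rng, 1, m)
        I = np.abs(to_detector(psi, spec)[0]) ** 2
        num, den = batch_error(I[None], [psi], [np.ones((m, m))], spec)
        assert num / den < 1e-24

    def test_zero_model_reduces_to_intensity_moments(self, rng):
        m = 4
        I = rng.uniform(0, 3, size=(2, m, m))
        psi0 = np.zeros((1, m, m), dtype=complex)
        num, den = batch_error(I, [psi0, psi0], [np.ones((m, m))] * 2, far_spec(m))
        assert num == pytest.approx(np.sum(I**2))
        assert den == pytest.approx(np.sum(I))

    def test_two_frame_scalar_oracle(self, rng):
        m = 2
        spec = far_spec(m)
        psi = [random_modes(rng, 1, m) for _ in range(2)]
        I = rng.uniform(0, 2, size=(2, m, m))
        masks = [np.array([[1, 0], [1, 1]]), np.ones((m, m))]
        num, den = batch_error(I, psi, masks, spec)
        exp_num = exp_den = 0.0
        for i in range(2):
            model = np.abs(to_detector(psi[i], spec)[0]) ** 2
            for u in range(m):
                for v in range(m):
                    exp_num += masks[i][u, v] * (I[i, u, v] - model[u, v]) ** 2
                    exp_den += masks[i][u, v] * I[i, u, v]
        assert num == pytest.approx(exp_num)
        assert den == pytest.approx(exp_den)


class TestAccumulators:
    def test_single_position_unit_probe(self, rng):
        m = 4
        psi_p = random_modes(rng, 1, m)
        probe = np.ones((1, m, m), dtype=complex)
        obj = np.ones((8, 8), dtype=complex)
        acc = UpdateAccumulator.zeros((8, 8), 1, (m, m))
        accumulate_updates([psi_p], probe, obj, [(1, 2)], acc)
        assert np.allclose(acc.obj_num[1:5, 2:6], psi_p[0])
        assert np.allclose(acc.obj_den[1:5, 2:6], 1.0)
        assert np.allclose(acc.obj_den[0], 0.0)

    def test_additivity_over_disjoint_positions(self, rng):
        m = 4
        probe = random_modes(rng, 1, m)
        obj = rng.normal(size=(12, 12)) + 1j * rng.normal(size=(12, 12))
        psis = [random_modes(rng, 1, m) for _ in range(2)]
        offs = [(0, 0), (6, 6)]
        both = UpdateAccumulator.zeros((12, 12), 1, (m, m))
        accumulate_updates(psis, probe, obj, offs, both)
        seq = UpdateAccumulator.zeros((12, 12), 1, (m, m))
        for psi, off in zip(psis, offs):
            accumulate_updates([psi], probe, obj, [off], seq)
        assert np.allclose(both.obj_num, seq.obj_num)
        assert np.allclose(both.probe_num, seq.probe_num)

    def test_overlapping_positions_match_loop_oracle(self, rng):
        m = 4
        probe = random_modes(rng, 2, m)
        obj = rng.normal(size=(10, 10)) + 1j * rng.normal(size=(10, 10))
        psis = [random_modes(rng, 2, m) for _ in range(3)]
        offs = [(0, 0), (2, 1), (3, 3)]
        acc = UpdateAccumulator.zeros((10, 10), 2, (m, m))
        accumulate_updates(psis, probe, obj, offs, acc)
        exp_on = np.zeros((10, 10), dtype=complex)
        exp_od = np.zeros((10, 10))
        exp_pn = np.zeros((2, m, m), dtype=complex)
        exp_pd = np.zeros((m, m))
        for psi, (oy, ox) in zip(psis, offs):
            for km in range(2):
                for y in range(m):
                    for x in range(m):
                        exp_on[oy + y, ox + x] += (
                            np.conj(probe[km, y, x]) * psi[km, y, x]
                        )
                        exp_pn[km, y, x] += (
                            np.conj(obj[oy + y, ox + x]) * psi[km, y, x]
                        )
            for y in range(m):
                for x in range(m):
                    exp_od[oy + y, ox + x] += np.sum(np.abs(probe[:, y, x]) ** 2)
                    exp_pd[y, x] += np.abs(obj[oy + y, ox + x]) ** 2
        assert np.allclose(acc.obj_num, exp_on)
        assert np.allclose(acc.obj_den, exp_od)
        assert np.allclose(acc.probe_num, exp_pn)
        assert np.allclose(acc.probe_den, exp_pd)

    def test_apply_updates_single_position_unit_probe(self, rng):
        m = 4
        psi_p = random_modes(rng, 1, m)
        probe = np.ones((1, m, m), dtype=complex)
        obj = np.full((8, 8), 0.5 + 0j)
        acc = UpdateAccumulator.zeros((8, 8), 1, (m, m))
        accumulate_updates([psi_p], probe, obj, [(1, 2)], acc)
        new_obj, _ = apply_global_updates(acc, obj, probe, update_probe=False)
        assert np.allclose(new_obj[1:5, 2:6], psi_p[0], rtol=1e-5)
        # unvisited pixels keep the prior
        assert np.allclose(new_obj[0], 0.5)

    def test_double_coverage_ratio_invariance(self, rng):
        m = 4
        psi_p = random_modes(rng, 1, m)
        probe = random_modes(rng, 1, m)
        obj = np.ones((m, m), dtype=complex)
        single = UpdateAccumulator.zeros((m, m), 1, (m, m))
        accumulate_updates([psi_p], probe, obj, [(0, 0)], single)
        double = UpdateAccumulator.zeros((m, m), 1, (m, m))
        accumulate_updates([psi_p, psi_p], probe, obj, [(0, 0), (0, 0)], double)
        o1, _ = apply_global_updates(single, obj, probe, update_probe=False)
        o2, _ = apply_global_updates(double, obj, probe, update_probe=False)
        assert np.allclose(o1, o2, rtol=1e-5)


class TestRPIEUpdates:
    def test_no_residual_no_change(self, rng):
        m = 4
        probe = random_modes(rng, 1, m)
        win = rng.normal(size=(m, m)) + 1j * rng.normal(size=(m, m))
        psi = probe * win[None]
        assert np.allclose(
            rpie_object_update(win, probe, psi, psi, 1.0, 0.1), win
        )
        assert np.allclose(
            rpie_probe_update(win, probe, psi, psi, 1.0, 0.1), probe
        )

    def test_full_regularization_is_constant_denominator(self, rng):
        m = 4
        probe = random_modes(rng, 1, m)
        win = np.ones((m, m), dtype=complex)
        psi = probe * win[None]
        psi_p = psi + random_modes(rng, 1, m)
        power = np.abs(probe[0]) ** 2
        expected = win + np.conj(probe[0]) * (psi_p - psi)[0] / power.max()
        out = rpie_object_update(win, probe, psi, psi_p, 1.0, 1.0)
        assert np.allclose(out, expected)

    def test_matches_elementwise_oracle(self, rng):
        m = 4
        probe = random_modes(rng, 1, m)
        win = rng.normal(size=(m, m)) + 1j * rng.normal(size=(m, m))
        psi = probe * win[None]
        psi_p = psi + 0.3 * random_modes(rng, 1, m)
        s, r = 0.8, 0.15
        out_o = rpie_object_update(win, probe, psi, psi_p, s, r)
        out_p = rpie_probe_update(win, probe, psi, psi_p, s, r)
        p2 = np.abs(probe[0]) ** 2
        o2 = np.abs(win) ** 2
        for y in range(m):
            for x in range(m):
                den_o = (1 - r) * p2[y, x] + r * p2.max()
                assert out_o[y, x] == pytest.approx(
                    win[y, x]
                    + s * np.conj(probe[0, y, x]) * (psi_p - psi)[0, y, x] / den_o
                )
                den_p = (1 - r) * o2[y, x] + r * o2.max()
                assert out_p[0, y, x] == pytest.approx(
                    probe[0, y, x]
                    + s * np.conj(win[y, x]) * (psi_p - psi)[0, y, x] / den_p
                )

    def test_zero_probe_without_regularization_rejected(self):
        m = 2
        z = np.zeros((1, m, m), dtype=complex)
        with pytest.raises(InvalidInputError):
            rpie_object_update(np.ones((m, m), complex), z, z, z, 1.0, 0.0)


class TestMomentum:
    def test_zero_friction_is_noop(self, rng):
        obj = rng.normal(size=(4, 4)) + 0j
        probe = rng.normal(size=(1, 2, 2)) + 0j
        state = MomentumState.init(obj, probe)
        o2, p2 = mpie_momentum(obj + 1.0, probe + 1.0, state, 0.0, 1)
        assert np.array_equal(o2, obj + 1.0)
        assert np.array_equal(p2, probe + 1.0)

    def test_scalar_recurrence_oracle(self):
        """Two identical steps with friction 0.9 follow the hand recurrence."""
        f = 0.9
        obj = np.zeros((1, 1), dtype=complex)
        probe = np.zeros((1, 1, 1), dtype=complex)
        state = MomentumState.init(obj, probe)
        # step 1: X moves 0 -> 1
        o, _ = mpie_momentum(obj + 1.0, probe, state, f, 1, friction_probe=f)
        v1 = 1.0          # v = f*0 + (1 - 0)
        x1 = 1.0 + f * v1  # accelerated iterate
        assert o[0, 0] == pytest.approx(x1)
        # step 2: another unit step from the accelerated iterate
        o2, _ = mpie_momentum(o + 1.0, probe, state, f, 1, friction_probe=f)
        v2 = f * v1 + 1.0
        x2 = (x1 + 1.0) + f * v2
        assert o2[0, 0] == pytest.approx(x2)

    def test_disabled_momentum_is_plain_rpie(self, small_benchmark):
        from ptychokit import ReconConfig, run_reconstruction

        stack = small_benchmark["stack"]
        init = {"offsets_px": small_benchmark["offsets"]}
        a = run_reconstruction(
            stack, ReconConfig(engine="rpie", iterations=5, seed=4), init=init
        )
        b = run_reconstruction(
            stack,
            ReconConfig(
                engine="mpie", iterations=5, seed=4,
                momentum_friction=0.0, momentum_friction_probe=0.0,
            ),
            init=init,
        )
        assert np.array_equal(a.error_trace, b.error_trace)
        assert np.array_equal(a.object.values, b.object.values)


class TestProbeSupport:
    def test_huge_support_is_identity(self, rng):
        probe = random_modes(rng, 2, 8)
        out = apply_probe_support(probe, diameter_m=100.0, pixel_m=1.0)
        assert np.array_equal(out, probe)

    def test_energy_ratio_matches_disk_area(self):
        m = 64
        probe = np.ones((1, m, m), dtype=complex)
        out = apply_probe_support(probe, diameter_m=m / 2.0, pixel_m=1.0)
        ratio = np.sum(np.abs(out) ** 2) / np.sum(np.abs(probe) ** 2)
        assert ratio == pytest.approx(np.pi * (m / 4) ** 2 / m**2, rel=0.05)

    def test_idempotent(self, rng):
        probe = random_modes(rng, 1, 16)
        once = apply_probe_support(probe, 8.0, 1.0)
        twice = apply_probe_support(once, 8.0, 1.0)
        assert np.array_equal(once, twice)


class TestOrthogonalization:
    def test_orthogonal_input_preserved_up_to_phase(self, rng):
        m = 8
        a = np.zeros((m, m), dtype=complex)
        a[2, 2] = 3.0
        b = np.zeros((m, m), dtype=complex)
        b[5, 5] = 1.0
        out = orthogonalize_probe_modes(ProbeStack(np.stack([a, b])))
        assert abs(np.vdot(out.modes[0], out.modes[1])) < 1e-10
        assert np.sum(np.abs(out.modes[0]) ** 2) == pytest.approx(9.0)

    def test_duplicated_mode_collapses_to_zero(self, rng):
        mode = random_modes(rng, 1, 8)[0]
        out = orthogonalize_probe_modes(ProbeStack(np.stack([mode, mode])))
        assert np.sum(np.abs(out.modes[1]) ** 2) < 1e-10 * np.sum(
            np.abs(out.modes[0]) ** 2
        )

    def test_gram_matrix_is_diagonal_and_power_conserved(self, rng):
        modes = random_modes(rng, 3, 8)
        out = orthogonalize_probe_modes(ProbeStack(modes))
        flat = out.modes.reshape(3, -1)
        gram = flat @ flat.conj().T
        power = np.abs(np.diag(gram))
        off = gram - np.diag(np.diag(gram))
        assert np.all(np.abs(off) < 1e-6 * power.max())
        assert np.sum(power) == pytest.approx(
            np.sum(np.abs(modes) ** 2), rel=1e-6
        )
        assert np.all(np.diff(power.real) <= 1e-9)
        assert out.occupancies.sum() == pytest.approx(1.0)


class TestAnnealing:
    def test_true_positions_are_kept_on_noiseless_data(self, small_benchmark):
        stack = small_benchmark["stack"]
        truth = small_benchmark["object"]
        probe = small_benchmark["probe"]
        offsets = small_benchmark["offsets"]
        spec = PropagatorSpec.from_geometry(stack.geometry)
        rng = np.random.default_rng(0)
        out = anneal_positions(
            truth.values, probe.modes, stack, offsets, spec,
            radius_px=2, trials=8, rng=rng, indices=[0, 5, 12],
        )
        assert np.array_equal(out, offsets)

    def test_exhaustive_search_recovers_known_shift(self, small_benchmark):
        stack = small_benchmark["stack"]
        truth = small_benchmark["object"]
        probe = small_benchmark["probe"]
        offsets = small_benchmark["offsets"].copy()
        wrong = offsets.copy()
        wrong[12] = offsets[12] + (2, -1)
        spec = PropagatorSpec.from_geometry(stack.geometry)
        out = anneal_positions(
            truth.values, probe.modes, stack, wrong, spec,
            radius_px=3, trials=None, rng=np.random.default_rng(0), indices=[12],
        )
        assert tuple(out[12]) == tuple(offsets[12])

    def test_seeded_trajectory_is_reproducible(self, small_benchmark):
        stack = small_benchmark["stack"]
        probe = small_benchmark["probe"]
        offsets = small_benchmark["offsets"]
        spec = PropagatorSpec.from_geometry(stack.geometry)
        obj = np.ones((64, 64), dtype=complex)
        runs = []
        for _ in range(2):
            rng = np.random.default_rng(77)
            runs.append(
                anneal_positions(
                    obj, probe.modes, stack, offsets, spec,
                    radius_px=2, trials=4, rng=rng,
                )
            )
        assert np.array_equal(runs[0], runs[1])

    def test_zero_radius_is_noop(self, small_benchmark):
        stack = small_benchmark["stack"]
        probe = small_benchmark["probe"]
        offsets = small_benchmark["offsets"]
        spec = PropagatorSpec.from_geometry(stack.geometry)
        out = anneal_positions(
            np.ones((64, 64), complex), probe.modes, stack, offsets, spec,
            radius_px=0, trials=8, rng=np.random.default_rng(0),
        )
        assert np.array_equal(out, offsets)
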