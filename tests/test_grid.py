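"""Grid engine: neighborhoods, diffusion, stepping, trajectories."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fibrogrid as fg
from fibrogrid.errors import ContractError, IntegrationError

from conftest import make_state
from naive import naive_step


class TestNeighborhood:
    def test_interior_cell(self):
        nbrs = set(fg.neighbor_coords(5, 5, 100))
        expected = {(i, j) for i in (4, 5, 6) for j in (4, 5, 6)} - {(5, 5)}
        assert nbrs == expected

    def test_corner_wraps_periodically(self):
        nbrs = set(fg.neighbor_coords(0, 0, 100))
        assert len(nbrs) == 8
        assert {(99, 99), (99, 0), (0, 99)} <= nbrs

    def test_symmetry_exhaustive_5x5(self):
        N = 5
        for a in range(N * N):
            for b in range(N * N):
                ai, aj = divmod(a, N)
                bi, bj = divmod(b, N)
                in_a = (bi, bj) in fg.neighbor_coords(ai, aj, N)
                in_b = (ai, aj) in fg.neighbor_coords(bi, bj, N)
                assert in_a == in_b

    def test_self_never_included(self):
        assert (2, 2) not in fg.neighbor_coords(2, 2, 5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ContractError):
            fg.neighbor_coords(5, 0, 5)


class TestDiffusion:
    def test_uniform_field_gives_zero(self):
        plane = np.full((7, 7), 0.3)
        np.testing.assert_allclose(fg.diffusion_term(plane, 0.25), 0.0)

    def test_single_hot_cell(self):
        plane = np.zeros((5, 5))
        plane[2, 2] = 1.0
        out = fg.diffusion_term(plane, 0.25)
        assert out[2, 2] == pytest.approx(-2.0)  # 0.25 * 8 * (0 - 1)
        for (i, j) in fg.neighbor_coords(2, 2, 5):
            assert out[i, j] == pytest.approx(0.25)
        assert abs(out.sum()) < 1e-12

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_conserves_mass_on_random_fields(self, seed):
        rng = np.random.default_rng(seed)
        plane = rng.random((10, 10))
        assert abs(fg.diffusion_term(plane, 0.25).sum()) < 1e-12


class TestAdaptiveDt:
    @pytest.mark.parametrize("rate,expected", [
        (0.0, 0.1),
        (2.0, 0.05),
        (0.5, 0.1),
    ])
    def test_examples(self, rate, expected):
        assert fg.adaptive_dt(rate, fg.StepPolicy()) == pytest.approx(expected)

    def test_negative_rate_rejected(self):
        with pytest.raises(ContractError):
            fg.adaptive_dt(-1.0, fg.StepPolicy())


class TestCounting:
    def test_reference_at_n100(self, ref_spec):
        assert fg.count_state_variables(ref_spec, 100) == 1_360_000

    def test_reference_at_n10(self, ref_spec):
        assert fg.count_state_variables(ref_spec, 10) == 13_600

    def test_toy_without_feedback(self, toy_chain_spec):
        spec = fg.NetworkSpec(
            species=[fg.Species("A"), fg.Species("B")],
            edges=[], inputs=[],
        )
        assert fg.count_state_variables(spec, 3) == 18


class TestStep:
    def test_zero_state_is_a_fixed_point(self, toy_chain_spec):
        N = 5
        config = fg.SimulationConfig(grid_size=N)
        state = make_state(toy_chain_spec, N)
        inputs = np.zeros((N, N, 1))
        out = fg.step(state, toy_chain_spec, config, inputs)
        assert np.all(out.intracellular == 0.0)
        assert out.iteration == 1
        assert out.time > 0

    def test_uniform_state_stays_uniform(self, ref_spec):
        N = 6
        config = fg.SimulationConfig(grid_size=N)
        rng = np.random.default_rng(0)
        cell = rng.random(ref_spec.n_species)
        state = make_state(
            ref_spec, N,
            intra=np.tile(cell, (N, N, 1)),
            feedback=np.full((4, N, N), 0.2),
            ecm=np.full((len(ref_spec.ecm_fields), N, N), 0.1),
        )
        inputs = np.full((N, N, 10), 0.5)
        out = fg.step(state, ref_spec, config, inputs)
        assert np.ptp(out.intracellular, axis=(0, 1)).max() < 1e-12
        assert np.ptp(out.feedback, axis=(1, 2)).max() < 1e-12
        assert np.ptp(out.ecm, axis=(1, 2)).max() < 1e-12

    def test_diffusion_only_conserves_field_total(self, diffusion_only_spec):
        N = 30
        config = fg.SimulationConfig(grid_size=N)
        rng = np.random.default_rng(42)
        fb = rng.random((1, N, N))
        state = make_state(diffusion_only_spec, N, feedback=fb)
        total0 = state.feedback.sum()
        inputs = np.zeros((N, N, 0))
        for _ in range(100):
            state = fg.step(state, diffusion_only_spec, config, inputs, dt=0.1)
        assert state.feedback.sum() == pytest.approx(total0, abs=1e-9)

    def test_translation_equivariance_of_diffusion(self, diffusion_only_spec):
        N = 12
        config = fg.SimulationConfig(grid_size=N)
        rng = np.random.default_rng(3)
        fb = rng.random((1, N, N))
        shift = (3, 5)
        a = make_state(diffusion_only_spec, N, feedback=fb.copy())
        b = make_state(
            diffusion_only_spec, N,
            feedback=np.roll(fb, shift, axis=(1, 2)).copy(),
        )
        inputs = np.zeros((N, N, 0))
        for _ in range(20):
            a = fg.step(a, diffusion_only_spec, config, inputs, dt=0.1)
            b = fg.step(b, diffusion_only_spec, config, inputs, dt=0.1)
        np.testing.assert_allclose(
            np.roll(a.feedback, shift, axis=(1, 2)), b.feedback, atol=1e-12
        )

    def test_matches_naive_loop_step_on_reference(self, ref_spec):
        """Vectorized engine vs per-cell/per-edge brute force, 5x5, 20 steps."""
        N = 5
        config = fg.SimulationConfig(grid_size=N, seed=11)
        rng = np.random.default_rng(11)
        state = make_state(
            ref_spec, N,
            intra=0.3 * rng.random((N, N, ref_spec.n_species)),
            feedback=0.3 * rng.random((4, N, N)),
            ecm=0.3 * rng.random((len(ref_spec.ecm_fields), N, N)),
        )
        inputs = rng.random((N, N, 10))
        intra, fb, ecm = (
            state.intracellular.copy(), state.feedback.copy(), state.ecm.copy()
        )
        for _ in range(20):
            state = fg.step(state, ref_spec, config, inputs, dt=0.1)
            intra, fb, ecm = naive_step(
                ref_spec, ref_spec.rates, intra, fb, ecm, inputs, 0.1
            )
        assert np.max(np.abs(state.intracellular - intra)) < 1e-9
        assert np.max(np.abs(state.feedback - fb)) < 1e-9
        assert np.max(np.abs(state.ecm - ecm)) < 1e-9

    def test_nonfinite_derivative_is_reported_with_location(self, toy_chain_spec):
        N = 3
        config = fg.SimulationConfig(grid_size=N)
        state = make_state(toy_chain_spec, N)
        state.intracellular[1, 2, 0] = np.nan
        inputs = np.zeros((N, N, 1))
        with pytest.raises(IntegrationError, match=r"\(1, 2\)"):
            fg.step(state, toy_chain_spec, config, inputs)

    def test_shape_mismatch_rejected(self, toy_chain_spec):
        config = fg.SimulationConfig(grid_size=4)
        state = make_state(toy_chain_spec, 5)
        with pytest.raises(ContractError):
            fg.step(state, toy_chain_spec, config, np.zeros((4, 4, 1)))

    @settings(max_examples=15, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1), dt=st.floats(0.01, 0.5))
    def test_concentrations_stay_clamped(self, ref_spec, seed, dt):
        N = 4
        config = fg.SimulationConfig(grid_size=N)
        rng = np.random.default_rng(seed)
        state = make_state(
            ref_spec, N,
            intra=rng.random((N, N, ref_spec.n_species)),
            feedback=rng.random((4, N, N)),
            ecm=rng.random((len(ref_spec.ecm_fields), N, N)),
        )
        inputs = rng.random((N, N, 10))
        for _ in range(5):
            state = fg.step(state, ref_spec, config, inputs, dt=dt)
            for arr in (state.intracellular, state.feedback, state.ecm):
                assert arr.min() >= 0.0
                assert arr.max() <= 1.0


class TestRun:
    def test_snapshot_zero_equals_seeded_initial_state(self, ref_spec):
        N = 10
        scenario = fg.scenario_case(1, N)
        scenario.duration_iterations = 5
        scenario.snapshot_iterations = (0, 5)
        config = fg.SimulationConfig(grid_size=N, seed=123)
        traj = fg.run(scenario, ref_spec, config)
        rng = np.random.default_rng(123)
        expected = fg.initial_state(ref_spec, config, rng)
        np.testing.assert_array_equal(
            traj.snapshots[0].field_plane("proCI"),
            expected.field_plane("proCI"),
        )

    def test_same_seed_gives_identical_trajectories(self, ref_spec):
        N = 8
        scenario = fg.scenario_case(2, N)
        scenario.duration_iterations = 30
        scenario.snapshot_iterations = (0, 30)
        config = fg.SimulationConfig(grid_size=N, seed=7)
        t1 = fg.run(scenario, ref_spec, config)
        t2 = fg.run(scenario, ref_spec, config)
        np.testing.assert_array_equal(
            t1.snapshots[30].intracellular, t2.snapshots[30].intracellular
        )
        np.testing.assert_array_equal(t1.times, t2.times)

    def test_snapshot_beyond_duration_rejected(self, ref_spec):
        N = 8
        scenario = fg.scenario_case(1, N)
        scenario.duration_iterations = 10
        scenario.snapshot_iterations = (0, 100)
        config = fg.SimulationConfig(grid_size=N, seed=0)
        with pytest.raises(ContractError):
            fg.run(scenario, ref_spec, config)

    def test_probe_series_track_probed_cells(self, ref_spec):
        N = 8
        scenario = fg.scenario_case(2, N)
        scenario.duration_iterations = 10
        scenario.snapshot_iterations = (0, 10)
        config = fg.SimulationConfig(grid_size=N, seed=1)
        traj = fg.run(scenario, ref_spec, config)
        assert set(traj.probes) == set(scenario.probe_cells)
        series = traj.probes[scenario.probe_cells[0]]
        assert series.intracellular.shape == (11, ref_spec.n_species)
        i, j = scenario.probe_cells[0]
        np.testing.assert_array_equal(
            series.intracellular[-1], traj.snapshots[10].intracellular[i, j]
        )

    def test_explicit_diffusion_is_stable_with_defaults(self):
        # 8 * D * dt = 8 * 0.25 * 0.1 = 0.2 < 1: no oscillatory blow-up
        assert 8 * fg.RateConstants().k_diffusion * fg.StepPolicy().dt_max < 1
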