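"""Movie analysis estimators: thresholds, opening rate, direction, rates."""

import numpy as np
import pytest

import porewave as pw
from porewave.movie import (
    SubunitTraceMatrix,
    arc_length_subunits,
    assign_states,
    estimate_propagation_rates,
    initiation_survival_fit,
    opening_rate,
    propagation_direction,
    transition_time,
    unfurling_speed,
    height_distribution,
)
from porewave.states import CellState, StateMatrix
from porewave.geometry import make_hex_layout
from porewave.synthetic import render_movie


def traces_from(heights, baseline=8.1, dt=0.2):
    return SubunitTraceMatrix(
        heights=np.asarray(heights, float), ring_id=0, frame_interval=dt,
        baseline_height=baseline,
    )


def sm(states, dt=0.2):
    return StateMatrix(states=np.asarray(states, dtype=np.int8), frame_interval=dt)


class TestAssignStates:
    def test_threshold_bands(self):
        row = [8.1, 8.1 + 0.79, 8.1 + 0.8, 8.1 + 1.6, 8.1 + 2.69, 8.1 + 2.7, 8.1 + 3.8,
               8.1 - 4.5] + [8.1] * 8
        out = assign_states(traces_from([row])).states[0]
        expect = [0, 0, 1, 1, 1, 2, 2, -1] + [0] * 8
        np.testing.assert_array_equal(out, expect)

    def test_baseline_required(self):
        tm = traces_from([[8.1] * 16], baseline=float("nan"))
        with pytest.raises(ValueError):
            assign_states(tm)


class TestOpeningRate:
    def test_zero_when_no_open_cells(self):
        states = sm(np.zeros((50, 16)))
        assert opening_rate([states]).rate == 0.0

    def test_recovers_generator_breakage_rate(self):
        """>= 50 ring-minutes at k_open = 1.8 recovers 1.8 +/- 0.2."""
        rates = pw.RingKineticRates(q_nucleate=0.0)
        trajs = pw.simulate_ensemble(rates, 50, 60.0, seed=40)
        states = [pw.trajectory_to_state_matrix(t, 300, 0.2) for t in trajs]
        est = opening_rate(states)
        assert est.rate == pytest.approx(1.8, abs=0.2)
        assert est.ci95[0] < est.rate < est.ci95[1]

    def test_linear_in_breakage_rate(self):
        halves = pw.RingKineticRates(q_nucleate=0.0, k_open=0.9)
        trajs = pw.simulate_ensemble(halves, 50, 60.0, seed=41)
        states = [pw.trajectory_to_state_matrix(t, 300, 0.2) for t in trajs]
        est = opening_rate(states)
        assert est.rate == pytest.approx(0.9, abs=0.12)

    def test_zero_observation_time_raises(self):
        pre_transitioned = sm(np.full((10, 16), CellState.PORE))
        with pytest.raises(ValueError):
            opening_rate([pre_transitioned])


class TestPropagationDirection:
    @staticmethod
    def wave_states(start=3, n=10, frames_per_step=2):
        states = np.zeros((n * frames_per_step + 4, 16), dtype=np.int8)
        for j in range(n):
            su = (start + j) % 16
            states[2 + j * frames_per_step :, su] = 1
        return sm(states)

    def test_clockwise_wave_scores_plus_one(self):
        assert propagation_direction(self.wave_states()) == 1.0

    def test_mirrored_wave_scores_minus_one(self):
        mirrored = sm(self.wave_states().states[:, ::-1])
        assert propagation_direction(mirrored) == -1.0

    def test_shuffled_entries_score_near_zero(self):
        rng = np.random.default_rng(42)
        small = 0
        for _ in range(100):
            frames = rng.permutation(100)[:16]
            states = np.zeros((101, 16), dtype=np.int8)
            for su, f in enumerate(frames):
                states[f:, su] = 1
            try:
                score = propagation_direction(sm(states))
            except ValueError:
                small += 1  # no adjacent consecutive pairs at all
                continue
            if abs(score) < 0.5:
                small += 1
        assert small > 95

    def test_fewer_than_two_events_undefined(self):
        states = np.zeros((10, 16), dtype=np.int8)
        states[3:, 5] = 1
        with pytest.raises(ValueError):
            propagation_direction(sm(states))

    def test_simulated_ensembles_score_exactly_plus_one(self, preset_state_matrices):
        scores = []
        for m in preset_state_matrices:
            try:
                scores.append(propagation_direction(m))
            except ValueError:
                continue
        assert len(scores) >= 200
        assert all(s == 1.0 for s in scores)


class TestPropagationRates:
    def test_recovers_k12_k23_at_frame_rate(self, preset_state_matrices):
        k12, k23 = estimate_propagation_rates(preset_state_matrices)
        assert k12.rate == pytest.approx(13.0, rel=0.20)
        assert k23.rate == pytest.approx(15.0, rel=0.20)
        assert k12.n_events >= 500 and k23.n_events >= 500

    def test_near_uncensored_limit_matches_naive_estimator(self, preset_rates):
        """At 2 ms frames the censored MLE converges to 1/mean."""
        trajs = pw.simulate_ensemble(preset_rates, 60, 30.0, seed=43)
        states = [pw.trajectory_to_state_matrix(t, 15000, 0.002) for t in trajs]
        k12, _ = estimate_propagation_rates(states)
        d12 = []
        for smx in states:
            from porewave.movie import _first_entry_frames, _wave_order

            first = _first_entry_frames(smx.states, 1)
            order = _wave_order(first)
            d12.extend(
                first[b] - first[a] for a, b in zip(order[:-1], order[1:])
            )
        naive = 1.0 / (np.mean(d12) * 0.002)
        assert k12.rate == pytest.approx(naive, rel=0.05)

    def test_unresolvable_rate_raises(self):
        states = [sm(np.array([[0] * 16, [1] * 16, [2] * 16] * 20))]
        with pytest.raises(ValueError, match="censored into a single frame"):
            estimate_propagation_rates(states)


class TestArcLengthAndTimes:
    def test_full_ring_is_sixteen(self):
        assert arc_length_subunits(sm(np.full((3, 16), 2))) == 16

    def test_270_degree_arc_is_twelve(self):
        states = np.zeros((3, 16), dtype=np.int8)
        states[-1, 2:14] = 2  # 12 contiguous sectors = 270 degrees
        assert arc_length_subunits(sm(states)) == 12

    def test_rotation_invariance(self):
        rng = np.random.default_rng(44)
        states = np.zeros((2, 16), dtype=np.int8)
        states[-1, 5:11] = 2
        base = arc_length_subunits(sm(states))
        for shift in rng.integers(1, 16, size=5):
            rolled = np.roll(states, shift, axis=1)
            assert arc_length_subunits(sm(rolled)) == base

    def test_matches_ground_truth_run_length(self, preset_trajectories, preset_state_matrices):
        for tr, smx in zip(preset_trajectories, preset_state_matrices):
            done = tr.run_length > 0 and all(
                t <= 29.5 for t in tr.times(pw.EventKind.TO_PORE)
            )
            if done:
                assert arc_length_subunits(smx) == tr.run_length

    def test_single_frame_transition_bounded_by_frame_interval(self):
        states = np.zeros((5, 16), dtype=np.int8)
        states[3, 4] = 1
        states[4, 4] = 2
        states[3:, 4] = [1, 2]
        t = transition_time(sm(states))
        assert t is not None and t <= 1 * 0.2 + 1e-12

    def test_survival_fit_recovers_five_seconds(self, preset_state_matrices):
        fit = initiation_survival_fit(preset_state_matrices)
        assert fit.tau == pytest.approx(5.0, rel=0.10)


class TestHeightDistribution:
    def test_pre_pore_scene_exact(self, quiet_conv):
        layout = make_hex_layout(4)
        trajs = [pw.RingTrajectory(events=[], ring_id=i, t_end=1.0) for i in range(4)]
        movie, _ = render_movie(layout, trajs, quiet_conv, n_frames=2)
        _, mean, std = height_distribution(movie, layout)
        assert mean == pytest.approx(8.1, abs=1e-6)
        assert std == pytest.approx(0.0, abs=1e-6)

    def test_recovers_base_height_under_noise(self):
        layout = make_hex_layout(9)
        trajs = [pw.RingTrajectory(events=[], ring_id=i, t_end=1.0) for i in range(9)]
        movie, _ = render_movie(
            layout, trajs, pw.HeightConventions(noise_sigma=0.3), n_frames=2, seed=45
        )
        _, mean, _ = height_distribution(movie, layout)
        assert mean == pytest.approx(8.1, abs=0.1)

    def test_pore_scene_about_11p9(self, quiet_conv):
        layout = make_hex_layout(2)
        trajs = []
        for i in range(2):
            events = []
            for su in range(16):
                events.append(pw.kmc.Event(0.001 + su * 1e-4, pw.EventKind.TO_II, su))
                events.append(pw.kmc.Event(0.01 + su * 1e-4, pw.EventKind.TO_PORE, su))
            trajs.append(pw.RingTrajectory(events=events, ring_id=i, t_end=1.0))
        movie, _ = render_movie(layout, trajs, quiet_conv, n_frames=2)
        _, mean, _ = height_distribution(movie, layout, frame=1)
        assert mean == pytest.approx(11.9, abs=1e-6)  # 3.8 nm above pre-pore


def test_detect_ring_centers_recovers_layout():
    from porewave.movie import detect_ring_centers

    layout = make_hex_layout(7)
    trajs = [pw.RingTrajectory(events=[], ring_id=i, t_end=2.0) for i in range(7)]
    movie, _ = render_movie(
        layout, trajs, pw.HeightConventions(noise_sigma=0.3), n_frames=5, seed=46
    )
    found = detect_ring_centers(movie, radius_nm=layout.ring_radius)
    assert len(found) == 7
    for c in layout.centers:
        assert np.min(np.linalg.norm(found - c, axis=1)) < 2.0  # nm


class TestUnfurling:
    def test_worked_example(self):
        est = unfurling_speed()
        assert round(est.strand_length_aa) == 23
        assert est.duration_ms == pytest.approx(45.8, abs=0.1)
        assert est.speed_aa_per_ms == pytest.approx(0.5, abs=0.05)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            unfurling_speed(dh_nm=0.0)
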