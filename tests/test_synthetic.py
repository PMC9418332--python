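"""Synthetic HS-AFM generator: layouts, rendering fidelity, ground truth."""

import numpy as np
import pytest
from scipy import stats

import porewave as pw
from porewave.geometry import LayoutCapacityError, make_hex_layout, sector_pixel_map
from porewave.movie import assign_states, unbend_layout, unbend_ring
from porewave.states import CellState
from porewave.synthetic import render_kymograph, render_movie


def still_ring_trajectory(ring_id=0, t_end=2.0):
    return pw.RingTrajectory(events=[], ring_id=ring_id, t_end=t_end)


class TestHexLayout:
    def test_single_ring_centered(self):
        layout = make_hex_layout(1, image_size=64)
        np.testing.assert_allclose(layout.centers[0], [32.0, 32.0], atol=0.5)

    def test_seven_rings_center_plus_hexagon(self):
        layout = make_hex_layout(7)
        d = np.linalg.norm(layout.centers[1:] - layout.centers[0], axis=1)
        np.testing.assert_allclose(d, d[0], rtol=1e-9)  # six equidistant neighbours
        ring = layout.centers[1:]
        nn = [np.sort(np.linalg.norm(ring - c, axis=1))[1] for c in ring]
        np.testing.assert_allclose(nn, d[0], rtol=1e-9)  # neighbours also at spacing

    def test_min_pairwise_distance_at_least_diameter(self):
        layout = make_hex_layout(19, ring_radius=10.0)
        c = layout.centers
        dists = np.linalg.norm(c[:, None] - c[None, :], axis=-1)
        dists[np.diag_indices_from(dists)] = np.inf
        assert dists.min() >= 2 * layout.ring_radius

    def test_overfull_layout_raises(self):
        with pytest.raises(LayoutCapacityError):
            make_hex_layout(20, image_size=64)


class TestRenderMovie:
    def test_all_pre_pore_noise_free_is_exactly_base_height(self, quiet_conv):
        layout = make_hex_layout(3)
        trajs = [still_ring_trajectory(i) for i in range(3)]
        movie, _ = render_movie(layout, trajs, quiet_conv, n_frames=4)
        for c in layout.centers:
            rows, cols, _ = sector_pixel_map(layout.image_shape, c, 10.0, 4.0)
            assert np.all(movie.frames[:, rows, cols] == np.float32(8.1))

    def test_pore_scene_is_3p8_above_pre_pore(self, quiet_conv):
        layout = make_hex_layout(1)
        events = [
            pw.RingTrajectory(
                events=[
                    *(
                        e
                        for i in range(16)
                        for e in (
                            pw.kmc.Event(0.001 + i * 1e-4, pw.EventKind.TO_II, i),
                            pw.kmc.Event(0.01 + i * 1e-4, pw.EventKind.TO_PORE, i),
                        )
                    )
                ],
                ring_id=0,
                t_end=1.0,
            )
        ]
        movie, _ = render_movie(layout, events, quiet_conv, n_frames=3)
        rows, cols, _ = sector_pixel_map(layout.image_shape, layout.centers[0], 10.0, 4.0)
        assert np.all(movie.frames[1:, rows, cols] == np.float32(8.1 + 1.6 + 2.2))

    def test_round_trip_zero_noise_recovers_truth_exactly(self, preset_rates, quiet_conv):
        trajs = pw.simulate_ensemble(preset_rates, 7, 20.0, seed=30)
        layout = make_hex_layout(7)
        movie, truth = render_movie(layout, trajs, quiet_conv, frame_interval=0.2, seed=31)
        for tm, gt in zip(unbend_layout(movie, layout), truth):
            np.testing.assert_array_equal(assign_states(tm).states, gt.states)

    def test_round_trip_at_noise_recovers_99_percent(self, preset_rates):
        trajs = pw.simulate_ensemble(preset_rates, 7, 20.0, seed=30)
        layout = make_hex_layout(7)
        movie, truth = render_movie(
            layout, trajs, pw.HeightConventions(), frame_interval=0.2, seed=31
        )
        agree = np.mean(
            [
                np.mean(assign_states(tm).states == gt.states)
                for tm, gt in zip(unbend_layout(movie, layout), truth)
            ]
        )
        assert agree >= 0.99

    def test_breakage_rendered_in_exactly_one_frame(self):
        rates = pw.RingKineticRates(q_nucleate=0.0)
        trajs = pw.simulate_ensemble(rates, 5, 20.0, seed=32)
        truth = [pw.trajectory_to_state_matrix(t, 100, 0.2) for t in trajs]
        n_breaks = sum(
            1 for t in trajs for e in t.events
            if e.kind is pw.EventKind.BREAK_OPEN and e.time < 20.0
        )
        open_cells = sum(int((sm.states == CellState.OPEN).sum()) for sm in truth)
        # two flanking sectors per breakage, modulo rare same-frame overlaps
        assert open_cells <= 2 * n_breaks
        assert open_cells >= 2 * n_breaks * 0.9

    def test_seed_determinism_bitwise(self, preset_rates):
        trajs = pw.simulate_ensemble(preset_rates, 3, 10.0, seed=33)
        layout = make_hex_layout(3)
        a, _ = render_movie(layout, trajs, pw.HeightConventions(), seed=34)
        b, _ = render_movie(layout, trajs, pw.HeightConventions(), seed=34)
        assert a.frames.tobytes() == b.frames.tobytes()

    def test_noise_residuals_are_gaussian_with_configured_sigma(self, quiet_conv):
        layout = make_hex_layout(3)
        trajs = [still_ring_trajectory(i) for i in range(3)]
        clean, _ = render_movie(layout, trajs, quiet_conv, n_frames=3)
        noisy, _ = render_movie(
            layout, trajs, pw.HeightConventions(noise_sigma=0.3), n_frames=3, seed=35
        )
        resid = (noisy.frames - clean.frames).ravel()
        sample = np.random.default_rng(36).choice(resid, size=4999, replace=False)
        assert stats.shapiro(sample).pvalue > 0.01
        assert np.std(resid) == pytest.approx(0.3, rel=0.02)

    def test_trajectory_count_mismatch_raises(self, quiet_conv):
        layout = make_hex_layout(3)
        with pytest.raises(ValueError):
            render_movie(layout, [still_ring_trajectory()], quiet_conv, n_frames=2)


class TestSectorConvention:
    def test_unbending_localizes_single_pore_sector(self, quiet_conv):
        layout = make_hex_layout(1)
        for sector in (0, 3, 9, 15):
            tr = pw.RingTrajectory(
                events=[
                    pw.kmc.Event(0.001, pw.EventKind.TO_II, sector),
                    pw.kmc.Event(0.002, pw.EventKind.TO_PORE, sector),
                ],
                ring_id=0,
                t_end=0.4,
            )
            movie, _ = render_movie(layout, [tr], quiet_conv, n_frames=2)
            tm = unbend_ring(movie, layout.centers[0], 10.0)
            elevated = np.where(tm.heights[1] > 8.1 + 1.0)[0]
            np.testing.assert_array_equal(elevated, [sector])
            assert tm.heights[1, sector] == pytest.approx(11.9, abs=1e-5)

    def test_rotating_states_by_one_sector_shifts_columns_by_one(self, quiet_conv):
        layout = make_hex_layout(1)
        base = pw.RingTrajectory(
            events=[
                pw.kmc.Event(0.001, pw.EventKind.TO_II, 4),
                pw.kmc.Event(0.002, pw.EventKind.TO_PORE, 4),
            ],
            ring_id=0, t_end=0.4,
        )
        rot = pw.RingTrajectory(
            events=[
                pw.kmc.Event(0.001, pw.EventKind.TO_II, 5),
                pw.kmc.Event(0.002, pw.EventKind.TO_PORE, 5),
            ],
            ring_id=0, t_end=0.4,
        )
        m1, _ = render_movie(layout, [base], quiet_conv, n_frames=2)
        m2, _ = render_movie(layout, [rot], quiet_conv, n_frames=2)
        t1 = unbend_ring(m1, layout.centers[0], 10.0).heights[1]
        t2 = unbend_ring(m2, layout.centers[0], 10.0).heights[1]
        np.testing.assert_allclose(np.roll(t1, 1), t2, atol=1e-5)


class TestRenderKymograph:
    def test_plateau_dwell_is_exact_by_construction(self, quiet_conv):
        t1 = 0.2
        t2 = t1 + 1.6 / 47.3 + 0.075
        _, gt = render_kymograph(
            [(CellState.PRE_I, 0.0), (CellState.PRE_II, t1), (CellState.PORE, t2)],
            conv=quiet_conv,
        )
        assert gt.dwell_II == pytest.approx(0.075, abs=1e-12)

    def test_ramp_durations_match_dh_over_v(self, quiet_conv):
        t1 = 0.2
        t2 = t1 + 1.6 / 47.3 + 0.075
        _, gt = render_kymograph(
            [(CellState.PRE_I, 0.0), (CellState.PRE_II, t1), (CellState.PORE, t2)],
            conv=quiet_conv,
        )
        assert gt.ramp1[1] - gt.ramp1[0] == pytest.approx(1.6 / 47.3, abs=1e-12)  # ~34 ms
        assert gt.ramp2[1] - gt.ramp2[0] == pytest.approx(2.2 / 48.0, abs=1e-12)  # ~46 ms

    def test_negative_dwell_raises(self, quiet_conv):
        with pytest.raises(ValueError, match="negative dwell"):
            render_kymograph(
                [(CellState.PRE_I, 0.0), (CellState.PRE_II, 0.2), (CellState.PORE, 0.21)],
                conv=quiet_conv,
            )

    def test_center_trace_levels(self, quiet_conv):
        kymo, gt = render_kymograph(
            [(CellState.PRE_I, 0.0), (CellState.PRE_II, 0.2), (CellState.PORE, 0.35)],
            conv=quiet_conv, duration=0.6,
        )
        trace = pw.extract_trace(kymo, width=3)
        assert trace[0] == pytest.approx(8.1, abs=1e-5)
        assert trace[-1] == pytest.approx(11.9, abs=1e-5)
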