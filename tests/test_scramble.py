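"""Angle traces, event detection, rates, density path, Poisson test."""

import numpy as np
import pytest

from memscramble.errors import DensityPathError, MemscrambleError
from memscramble.membrane import DensityGrid
from memscramble.scramble import (
    AngleTrace,
    build_density_path,
    classify_events,
    compute_angle_traces,
    detect_events,
    estimate_rate,
    poisson_interval_test,
)
from memscramble.synthgen import (
    BilayerSpec,
    Flip,
    FlipSchedule,
    add_protein_scaffold,
    apply_flips,
    make_bilayer,
)
from memscramble.trajio import LipidRecord, Topology, Trajectory


def _one_lipid_traj(nc3, c4a, c4b):
    """Single-frame, single-lipid trajectory with explicit bead positions."""
    coords = np.zeros((1, 6, 3))
    coords[0, 0] = nc3
    coords[0, 1] = (0.0, 0.0, 5.0)  # PO4 (unused here)
    coords[0, 2] = (0.5, 0.0, 0.0)  # GL1
    coords[0, 3] = (-0.5, 0.0, 0.0)  # GL2
    coords[0, 4] = c4a
    coords[0, 5] = c4b
    top = Topology(
        n_beads=6,
        bead_names=["NC3", "PO4", "GL1", "GL2", "C4A", "C4B"],
        lipids=[LipidRecord(0, {r: i for i, r in enumerate(
            ("NC3", "PO4", "GL1", "GL2", "C4A", "C4B"))})],
    )
    return Trajectory(coords, np.array([0.0]), np.array([50.0, 50.0, 50.0]),
                      top)


class TestAngleTraces:
    @pytest.mark.parametrize(
        "nc3,c4a,c4b,expected",
        [
            ((0, 0, 10), (0, 0, 0), (0, 0, 0), 180.0),
            ((0, 0, 0), (0, 0, 10), (0, 0, 10), 0.0),
            ((0, 0, 0), (10, 0, -10), (-10, 0, -10), 180.0),
            ((0, 0, 0), (10, 0, 10), (-10, 0, 10), 0.0),
        ],
    )
    def test_hand_computed_angles(self, nc3, c4a, c4b, expected):
        traj = _one_lipid_traj(nc3, c4a, c4b)
        traces = compute_angle_traces(traj)
        assert traces[0].theta[0] == pytest.approx(expected, abs=1e-9)

    def test_degenerate_vector_raises(self):
        traj = _one_lipid_traj((0, 0, 0), (5, 0, 0), (-5, 0, 0))
        with pytest.raises(MemscrambleError, match="degenerate"):
            compute_angle_traces(traj)

    def test_z_mirror_maps_theta_to_supplement(self, small_bilayer):
        mirrored = small_bilayer.copy()
        mirrored.coords[..., 2] *= -1
        a = compute_angle_traces(small_bilayer)
        b = compute_angle_traces(mirrored)
        for ta, tb in zip(a, b):
            assert np.allclose(ta.theta + tb.theta, 180.0, atol=1e-9)

    def test_smoothed_trace_defined_everywhere(self, small_bilayer):
        for tr in compute_angle_traces(small_bilayer, window_ns=100.0):
            assert np.all(np.isfinite(tr.theta_smooth))
            assert len(tr.theta_smooth) == small_bilayer.n_frames


def _trace_from_angles(angles, lipid_id=0):
    a = np.asarray(angles, dtype=float)
    t = np.arange(len(a), dtype=float)
    return AngleTrace(lipid_id, t, a, a)  # already-smoothed synthetic trace


class TestDetectEvents:
    def test_monotone_crossing_counts_once(self):
        tr = _trace_from_angles(np.linspace(150, 30, 121))
        events = detect_events([tr])
        assert len(events) == 1
        ev = events[0]
        assert ev.direction == "upper_to_lower"
        # completion at the first frame at or below 35 degrees
        assert tr.theta_smooth[ev.i_complete] <= 35.0
        assert tr.theta_smooth[ev.i_complete - 1] > 35.0

    def test_partial_transition_not_counted(self):
        tr = _trace_from_angles(
            np.concatenate([np.linspace(150, 60, 50), np.linspace(60, 150, 50)])
        )
        assert detect_events([tr]) == []

    def test_round_trip_counts_two_events(self):
        tr = _trace_from_angles(
            np.concatenate([np.linspace(150, 30, 60), np.linspace(30, 150, 60)])
        )
        events = detect_events([tr])
        assert [e.direction for e in events] == [
            "upper_to_lower", "lower_to_upper",
        ]

    def test_transition_window_opens_at_reference_angle(self):
        angles = np.concatenate(
            [np.full(20, 155.0), np.linspace(155, 30, 40), np.full(10, 30.0)]
        )
        ev = detect_events([_trace_from_angles(angles)])[0]
        # entry = last frame at or above 150 before completion
        assert angles[ev.i_entry] >= 150.0
        assert angles[ev.i_entry + 1] < 150.0

    def test_event_count_invariant_under_rigid_motion(self):
        spec = BilayerSpec(lipids_per_leaflet=9, box_xy=40.0,
                           noise_sigma=0.5, seed=8)
        traj = make_bilayer(spec, 700)
        traj = apply_flips(
            traj, FlipSchedule(flips=[Flip(2, 200.0, direction="down")])
        )
        moved = traj.copy()
        theta = np.radians(37.0)
        rot = np.array(
            [[np.cos(theta), -np.sin(theta), 0],
             [np.sin(theta), np.cos(theta), 0],
             [0, 0, 1.0]]
        )
        moved.coords = moved.coords @ rot.T + np.array([11.0, -4.0, 2.5])
        e0 = detect_events(compute_angle_traces(traj))
        e1 = detect_events(compute_angle_traces(moved))
        assert len(e0) == len(e1) == 1
        assert e0[0].direction == e1[0].direction

    def test_z_mirror_swaps_directions_preserves_count(self):
        spec = BilayerSpec(lipids_per_leaflet=9, box_xy=40.0,
                           noise_sigma=0.5, seed=9)
        traj = make_bilayer(spec, 900)
        traj = apply_flips(
            traj,
            FlipSchedule(flips=[Flip(2, 150.0, direction="down"),
                                Flip(12, 400.0, direction="up")]),
        )
        mirrored = traj.copy()
        mirrored.coords[..., 2] *= -1
        e0 = detect_events(compute_angle_traces(traj))
        e1 = detect_events(compute_angle_traces(mirrored))
        assert len(e0) == len(e1) == 2
        swap = {"upper_to_lower": "lower_to_upper",
                "lower_to_upper": "upper_to_lower"}
        assert sorted(swap[e.direction] for e in e0) == sorted(
            e.direction for e in e1
        )


class TestEstimateRate:
    def test_uniform_220_events_in_9us(self):
        times = 1000.0 + np.arange(220) * (9000.0 / 220)
        r = estimate_rate(times, 1000.0, 10000.0)
        assert round(r.mean_rate, 1) == 24.4
        assert r.counts.sum() == 220

    def test_zero_events(self):
        r = estimate_rate([], 1000.0, 10000.0)
        assert r.mean_rate == 0.0 and r.sd == 0.0

    def test_one_event_per_block_zero_variance(self):
        times = 1000.0 + 500.0 + 1000.0 * np.arange(9)
        r = estimate_rate(times, 1000.0, 10000.0)
        assert r.mean_rate == 1.0 and r.sd == 0.0

    def test_mean_equals_tiled_count_over_duration(self):
        rng = np.random.default_rng(3)
        times = np.sort(rng.uniform(0.0, 7400.0, 57))
        r = estimate_rate(times, 0.0, 7400.0)  # 7 full blocks
        tiled = times[times < 7000.0]
        assert r.mean_rate == pytest.approx(len(tiled) / 7.0)

    def test_too_short_window_raises(self):
        with pytest.raises(MemscrambleError):
            estimate_rate([1.0], 0.0, 500.0)


class TestPoissonIntervalTest:
    def test_regular_stream_rejected_as_underdispersed(self):
        times = np.arange(0.0, 9000.0, 100.0)  # exactly 10 per block
        res = poisson_interval_test(times, 0.0, 9000.0)
        assert res.dispersion == pytest.approx(0.0)
        assert res.pvalue < 0.05

    def test_clustered_stream_rejected_as_overdispersed(self):
        times = np.linspace(100.0, 900.0, 90)  # all events in block 1 of 9
        res = poisson_interval_test(times, 0.0, 9000.0)
        assert res.dispersion > 1.0
        assert res.pvalue < 0.05

    def test_insufficient_events_flagged(self):
        res = poisson_interval_test([1.0, 2.0], 0.0, 9000.0)
        assert not res.sufficient
        assert np.isnan(res.pvalue)


class TestDensityPath:
    def _grid(self, counts):
        return DensityGrid(origin=np.array([0.0, 0.0, -10.0]), spacing=0.5,
                           counts=counts, n_frames=1)

    def test_single_column_gives_vertical_line(self):
        counts = np.zeros((40, 40, 40))
        counts[14, 22, :] = 5.0
        path = build_density_path(self._grid(counts), (-10, 10),
                                  smooth_slabs=1)
        assert np.allclose(path[:, 0], 14 * 0.5 + 0.25)
        assert np.allclose(path[:, 1], 22 * 0.5 + 0.25)
        assert path[0, 2] > path[-1, 2]  # ordered top to bottom

    def test_helical_ridge_recovered_within_one_voxel(self):
        counts = np.zeros((60, 60, 40))
        zc = -10.0 + (np.arange(40) + 0.5) * 0.5
        cx, cy, r = 15.0, 15.0, 5.0
        for iz, z in enumerate(zc):
            phi = 2 * np.pi * (z + 10) / 20.0
            x, y = cx + r * np.cos(phi), cy + r * np.sin(phi)
            counts[int(x / 0.5), int(y / 0.5), iz] = 10.0
        path = build_density_path(self._grid(counts), (-10, 10),
                                  smooth_slabs=1)
        for p in path:
            phi = 2 * np.pi * (p[2] + 10) / 20.0
            ref = np.array([cx + r * np.cos(phi), cy + r * np.sin(phi)])
            assert np.linalg.norm(p[:2] - ref) <= 0.5 * np.sqrt(2) + 1e-9

    def test_uniform_density_tie_warns_lowest_index(self):
        counts = np.ones((10, 10, 8))
        with pytest.warns(UserWarning, match="tie"):
            path = build_density_path(self._grid(counts), (-10, 10),
                                      smooth_slabs=1)
        assert np.allclose(path[:, 0], 0.25)  # lowest voxel index

    def test_empty_gap_interpolated(self):
        counts = np.zeros((20, 20, 12))
        counts[4, 4, :4] = 1.0
        counts[8, 8, 8:] = 1.0  # middle layers empty
        path = build_density_path(self._grid(counts), (-10, -4.1),
                                  smooth_slabs=1)
        assert np.all(np.isfinite(path))

    def test_all_empty_raises(self):
        counts = np.zeros((10, 10, 8))
        with pytest.raises(DensityPathError):
            build_density_path(self._grid(counts), (-10, 10))


class TestClassifyEvents:
    def test_boundary_at_cutoff_is_in_groove(self):
        spec = BilayerSpec(lipids_per_leaflet=16, box_xy=48.0,
                           noise_sigma=0.0, lateral_sigma=0.0, seed=0)
        traj = make_bilayer(spec, 600)
        traj = add_protein_scaffold(traj, groove_center=(24.0, 24.0),
                                    groove_width=8.0)
        # flip path offset so the PO4 bead passes exactly 4.7 A from the line
        path = [(24.0, 24.0, 15.0), (24.0, 24.0, -15.0)]
        traj = apply_flips(
            traj, FlipSchedule(flips=[Flip(2, 200.0, direction="down",
                                           path=path)])
        )
        events = detect_events(compute_angle_traces(traj))
        assert len(events) == 1
        ev = events[0]
        po4 = traj.topology.lipid(ev.lipid_id).beads["PO4"]
        mid = (ev.i_entry + ev.i_complete) // 2
        p = traj.coords[mid, po4]
        # a pathway point displaced 4.7 A in y from the mid-window PO4
        # position: the window minimum distance is then exactly the cutoff
        polyline = np.array([[p[0], p[1] + 4.7, p[2]]])
        labelled = classify_events(events, traj, polyline, cutoff=4.7)
        assert labelled[0].min_path_dist == pytest.approx(4.7, abs=1e-12)
        assert labelled[0].pathway == "in_groove"
        # a hair beyond the cutoff flips the label
        beyond = classify_events(
            events, traj, polyline + np.array([0.0, 1e-6, 0.0]), cutoff=4.7
        )
        assert beyond[0].pathway == "out_of_groove"
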