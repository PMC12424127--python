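"""Migration metrics against hand-computed and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chemokin.migration import (
    aggregate_by_experiment,
    burst_speed,
    flower_transform,
    line_speed_to_tip,
    migration_efficiency,
    msd,
    path_length,
    radial_bin,
    speed,
    straightness,
)
from chemokin.walks import Trajectory

from conftest import make_track

TIP = (0.0, 0.0)


def brute_force_metrics(track, tip):
    """Independent segment-by-segment oracle (plain python loops)."""
    import math

    path = 0.0
    for i in range(len(track) - 1):
        dx = track.positions[i + 1, 0] - track.positions[i, 0]
        dy = track.positions[i + 1, 1] - track.positions[i, 1]
        path += math.hypot(dx, dy)
    r_first = math.hypot(track.positions[0, 0] - tip[0],
                         track.positions[0, 1] - tip[1])
    r_last = math.hypot(track.positions[-1, 0] - tip[0],
                        track.positions[-1, 1] - tip[1])
    elapsed_min = (track.times[-1] - track.times[0]) / 60.0
    return {
        "path": path,
        "efficiency": (r_first - r_last) / path,
        "speed": path / elapsed_min,
        "line_speed": (r_first - r_last) / elapsed_min,
    }


def random_track(rng, n=25):
    return Trajectory(
        cell_id=0,
        times=np.arange(n) * 15.0,
        positions=rng.uniform(-400, 400, size=(n, 2)),
    )


class TestEfficiency:
    def test_straight_radial_approach(self):
        tr = make_track([(0.0, 300.0), (0.0, 100.0)])
        assert migration_efficiency(tr, TIP) == pytest.approx(1.0)

    def test_hand_computed_elbow(self):
        # (0,300) -> (0,200) -> (100,200): net approach 76.39 over 200 um
        tr = make_track([(0.0, 300.0), (0.0, 200.0), (100.0, 200.0)])
        expected = (300.0 - np.hypot(100.0, 200.0)) / 200.0
        assert expected == pytest.approx(0.382, abs=5e-4)
        assert migration_efficiency(tr, TIP) == pytest.approx(expected)

    def test_closed_loop_zero(self):
        tr = make_track([(0.0, 300.0), (50.0, 300.0), (50.0, 250.0),
                         (0.0, 250.0), (0.0, 300.0)])
        assert migration_efficiency(tr, TIP) == pytest.approx(0.0)

    def test_stationary_excluded(self):
        tr = make_track([(10.0, 10.0), (10.0, 10.0)])
        with pytest.raises(ValueError):
            migration_efficiency(tr, TIP)

    def test_positive_steps_mode_bounds_net(self, rng):
        for _ in range(20):
            tr = random_track(rng)
            assert migration_efficiency(tr, TIP, "positive_steps") >= (
                migration_efficiency(tr, TIP, "net") - 1e-12
            )


class TestSpeedFamily:
    def test_straight_speed(self):
        tr = make_track([(0.0, 0.0), (100.0, 0.0)], dt=600.0)
        assert speed(tr) == pytest.approx(10.0)

    def test_zigzag_uses_path_not_displacement(self):
        pts = [(0.0, 0.0), (50.0, 0.0), (0.0, 0.0), (50.0, 0.0), (0.0, 0.0)]
        tr = make_track(pts, dt=150.0)
        assert speed(tr) == pytest.approx(20.0)

    def test_line_speed_radial(self):
        tr = make_track([(0.0, 300.0), (0.0, 100.0)], dt=600.0)
        assert line_speed_to_tip(tr, TIP) == pytest.approx(20.0)

    def test_line_speed_constant_radius_arc(self):
        ang = np.linspace(0.0, np.pi / 2, 10)
        tr = make_track(np.column_stack([200 * np.cos(ang), 200 * np.sin(ang)]))
        assert line_speed_to_tip(tr, TIP) == pytest.approx(0.0, abs=1e-9)

    def test_burst_speed_is_max_step(self):
        tr = make_track([(0.0, 0.0), (1.0, 0.0), (4.0, 0.0), (5.0, 0.0)], dt=60.0)
        assert burst_speed(tr) == pytest.approx(3.0)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            tr = random_track(rng)
            ref = brute_force_metrics(tr, TIP)
            assert path_length(tr) == pytest.approx(ref["path"], rel=1e-12)
            assert speed(tr) == pytest.approx(ref["speed"], rel=1e-12)
            assert migration_efficiency(tr, TIP) == pytest.approx(
                ref["efficiency"], rel=1e-12
            )
            assert line_speed_to_tip(tr, TIP) == pytest.approx(
                ref["line_speed"], rel=1e-12
            )

    def test_identity_efficiency_times_speed(self, rng):
        for _ in range(100):
            tr = random_track(rng)
            lhs = migration_efficiency(tr, TIP) * speed(tr)
            assert lhs == pytest.approx(line_speed_to_tip(tr, TIP), rel=1e-9)


class TestStraightness:
    def test_straight_line_any_direction(self):
        tr = make_track([(10.0, 20.0), (110.0, 220.0)])
        assert straightness(tr) == pytest.approx(1.0)

    def test_closed_loop(self):
        tr = make_track([(0.0, 0.0), (50.0, 0.0), (50.0, 50.0), (0.0, 0.0)])
        assert straightness(tr) == pytest.approx(0.0, abs=1e-12)

    def test_right_angle(self):
        tr = make_track([(0.0, 0.0), (100.0, 0.0), (100.0, 100.0)])
        assert straightness(tr) == pytest.approx(np.sqrt(2) / 2)


class TestMsd:
    def test_ballistic_quadratic(self):
        v = 2.0  # um/s
        tr = make_track([(v * 15 * i, 0.0) for i in range(10)])
        curve = msd([tr] * 5)
        np.testing.assert_allclose(curve["msd_um2"], (v * curve["lag_s"]) ** 2)

    def test_single_step_track(self):
        tr = make_track([(0.0, 0.0), (3.0, 4.0)])
        curve = msd([tr] * 5)
        assert len(curve) == 1
        assert curve["msd_um2"].iloc[0] == pytest.approx(25.0)

    def test_min_cells_per_lag(self):
        long = make_track([(float(i), 0.0) for i in range(10)])
        short = make_track([(float(i), 0.0) for i in range(3)])
        curve = msd([long] * 4 + [short] * 4, min_cells=5)
        # lags beyond the short tracks have only 4 contributors
        assert curve["lag_s"].max() == pytest.approx(2 * 15.0)

    def test_mixed_intervals_rejected(self):
        a = make_track([(0.0, 0.0), (1.0, 0.0)], dt=15.0)
        b = make_track([(0.0, 0.0), (1.0, 0.0)], dt=10.0)
        with pytest.raises(ValueError):
            msd([a] * 5 + [b] * 5)


class TestBinningAndAggregation:
    def test_half_open_bins(self):
        tr150 = make_track([(150.0, 0.0), (150.0, 1.0)])
        tr200 = make_track([(200.0, 0.0), (200.0, 1.0)], cell_id=1)
        tr80 = make_track([(80.0, 0.0), (80.0, 1.0)], cell_id=2)
        out = radial_bin([tr150, tr200, tr80], TIP)
        assert list(out["bin"]) == ["100-200", "200-300", "out_of_range"]

    def test_bad_edges_rejected(self):
        tr = make_track([(150.0, 0.0), (150.0, 1.0)])
        with pytest.raises(ValueError):
            radial_bin([tr], TIP, edges=(200.0, 100.0))

    def test_sem_of_two_experiments(self):
        df = pd.DataFrame(
            {"experiment": [0, 1], "bin": ["100-200"] * 2, "efficiency": [0.2, 0.4]}
        )
        out = aggregate_by_experiment(df, ["efficiency"])
        assert out["mean"].iloc[0] == pytest.approx(0.3)
        assert out["sem"].iloc[0] == pytest.approx(0.1)
        assert out["n_experiments"].iloc[0] == 2

    def test_single_experiment_sem_undefined(self):
        df = pd.DataFrame(
            {"experiment": [0, 0], "bin": ["100-200"] * 2, "efficiency": [0.2, 0.4]}
        )
        out = aggregate_by_experiment(df, ["efficiency"])
        assert np.isnan(out["sem"].iloc[0])

    def test_cell_imbalance_does_not_weight_mean(self):
        # experiment 0 has 10 cells at 0.2; experiment 1 one cell at 0.4
        df = pd.DataFrame(
            {
                "experiment": [0] * 10 + [1],
                "bin": ["100-200"] * 11,
                "efficiency": [0.2] * 10 + [0.4],
            }
        )
        out = aggregate_by_experiment(df, ["efficiency"])
        assert out["mean"].iloc[0] == pytest.approx(0.3)


class TestFlowerTransform:
    def test_tip_maps_to_origin(self):
        tip = (422.5, 422.5)
        tr = make_track([tip, (500.0, 500.0)])
        (out,) = flower_transform([tr], tip)
        np.testing.assert_allclose(out.positions[0], (0.0, 0.0))

    def test_rigid_translation_preserves_distances(self, rng):
        tr = random_track(rng)
        (out,) = flower_transform([tr], (123.0, -45.0))
        d_in = np.linalg.norm(np.diff(tr.positions, axis=0), axis=1)
        d_out = np.linalg.norm(np.diff(out.positions, axis=0), axis=1)
        np.testing.assert_allclose(d_in, d_out, rtol=1e-12)

    def test_inverse_restores_originals(self, rng):
        tr = random_track(rng)
        (fwd,) = flower_transform([tr], (37.0, 91.0))
        (back,) = flower_transform([fwd], (-37.0, -91.0))
        np.testing.assert_allclose(back.positions, tr.positions, atol=1e-12)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    angle=st.floats(0.0, 2 * np.pi),
    shift=st.tuples(st.floats(-500, 500), st.floats(-500, 500)),
)
def test_metrics_invariant_under_rigid_motion(angle, shift):
    """Rotating and translating tracks and tip together changes nothing."""
    rng = np.random.default_rng(7)
    tr = random_track(rng)
    tip = np.array([50.0, -20.0])
    rot = np.array(
        [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
    )
    moved = Trajectory(
        cell_id=0,
        times=tr.times.copy(),
        positions=tr.positions @ rot.T + shift,
    )
    tip_moved = rot @ tip + np.asarray(shift)
    assert migration_efficiency(moved, tip_moved) == pytest.approx(
        migration_efficiency(tr, tip), rel=1e-9, abs=1e-9
    )
    assert speed(moved) == pytest.approx(speed(tr), rel=1e-9)
    assert straightness(moved) == pytest.approx(straightness(tr), rel=1e-9)
    # straightness and speed do not depend on the tip at all
    assert straightness(moved) == pytest.approx(straightness(tr), rel=1e-9)
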