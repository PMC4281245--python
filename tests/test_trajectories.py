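"""Trajectory metrics, exclusion cascades and the synthetic fixture generator."""

import math

import numpy as np
import pandas as pd
import pytest

import scfield as sf
from scfield.trajectories import (
    SAMPLE_INTERVAL_MS,
    TooShortError,
    ZeroAmplitudeError,
    MissingBaselineError,
    frames_to_trajectories,
    trajectories_to_frames,
)


def _traj(points, target_dir=0.0, side="left", pad=0):
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    t = np.arange(n + 2 * pad) * SAMPLE_INTERVAL_MS
    x = np.concatenate([np.full(pad, pts[0, 0]), pts[:, 0], np.full(pad, pts[-1, 0])])
    y = np.concatenate([np.full(pad, pts[0, 1]), pts[:, 1], np.full(pad, pts[-1, 1])])
    return sf.SaccadeTrajectory(
        t, x, y, start_index=pad, end_index=pad + n - 1,
        target_dir_deg=target_dir, distractor_side=side,
    )


class TestInitialDirection:
    def test_simple_geometry(self):
        # start (0,0), sample 10 ms in at (1,1) -> 45 deg
        pts = [(0, 0), (0.2, 0.2), (0.4, 0.4), (0.6, 0.6), (0.8, 0.8),
               (1, 1), (2, 1.2), (3, 1.2)]
        tr = _traj(pts)
        assert sf.initial_direction(tr, ("at_time", 10.0)) == pytest.approx(45.0)

    def test_straight_saccade_recovers_target_direction(self):
        th = math.radians(30.0)
        pts = [(r * math.cos(th), r * math.sin(th)) for r in np.linspace(0, 10, 21)]
        tr = _traj(pts, target_dir=30.0)
        for rule in (("at_time", 10.0), ("at_fraction", 0.2)):
            assert sf.initial_direction(tr, rule) == pytest.approx(30.0, abs=1e-9)

    def test_fraction_rule_index_arithmetic(self):
        # 40 ms saccade at 500 Hz: the 20%-of-duration rule lands 8 ms in,
        # i.e. on the 5th sample (index 4)
        pts = [(i, 0.0 if i != 4 else 0.0) for i in range(21)]
        pts[4] = (4.0, 1.0)  # only sample 4 is displaced
        tr = _traj(pts)
        d = sf.initial_direction(tr, ("at_fraction", 0.2))
        assert d == pytest.approx(math.degrees(math.atan2(1.0, 4.0)))

    def test_too_short_raises(self):
        tr = _traj([(0, 0), (1, 0), (2, 0)])
        with pytest.raises(TooShortError):
            sf.initial_direction(tr, ("at_time", 50.0))


class TestMaxCurvature:
    def test_collinear_is_zero(self):
        tr = _traj([(0, 0), (1, 0), (2, 0), (3, 0)])
        assert sf.max_curvature(tr) == 0.0

    def test_triangle_apex(self):
        # apex 1 deg above the straight path; distractor on the left (above)
        tr = _traj([(0, 0), (1, 1), (2, 0)], side="left")
        assert sf.max_curvature(tr) == pytest.approx(1.0)
        assert sf.max_curvature(tr, normalize=True) == pytest.approx(0.5)

    def test_sign_follows_distractor_side(self):
        tr = _traj([(0, 0), (1, 1), (2, 0)], side="right")
        assert sf.max_curvature(tr) == pytest.approx(-1.0)

    def test_tie_resolved_to_earliest_sample(self):
        tr = _traj([(0, 0), (1, 1), (2, -1), (3, 0)], side="left")
        # both excursions have |distance| 1; the first (positive) one wins
        assert sf.max_curvature(tr) == pytest.approx(1.0)

    def test_degenerate_raises(self):
        tr = _traj([(0, 0), (1, 1), (0, 0)])
        with pytest.raises(ZeroAmplitudeError):
            sf.max_curvature(tr)

    def test_rotation_invariance(self):
        """Rotating trajectory and target direction together leaves both
        deviation measures unchanged."""
        base = sf.generate_fixture(1, deviation_deg=4.0, curvature_deg=1.2,
                                   noise_sd=0.0, target_dir_deg=75.0)[0]
        for rot in (33.0, -120.0):
            th = math.radians(rot)
            c, s = math.cos(th), math.sin(th)
            rotated = sf.SaccadeTrajectory(
                base.t_ms,
                c * base.x_deg - s * base.y_deg,
                s * base.x_deg + c * base.y_deg,
                base.start_index, base.end_index,
                base.target_dir_deg + rot, base.distractor_side,
            )
            assert sf.max_curvature(rotated) == pytest.approx(
                sf.max_curvature(base), abs=1e-9
            )
            d0 = sf.initial_direction(base, ("at_time", 10.0)) - base.target_dir_deg
            d1 = (
                sf.initial_direction(rotated, ("at_time", 10.0))
                - rotated.target_dir_deg
            )
            assert (d1 - d0 + 180) % 360 - 180 == pytest.approx(0.0, abs=1e-9)


class TestReferenceToBaseline:
    def test_value_at_baseline_mean_is_zero(self):
        out = sf.reference_to_baseline([2.0], [1.0, 2.0, 3.0])
        assert out[0] == pytest.approx(0.0)

    def test_subtraction(self):
        out = sf.reference_to_baseline([5.0], [2.0, 2.0])
        assert out[0] == pytest.approx(3.0)

    def test_empty_baseline_raises(self):
        with pytest.raises(MissingBaselineError):
            sf.reference_to_baseline([1.0], [])


class TestFixtureRecovery:
    def test_noiseless_curvature_recovery(self):
        tr = sf.generate_fixture(1, deviation_deg=5.0, curvature_deg=1.0,
                                 noise_sd=0.0)[0]
        assert sf.max_curvature(tr) == pytest.approx(1.0, abs=1e-6)

    def test_noiseless_deviation_recovery(self):
        tr = sf.generate_fixture(1, deviation_deg=5.0, curvature_deg=1.0,
                                 noise_sd=0.0)[0]
        for rule in (("at_time", 10.0), ("at_fraction", 0.2)):
            measured = sf.initial_direction(tr, rule) - tr.target_dir_deg
            assert measured == pytest.approx(5.0, abs=1e-6)

    def test_right_side_flips_screen_sign_not_toward_sign(self):
        tr = sf.generate_fixture(1, deviation_deg=5.0, curvature_deg=1.0,
                                 noise_sd=0.0, distractor_side="right")[0]
        measured = sf.initial_direction(tr, ("at_time", 10.0)) - tr.target_dir_deg
        assert measured == pytest.approx(-5.0, abs=1e-6)  # clockwise on screen
        assert sf.max_curvature(tr) == pytest.approx(+1.0, abs=1e-6)  # toward

    def test_monte_carlo_recovery_under_noise(self):
        """With per-sample noise the mean recovered deviation stays within
        three standard errors of the generating value."""
        n = 200
        trs = sf.generate_fixture(n, deviation_deg=5.0, curvature_deg=1.0,
                                  noise_sd=0.1, seed=42)
        vals = np.array(
            [sf.initial_direction(t, ("at_time", 10.0)) - 75.0 for t in trs]
        )
        se = vals.std(ddof=1) / math.sqrt(n)
        assert abs(vals.mean() - 5.0) <= 3 * se

    def test_reproducible_per_seed(self):
        a = sf.generate_fixture(3, noise_sd=0.2, seed=9)
        b = sf.generate_fixture(3, noise_sd=0.2, seed=9)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.x_deg, tb.x_deg)
            assert np.array_equal(ta.y_deg, tb.y_deg)

    def test_tabular_round_trip(self):
        trs = sf.generate_fixture(2, noise_sd=0.05, seed=1)
        samples, meta = trajectories_to_frames(trs)
        back = frames_to_trajectories(samples, meta)
        for orig, rec in zip(trs, back):
            assert np.allclose(orig.x_deg, rec.x_deg)
            assert rec.start_index == orig.start_index
            assert rec.end_index == orig.end_index


def _records(**overrides):
    base = dict(
        srt_ms=[200.0] * 6,
        start_offset_deg=[0.5] * 6,
        initial_dir_deg=[75.0] * 6,
        target_dir_deg=[75.0] * 6,
        dir_dev_deg=[0.0] * 6,
        cell=["a"] * 6,
    )
    base.update(overrides)
    return pd.DataFrame(base)


class TestApplyFilters:
    def test_fast_response_excluded(self):
        rec = _records(srt_ms=[79.0, 80.0, 200.0, 500.0, 501.0, 300.0])
        kept, counts = sf.apply_filters(rec, experiment=1)
        assert counts["srt"] == 2  # 79 ms (< 80) and 501 ms (> 500)
        assert len(kept) == 4

    def test_experiment2_srt_window_wider(self):
        rec = _records(srt_ms=[79.0, 80.0, 200.0, 540.0, 551.0, 300.0])
        kept, counts = sf.apply_filters(rec, experiment=2)
        assert counts["srt"] == 2  # 79 and 551; 540 survives the 550 cutoff

    def test_start_point_tolerance(self):
        rec = _records(start_offset_deg=[1.6, 1.5, 0.1, 0.2, 0.3, 0.4])
        kept, counts = sf.apply_filters(rec, experiment=1)
        assert counts["start"] == 1  # only the 1.6 deg start point
        rec2 = _records(start_offset_deg=[1.9, 2.1, 0.1, 0.2, 0.3, 0.4])
        kept2, counts2 = sf.apply_filters(rec2, experiment=2)
        assert counts2["start"] == 1  # exp 2 tolerance is 2.0 deg

    def test_direction_tolerance(self):
        rec = _records(initial_dir_deg=[75.0, 106.0, 44.0, 75.0, 75.0, 75.0])
        kept, counts = sf.apply_filters(rec, experiment=1)
        assert counts["direction"] == 2  # 31 deg off in both directions

    def test_sd_outlier_rule(self):
        rec = _records(
            srt_ms=[200.0] * 5, start_offset_deg=[0.5] * 5,
            initial_dir_deg=[75.0] * 5, target_dir_deg=[75.0] * 5,
            dir_dev_deg=[0.0, 0.0, 0.0, 0.0, 100.0], cell=["a"] * 5,
        )
        kept, counts = sf.apply_filters(rec, experiment=2)
        assert counts["outlier"] == 1
        assert 100.0 not in kept["dir_dev_deg"].to_numpy()

    def test_outlier_rule_runs_on_survivors(self):
        # the extreme value is already excluded by the SRT rule, so the
        # remaining cell is clean and the outlier rule fires on nothing
        rec = _records(
            srt_ms=[200.0, 200.0, 200.0, 200.0, 200.0, 60.0],
            dir_dev_deg=[0.0, 0.1, -0.1, 0.05, -0.05, 100.0],
        )
        kept, counts = sf.apply_filters(rec, experiment=2)
        assert counts["srt"] == 1
        assert counts["outlier"] == 0

    def test_record_carries_every_flag_it_triggers(self):
        # one record violates both the SRT and the start-point rule; both
        # counters increment even though it can only be excluded once
        rec = _records(srt_ms=[60.0] + [200.0] * 5,
                       start_offset_deg=[2.0] + [0.5] * 5)
        kept, counts = sf.apply_filters(rec, experiment=1)
        assert counts["srt"] == 1 and counts["start"] == 1
        assert len(kept) == 5

    def test_idempotence(self):
        rng = np.random.default_rng(5)
        rec = _records(
            srt_ms=rng.uniform(50, 600, 6),
            start_offset_deg=rng.uniform(0, 2, 6),
            dir_dev_deg=rng.normal(0, 3, 6),
        )
        once, _ = sf.apply_filters(rec, experiment=2)
        twice, counts = sf.apply_filters(
            once.drop(columns="exclusion_flags"), experiment=2
        )
        assert len(twice) == len(once)
        assert counts["srt"] == counts["start"] == counts["outlier"] == 0

    def test_criteria_validation(self):
        with pytest.raises(ValueError):
            sf.FilterCriteria(srt_min_ms=500.0, srt_max_ms=80.0)
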