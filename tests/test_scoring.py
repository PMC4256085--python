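import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from notowave import (
    ModelConfig,
    StateLattice,
    find_arc,
    find_pgc,
    interval_distribution,
    landmark_intervals,
    pair_count,
    run,
    run_pair,
    totals,
    window_green_count,
    window_series,
)
from notowave.scoring import arc_series, pgc_series, pooled_intervals

S, G1 = True, False


def one_frame(states):
    """(n,1) row from a list of per-cell states."""
    return np.asarray(states, dtype=bool)[:, None]


class TestLandmarks:
    def test_pgc_arc_on_mixed_row(self):
        col = one_frame([S, S, G1, S, G1, G1])
        assert find_pgc(col, 0) == 4
        assert find_arc(col, 0) == 3

    def test_all_g1(self):
        col = one_frame([G1] * 6)
        assert find_pgc(col, 0) is None
        assert find_arc(col, 0) == 1

    def test_all_s(self):
        col = one_frame([S] * 6)
        assert find_pgc(col, 0) == 6
        assert find_arc(col, 0) is None

    @settings(max_examples=100, derandomize=True)
    @given(st.data())
    def test_landmarks_nondecreasing_on_monotone_lattices(self, data):
        # PGC/ARC positions can never move anteriorly
        n = data.draw(st.integers(2, 12))
        T = data.draw(st.integers(2, 15))
        entries = data.draw(
            st.lists(st.integers(0, T + 3), min_size=n, max_size=n)
        )
        states = np.arange(T)[None, :] >= np.asarray(entries)[:, None]
        for series in (pgc_series(states), arc_series(states)):
            vals = series[~np.isnan(series)]
            assert (np.diff(vals) >= 0).all()


class TestWindowCounts:
    def test_saturated_window(self):
        states = one_frame([S] * 8 + [G1] * 4)
        assert window_green_count(states, 0, window=8) == 8

    def test_clipped_window_counted_by_hand(self):
        # PGC=6, window clipped to positions 1..6, greens at 1,3,4,6
        states = one_frame([S, G1, S, S, G1, S, G1, G1])
        assert window_green_count(states, 0, window=8) == 4

    def test_no_pgc_returns_none(self):
        assert window_green_count(one_frame([G1, G1]), 0) is None

    def test_window_contains_its_pgc(self):
        # the PGC itself is green, so every defined count >= 1
        states, _ = run(ModelConfig(alpha_dt=0.1, z=8, seed=3))
        for t in range(states.shape[1]):
            c = window_green_count(states, t)
            if find_pgc(states, t) is not None:
                assert c >= 1

    def test_pgc_advance_without_other_transitions_adds_one(self):
        # brute force on a small lattice: only the PGC advances between frames
        before = [S, S, G1, S, G1, G1, G1, G1]
        after = [S, S, G1, S, S, G1, G1, G1]  # position 5 becomes the new PGC
        states = np.stack([before, after], axis=1)
        c0 = window_green_count(states, 0, window=8)
        c1 = window_green_count(states, 1, window=8)
        # old window clipped 1..4 greens {1,2,4}; new window 1..5 adds pos 5
        assert (c0, c1) == (3, 4)

    def test_pair_count_positional_and(self):
        upper = one_frame([S, G1, S, S, S, G1, S, S])
        lower = one_frame([S, S, G1, S, S, S, G1, S])
        lattice = StateLattice.from_rows(upper, lower)
        assert pair_count(lattice, 0, window=8) == 4

    def test_pair_count_upper_all_red_is_zero(self):
        lattice = StateLattice.from_rows(one_frame([G1] * 8), one_frame([S] * 8))
        assert pair_count(lattice, 0, window=8) == 0

    def test_pair_count_saturated(self):
        lattice = StateLattice.from_rows(one_frame([S] * 8), one_frame([S] * 8))
        assert pair_count(lattice, 0, window=8) == 8

    def test_pair_count_needs_landmark_pgc(self):
        lattice = StateLattice.from_rows(one_frame([S] * 4), one_frame([G1] * 4))
        assert pair_count(lattice, 0, landmark="lower") is None
        assert pair_count(lattice, 0, landmark="upper") == 0


class TestTotals:
    def test_partition_conservation(self):
        cfg = ModelConfig(alpha_dt=0.2, z=8, n_cells=30, t_max=50, seed=1)
        lattice, _ = run_pair(cfg)
        for t in (0, 10, 49):
            for row, (n_g1, n_s) in totals(lattice, t).items():
                assert n_g1 + n_s == cfg.n_cells

    def test_event_counting(self):
        cfg = ModelConfig(alpha_dt=0.2, z=8, n_cells=30, t_max=50, seed=2)
        lattice, truth = run_pair(cfg)
        t = 30
        for row in ("upper", "lower"):
            k = (
                truth.loc[truth["row"] == row, "entry_frame"]
                .dropna()
                .le(t)
                .sum()
            )
            assert totals(lattice, t)[row][1] == k


class TestIntervals:
    def test_advances_at_frames_1_and_3_give_interval_2(self):
        # waiting time T2 - T1 = 2
        entries = [1, 3, 99]
        states = np.arange(6)[None, :] >= np.asarray(entries)[:, None]
        np.testing.assert_array_equal(landmark_intervals(states), [2])

    def test_multicell_jump_is_one_event(self):
        entries = [1, 1, 1, 4]  # PGC jumps 1->3 at frame 1, then 3->4 at 4
        states = np.arange(6)[None, :] >= np.asarray(entries)[:, None]
        np.testing.assert_array_equal(landmark_intervals(states), [3])

    def test_never_advancing_landmark_gives_empty_list(self):
        states = np.zeros((4, 6), dtype=bool)
        assert landmark_intervals(states).size == 0

    def test_deterministic_z1_alternates_2_1(self):
        # integer frame grid vs 1.5-frame front: intervals alternate 1 and 2
        cfg = ModelConfig(alpha_dt=1.0, z=1, n_cells=30, t_max=60, seed=0)
        states, _ = run(cfg)
        iv = landmark_intervals(states)
        assert set(iv) == {1, 2}
        assert all(a != b for a, b in zip(iv, iv[1:]))

    def test_interval_sum_telescopes(self):
        cfg = ModelConfig(alpha_dt=0.1, z=16, seed=6)
        states, _ = run(cfg)
        series = pgc_series(states)
        adv = [
            t
            for t in range(1, len(series))
            if not np.isnan(series[t])
            and (np.isnan(series[t - 1]) or series[t] > series[t - 1])
        ]
        iv = landmark_intervals(states)
        first_appearance = int(np.argmax(~np.isnan(series)))
        assert iv.sum() == (adv[-1] - first_appearance if adv else 0)


class TestIntervalDistribution:
    def test_normalization_by_hand(self):
        dist = interval_distribution([2, 2, 4])
        assert dist.pmf.loc[2] == pytest.approx(2 / 3)
        assert dist.pmf.loc[4] == pytest.approx(1 / 3)
        assert dist.n_obs == 3

    def test_pooling_equals_concatenation(self):
        a, b = [1, 2, 2], [2, 3]
        assert interval_distribution(a + b).pmf.equals(
            interval_distribution(np.concatenate([a, b])).pmf
        )

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            interval_distribution([])

    def test_continuous_model_mass_concentrated_and_decreasing(self):
        # z=1 intervals sit mostly below 20 min with decreasing frequency
        cfg = ModelConfig(alpha_dt=0.1, z=1, t_max=240)
        pooled = np.concatenate(
            [
                pooled_intervals(run_pair(cfg, seed_seq=np.random.SeedSequence(s))[0])
                for s in range(10)
            ]
        )
        dist = interval_distribution(pooled)
        mass = lambda lo, hi: dist.pmf.loc[
            (dist.pmf.index >= lo) & (dist.pmf.index <= hi)
        ].sum()
        assert mass(1, 8) > 0.8
        assert mass(1, 4) > mass(5, 8) > mass(9, 12)


class TestWindowSeries:
    def test_series_shape_and_monotone_landmarks(self):
        cfg = ModelConfig(alpha_dt=0.1, z=8, n_cells=40, t_max=60, seed=5)
        lattice, _ = run_pair(cfg)
        ws = window_series(lattice)
        assert len(ws) == 2 * cfg.t_max
        for row in ("upper", "lower"):
            sub = ws[ws["row"] == row].sort_values("frame")
            for col in ("pgc", "arc"):
                vals = sub[col].dropna().to_numpy(float)
                assert (np.diff(vals) >= 0).all()

    def test_clipped_flag_marks_early_windows(self):
        cfg = ModelConfig(alpha_dt=1.0, z=1, n_cells=30, t_max=30, seed=0)
        lattice, _ = run_pair(cfg)
        ws = window_series(lattice)
        flagged = ws[ws["clipped"].astype(bool)]
        assert (flagged["pgc"].dropna() < 8).all()
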