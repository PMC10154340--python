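"""Asynchrony / IRI contracts, with a brute-force matching oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from taptiming.design import Mode, Phase, build_default_design
from taptiming.metrics import (
    asynchrony,
    asynchrony_frame,
    correct_device_delay,
    iri,
    iri_frame,
    match_taps,
    summarize,
    target_times,
)
from taptiming.simulate import sessions_to_frame, simulate_cohort

from conftest import params_by_group


class TestDeviceDelay:
    def test_hand_examples(self):
        assert list(correct_device_delay([1025.0, 2025.0], 25.0)) == [1000.0, 2000.0]
        assert list(correct_device_delay([100.0], 25.0)) == [75.0]

    def test_zero_delay_is_identity(self):
        x = [3.0, 7.0, 11.0]
        assert list(correct_device_delay(x, 0.0)) == x

    def test_negative_delay_rejected(self):
        with pytest.raises(ValueError):
            correct_device_delay([0.0], -1.0)


class TestTargets:
    def test_synchronized_beats(self):
        d = build_default_design(pacing_cycles=3, continuation_cycles=1)
        assert list(target_times(d, Mode.SYNCHRONIZED)) == [0.0, 1000.0, 2000.0, 3000.0]

    def test_syncopated_midpoints(self):
        d = build_default_design(pacing_cycles=3, continuation_cycles=1)
        assert list(target_times(d, Mode.SYNCOPATED, Phase.PACING)) == [
            500.0, 1500.0, 2500.0]

    def test_continuation_extrapolates_grid(self, default_design):
        full = target_times(default_design, Mode.SYNCHRONIZED)
        cont = target_times(default_design, Mode.SYNCHRONIZED, Phase.CONTINUATION)
        assert np.allclose(np.diff(full), 1000.0)  # one arithmetic sequence
        assert cont[0] == 15000.0
        assert np.allclose(cont, full[15:])


def brute_force_match(taps, targets, window):
    """Exhaustive minimum-cost assignment (oracle for <=5 taps)."""
    taps, targets = list(taps), list(targets)
    best_pairs, best_cost, best_size = [], np.inf, -1
    k = min(len(taps), len(targets))
    for size in range(k, -1, -1):
        for tap_idx in itertools.combinations(range(len(taps)), size):
            for tgt_idx in itertools.permutations(range(len(targets)), size):
                cost = sum(abs(taps[i] - targets[j])
                           for i, j in zip(tap_idx, tgt_idx))
                if any(abs(taps[i] - targets[j]) > window
                       for i, j in zip(tap_idx, tgt_idx)):
                    continue
                if size > best_size or (size == best_size and cost < best_cost):
                    best_size, best_cost = size, cost
                    best_pairs = sorted(
                        (taps[i], targets[j]) for i, j in zip(tap_idx, tgt_idx)
                    )
        if best_size == size:
            break
    return best_pairs


class TestMatching:
    def test_exact_taps_match_perfectly(self):
        targets = [0.0, 1000.0, 2000.0]
        res = match_taps(targets, targets, window=500.0)
        assert res.pairs == [(t, t) for t in targets]
        assert res.unmatched_taps == 0
        assert res.missing_targets == 0

    def test_absent_tap_reported_missing(self):
        res = match_taps([10.0, 2010.0], [0.0, 1000.0, 2000.0], window=500.0)
        assert res.missing_targets == 1
        assert res.unmatched_taps == 0

    def test_competing_taps_closer_wins(self):
        # both taps nearest target 1000; closer one is matched
        res = match_taps([980.0, 1100.0], [0.0, 1000.0], window=450.0)
        assert (980.0, 1000.0) in res.pairs
        assert res.unmatched_taps == 1

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        taps=st.lists(st.floats(min_value=-200, max_value=4200), min_size=0,
                      max_size=5),
    )
    def test_matches_brute_force_assignment_size(self, taps):
        targets = [0.0, 1000.0, 2000.0, 3000.0, 4000.0]
        window = 450.0
        got = match_taps(taps, targets, window)
        oracle = brute_force_match(taps, targets, window)
        # greedy nearest-first achieves the maximal assignment size here
        assert len(got.pairs) == len(oracle)
        for tap, tgt in got.pairs:
            assert abs(tap - tgt) <= window

    def test_window_wider_than_half_spacing_rejected(self):
        with pytest.raises(ValueError):
            match_taps([0.0], [0.0, 1000.0], window=600.0)


class TestAsynchrony:
    def test_sign_convention(self):
        targets = np.array([0.0, 1000.0, 2000.0])
        assert np.allclose(asynchrony(zip(targets, targets)), 0.0)
        assert np.allclose(asynchrony(zip(targets - 30.0, targets)), -30.0)
        assert np.allclose(asynchrony(zip(targets + 50.0, targets)), 50.0)

    @settings(derandomize=True, max_examples=30)
    @given(shift=st.floats(min_value=-400, max_value=400))
    def test_shift_equivariance(self, shift):
        targets = np.array([0.0, 1000.0, 2000.0, 3000.0])
        taps = targets + np.array([-20.0, 5.0, 12.0, -3.0])
        base = asynchrony(zip(taps, targets))
        shifted = asynchrony(zip(taps + shift, targets))
        assert np.allclose(shifted, base + shift, atol=1e-9)

    def test_zero_noise_virtual_asynchrony_is_zero(self, zero_noise_params):
        df = sessions_to_frame(
            simulate_cohort(1, 0, params_by_group(zero_noise_params), seed=1)
        )
        af = asynchrony_frame(df)
        sync = af[af["mode"] == "syncopated"]
        assert len(sync) > 0
        assert np.allclose(sync["asynchrony_ms"], 0.0)


class TestIRI:
    def test_periodic_taps(self):
        assert list(iri([0.0, 1000.0, 2000.0])) == [1000.0, 1000.0]
        assert list(iri([0.0, 980.0, 2010.0])) == [980.0, 1030.0]

    def test_mean_iri_of_periodic_train_is_period(self):
        taps = np.arange(27) * 1000.0
        assert iri(taps).mean() == 1000.0

    def test_gap_spanning_missed_cycle_excluded(self):
        vals = iri([0.0, 1000.0, 3010.0], cycles=[0, 1, 3])
        assert list(vals) == [1000.0]

    def test_non_monotone_rejected(self):
        with pytest.raises(ValueError):
            iri([0.0, 1000.0, 900.0])

    def test_iri_frame_labels_interval_by_later_cycle(self, zero_noise_params):
        df = sessions_to_frame(
            simulate_cohort(1, 0, params_by_group(zero_noise_params), seed=1)
        )
        frame = iri_frame(df)
        # 26 intervals per 27-cycle trial, 20 trials
        assert len(frame) == 26 * 20
        assert np.allclose(frame["iri_ms"], 1000.0)
        # the first unpaced interval (cycle 14 -> 15) belongs to continuation
        first_cont = frame[frame["cycle"] == 15]
        assert set(first_cont["phase"]) == {"continuation"}


class TestSummarize:
    def test_constant_and_symmetric(self):
        df = pd.DataFrame({"design": ["blocked"] * 4, "mode": ["synchronized"] * 4,
                           "phase": ["pacing"] * 4, "v": [5.0, 5.0, -1.0, 1.0]})
        out = summarize(df, "v")
        assert out.loc[0, "n"] == 4
        assert out.loc[0, "mean_ms"] == pytest.approx(2.5)
        out2 = summarize(df.assign(v=3.0), "v")
        assert out2.loc[0, "sd_ms"] == 0.0

    def test_zero_noise_condition_mean_equals_bias(self, zero_noise_params):
        params = params_by_group(zero_noise_params.replace(pacing_bias=-30.0))
        df = sessions_to_frame(simulate_cohort(1, 0, params, seed=1))
        af = asynchrony_frame(df)
        out = summarize(af[af.phase == "pacing"], "asynchrony_ms")
        assert np.allclose(out["mean_ms"], -30.0)
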