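"""Waveform classification, unit filtering, valid trials, burst detection,
delta-burst, shuffle null, d-prime, and opto-tagging."""

import numpy as np
import pandas as pd
import pytest

from pvburst.spikes import (SpikeTrain, UnitWaveformFeatures,
                            burst_spike_proportion, classify_unit, d_prime,
                            delta_burst, detect_bursts, extract_valid_trials,
                            filter_units, opto_tag_test, shuffle_null,
                            _resample_windows)


class TestClassifyUnit:
    @pytest.mark.parametrize("ratio,width,label", [
        (2.0, 400.0, "pExc"),
        (1.0, 150.0, "pInh"),
        (2.0, 150.0, "unclassified"),   # broad-ratio, narrow-width
        (1.0, 400.0, "unclassified"),
        (1.5, 250.0, "unclassified"),   # exactly on both boundaries
    ])
    def test_quadrants(self, ratio, width, label):
        f = UnitWaveformFeatures(ratio, width)
        assert classify_unit(f) == label

    def test_invalid_features_rejected(self):
        with pytest.raises(ValueError):
            UnitWaveformFeatures(np.nan, 100.0)
        with pytest.raises(ValueError):
            UnitWaveformFeatures(1.0, -5.0)


class TestFilterUnits:
    def _frames(self):
        sessions = pd.DataFrame({
            "session": ["rest", "s1"],
            "start_s": [0.0, 100.0],
            "end_s": [100.0, 200.0],
        })
        rows = []
        # unit a: 0.5 Hz overall (at the threshold -> excluded), both sessions
        rows += [("a", t) for t in np.linspace(1, 199, 100)]
        # unit b: 2 Hz, both sessions -> kept
        rows += [("b", t) for t in np.linspace(0.5, 199.5, 400)]
        # unit c: 2 Hz but silent in s1 -> excluded
        rows += [("c", t) for t in np.linspace(0.5, 99.5, 400)]
        spikes = pd.DataFrame(rows, columns=["unit_id", "time_s"])
        return spikes, sessions

    def test_rate_and_session_rules(self):
        spikes, sessions = self._frames()
        assert filter_units(spikes, sessions) == ["b"]

    def test_required_sessions_subset(self):
        spikes, sessions = self._frames()
        kept = filter_units(spikes, sessions, required_sessions=["rest"])
        assert kept == ["b", "c"]

    def test_empty_input(self):
        _, sessions = self._frames()
        empty = pd.DataFrame(columns=["unit_id", "time_s"])
        assert filter_units(empty, sessions) == []


class TestExtractValidTrials:
    def _events(self, rows):
        return pd.DataFrame(rows, columns=["session", "target", "side",
                                           "start_s", "end_s"])

    def test_gap_and_duration_rules(self):
        ev = self._events([
            ("s1", "S", "L", 0.0, 5.0),     # first: infinite gap, dur 5 -> ok
            ("s1", "E", "R", 6.0, 8.0),     # gap 1 s -> rejected
            ("s1", "S", "L", 11.0, 11.5),   # gap ok, dur 0.5 -> rejected
            ("s1", "O", "R", 14.0, 16.0),   # gap 2.5, dur 2 -> ok
        ])
        valid = extract_valid_trials(ev)
        assert list(valid["start_s"]) == [0.0, 14.0]

    def test_gap_exactly_two_seconds_rejected(self):
        ev = self._events([("s1", "S", "L", 0.0, 3.0),
                           ("s1", "E", "R", 5.0, 8.0)])
        assert len(extract_valid_trials(ev)) == 1

    def test_overlap_rejected(self):
        ev = self._events([("s1", "S", "L", 0.0, 5.0),
                           ("s1", "E", "R", 4.0, 8.0)])
        with pytest.raises(ValueError):
            extract_valid_trials(ev)

    def test_bad_interval_rejected(self):
        ev = self._events([("s1", "S", "L", 5.0, 5.0)])
        with pytest.raises(ValueError):
            extract_valid_trials(ev)


def _brute_force_proportion(t, thr_ms, min_spikes=2):
    """Independent re-derivation: mark every spike adjacent to a sub-threshold
    ISI, then count maximal marked runs of >= min_spikes spikes."""
    t = np.asarray(t, float)
    if t.size == 0:
        return 0.0
    close = np.diff(t) * 1000.0 < thr_ms
    member = np.zeros(t.size, bool)
    member[:-1] |= close
    member[1:] |= close
    # runs of members connected through sub-threshold ISIs
    in_burst = 0
    i = 0
    while i < t.size:
        j = i
        while j + 1 < t.size and close[j]:
            j += 1
        if j > i and (j - i + 1) >= min_spikes:
            in_burst += j - i + 1
        i = j + 1
    return in_burst / t.size


class TestDetectBursts:
    def test_simple_doublet(self):
        s = detect_bursts(np.array([1.0, 1.005, 2.0]))
        assert len(s.burst_groups) == 1
        assert list(s.burst_groups[0]) == [0, 1]
        assert s.burst_spike_proportion == pytest.approx(2 / 3)

    def test_threshold_is_strict(self):
        # ISI exactly 12 ms must NOT form a burst (strict <)
        s = detect_bursts(np.array([1.0, 1.012]))
        assert s.burst_groups == []
        s2 = detect_bursts(np.array([1.0, 1.0119]))
        assert len(s2.burst_groups) == 1

    def test_triplet_single_group(self):
        s = detect_bursts(np.array([0.0, 0.005, 0.010, 1.0, 1.005]))
        assert [list(g) for g in s.burst_groups] == [[0, 1, 2], [3, 4]]
        assert s.burst_spike_proportion == 1.0

    def test_empty_train_degenerate(self):
        s = detect_bursts(np.array([]))
        assert s.degenerate and s.burst_spike_proportion == 0.0

    def test_matches_brute_force_on_random_trains(self, rng):
        for _ in range(25):
            n = rng.integers(0, 60)
            t = np.sort(rng.uniform(0, 3.0, n))
            if t.size:
                t = t[np.concatenate([[True], np.diff(t) > 0])]
            for thr in (3.0, 12.0, 30.0):
                s = detect_bursts(t, isi_threshold_ms=thr)
                assert s.burst_spike_proportion == pytest.approx(
                    _brute_force_proportion(t, thr))

    def test_monotone_in_threshold(self, rng):
        """A larger ISI threshold can only merge more spikes into bursts."""
        t = np.sort(rng.uniform(0, 2.0, 80))
        props = [detect_bursts(t, thr).burst_spike_proportion
                 for thr in (3.0, 6.0, 12.0, 24.0, 48.0)]
        assert all(a <= b + 1e-12 for a, b in zip(props, props[1:]))

    def test_min_spikes_three(self):
        t = np.array([0.0, 0.005, 1.0, 1.005, 1.010])
        s = detect_bursts(t, min_spikes=3)
        assert [list(g) for g in s.burst_groups] == [[2, 3, 4]]

    def test_threshold_above_cap_rejected(self):
        with pytest.raises(ValueError):
            detect_bursts(np.array([0.0, 1.0]), isi_threshold_ms=250.0)

    def test_poisson_oracle(self):
        """For a homogeneous Poisson train the expected burst-spike proportion
        has the closed form E = ((n-2)(1 - q^2) + 2(1 - q)) / n with
        q = exp(-r * theta): interior spikes join a burst unless both flanking
        ISIs exceed theta; the two edge spikes have one flank."""
        r, thr_s = 20.0, 0.012
        rng = np.random.default_rng(99)
        props, ns = [], []
        for _ in range(300):
            t = np.cumsum(rng.exponential(1 / r, 200))
            props.append(detect_bursts(t, 12.0).burst_spike_proportion)
            ns.append(t.size)
        q = np.exp(-r * thr_s)
        n = 200
        expected = ((n - 2) * (1 - q * q) + 2 * (1 - q)) / n
        se = np.std(props, ddof=1) / np.sqrt(len(props))
        assert abs(np.mean(props) - expected) < 4 * se + 1e-3


class TestWindowedProportion:
    def test_windows_do_not_bridge(self):
        # two spikes 5 ms apart but in different windows: no burst
        t = np.array([0.999, 1.004])
        prop, n = burst_spike_proportion(t, [(0.0, 1.0), (1.0, 2.0)])
        assert (prop, n) == (0.0, 2)
        prop2, n2 = burst_spike_proportion(t, [(0.0, 2.0)])
        assert (prop2, n2) == (1.0, 2)

    def test_empty_windows(self):
        prop, n = burst_spike_proportion(np.array([5.0]), [(0.0, 1.0)])
        assert (prop, n) == (0.0, 0)


class TestDeltaBurst:
    def test_hand_computed(self):
        # rest: 4 spikes, one doublet -> 0.5; target S: 3 spikes all burst
        times = np.array([0.1, 0.105, 1.0, 2.0,          # rest window (0,3)
                          10.0, 10.005, 10.010,           # S trial
                          20.0, 21.0])                    # E trial, no burst
        train = SpikeTrain("u", times)
        trials = pd.DataFrame({"target": ["S", "E"],
                               "start_s": [9.5, 19.5],
                               "end_s": [11.0, 21.5]})
        df = delta_burst(train, trials, [(0.0, 3.0)])
        s = df[df.target == "S"].iloc[0]
        e = df[df.target == "E"].iloc[0]
        assert s.delta_burst == pytest.approx(1.0 - 0.5)
        assert e.delta_burst == pytest.approx(0.0 - 0.5)
        assert not s.degenerate and not e.degenerate

    def test_degenerate_flag(self):
        train = SpikeTrain("u", np.array([10.0, 10.005]))
        trials = pd.DataFrame({"target": ["S"], "start_s": [9.5],
                               "end_s": [11.0]})
        df = delta_burst(train, trials, [(0.0, 3.0)])  # no rest spikes
        assert bool(df.iloc[0].degenerate)


class TestShuffleNull:
    def test_counts_conserved_per_window(self, rng):
        windows = [(0.0, 1.0), (2.0, 2.5), (4.0, 10.0)]
        counts = [3, 0, 7]
        for _ in range(20):
            draws = _resample_windows(windows, counts, rng)
            assert len(draws) == 2  # empty window dropped
            assert [d.size for d in draws] == [3, 7]
            for d, (a, b) in zip(draws, [windows[0], windows[2]]):
                assert np.all((d >= a) & (d <= b))
                assert np.all(np.diff(d) >= 0)

    def test_reproducible(self):
        train = SpikeTrain("u", np.sort(
            np.random.default_rng(3).uniform(0, 50, 400)))
        wins = [(i * 10.0, i * 10.0 + 8.0) for i in range(5)]
        a = shuffle_null(train, wins, n_perm=10, seed=42)
        b = shuffle_null(train, wins, n_perm=10, seed=42)
        assert np.array_equal(a, b)

    def test_null_mean_matches_poisson_oracle(self):
        """Uniform redraws of a fixed count in a window are the order
        statistics of n uniforms, i.e. a conditioned Poisson process; the
        closed-form expectation from the Poisson oracle applies per window."""
        rate, W, n_win = 20.0, 10.0, 5
        rng = np.random.default_rng(7)
        times = np.sort(rng.uniform(0, n_win * W,
                                    int(rate * n_win * W)))
        train = SpikeTrain("u", times)
        wins = [(i * W, (i + 1) * W) for i in range(n_win)]
        null = shuffle_null(train, wins, n_perm=50, seed=11)
        n = int(rate * W)
        q = np.exp(-rate * 0.012)
        expected = ((n - 2) * (1 - q * q) + 2 * (1 - q)) / n
        se = null.std(ddof=1) / np.sqrt(null.size)
        assert abs(null.mean() - expected) < 4 * se + 5e-3

    def test_nperm_validated(self):
        train = SpikeTrain("u", np.array([1.0]))
        with pytest.raises(ValueError):
            shuffle_null(train, [(0.0, 2.0)], n_perm=0, seed=0)


class TestDPrime:
    def test_known_value(self):
        assert d_prime(2.0, 1.0, 0.0, 1.0) == pytest.approx(2.0)
        assert d_prime(1.0, 2.0, 0.0, 0.0) == pytest.approx(1 / np.sqrt(2.0))

    def test_antisymmetric(self):
        assert d_prime(3.0, 1.0, 1.0, 2.0) == -d_prime(1.0, 2.0, 3.0, 1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            d_prime(1.0, 0.0, 0.0, 0.0)


class TestOptoTag:
    def _pulsed_train(self, onsets, early_n, late_n, rng):
        t = []
        for o in onsets:
            t.extend(o + rng.uniform(0.0, 0.020, early_n))
            t.extend(o + rng.uniform(0.080, 0.100, late_n))
        return SpikeTrain("u", np.unique(np.sort(t)))

    def test_responsive_unit_tagged(self, rng):
        onsets = np.arange(0.0, 5.0, 0.1)
        train = self._pulsed_train(onsets, 3, 0, rng)
        assert opto_tag_test(train, onsets) == "tagged"

    def test_flat_unit_untagged(self, rng):
        onsets = np.arange(0.0, 5.0, 0.1)
        train = self._pulsed_train(onsets, 2, 2, rng)
        assert opto_tag_test(train, onsets) == "untagged"

    def test_silent_unit_untagged(self):
        onsets = np.arange(0.0, 5.0, 0.1)
        train = SpikeTrain("u", np.array([100.0, 101.0]))
        assert opto_tag_test(train, onsets) == "untagged"

    def test_false_positive_rate_controlled(self):
        """Poisson units with no light response are tagged at ~alpha."""
        onsets = np.arange(0.0, 10.0, 0.1)
        rng = np.random.default_rng(17)
        tagged = 0
        n_units = 200
        for _ in range(n_units):
            t = np.cumsum(rng.exponential(1 / 10.0, 150))
            tagged += opto_tag_test(SpikeTrain("u", t), onsets) == "tagged"
        # binomial 99% bound around alpha = 0.05
        assert tagged / n_units < 0.05 + 2.6 * np.sqrt(0.05 * 0.95 / n_units)

    def test_too_few_pulses_rejected(self):
        with pytest.raises(ValueError):
            opto_tag_test(SpikeTrain("u", np.array([0.0])), np.array([0.0]))
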