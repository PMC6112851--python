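"""PSTH construction, response detection/quantification, unit classification."""

import numpy as np
import pytest

from songcircuit.ephys import (
    PSTH,
    ResponseEvent,
    SpikeTrain,
    StimulationProtocol,
    classify_profile,
    classify_unit,
    compare_conditions,
    compute_psth,
    detect_response_events,
    first_response_latency,
    peak_response_rate,
    percent_resting_response,
    response_strength,
    spontaneous_rate,
)


def brute_force_psth(spikes, onsets, bin_ms, pre_ms, post_ms):
    """Independent per-trial, per-bin spike counter (the oracle)."""
    n_bins = int(round((pre_ms + post_ms) / bin_ms))
    counts = np.zeros(n_bins)
    for onset in onsets:
        for s in spikes:
            rel = (s - onset) * 1000.0
            if -pre_ms <= rel < post_ms:
                b = int((rel + pre_ms) // bin_ms)
                if 0 <= b < n_bins:
                    counts[b] += 1
    return counts / (len(onsets) * bin_ms / 1000.0)


def make_psth(rates, bin_ms=2.0, pre_ms=20.0, mean=50.0, sd=2.0, n_trials=50_000):
    """PSTH with a hand-set post-stimulation rate vector and baseline stats.

    The large trial count keeps the Poisson counting floor of the detector
    well below the constructed baseline SD, so the planted band is in force.
    """
    pre_bins = int(pre_ms / bin_ms)
    full = np.concatenate([np.full(pre_bins, mean), rates])
    return PSTH(
        bin_width=bin_ms,
        pre_window=pre_ms,
        post_window=len(rates) * bin_ms,
        rate_per_bin=full,
        n_trials=n_trials,
        baseline_mean=mean,
        baseline_sd=sd,
        baseline_window=pre_ms,
    )


class TestSpontaneousRateAndClass:
    def test_rate_is_count_over_window(self):
        train = SpikeTrain("u1", np.linspace(0.01, 1.99, 70), 2.0)
        assert spontaneous_rate(train, (0.0, 2.0)) == pytest.approx(35.0)

    def test_no_spikes_zero_rate(self):
        train = SpikeTrain("u1", np.array([]), 2.0)
        assert spontaneous_rate(train, (0.0, 2.0)) == 0.0

    def test_empty_window_rejected(self):
        train = SpikeTrain("u1", np.array([0.5]), 2.0)
        with pytest.raises(ValueError):
            spontaneous_rate(train, (1.0, 1.0))

    @pytest.mark.parametrize(
        "rate,label",
        [(35.4, "pallidal"), (5.0, "low_rate"), (15.0, "unclassified"),
         (25.0, "unclassified"), (10.0, "unclassified")],
    )
    def test_unit_classification(self, rate, label):
        assert classify_unit(rate).label == label

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            classify_unit(-1.0)


class TestComputePsth:
    def test_matches_brute_force_on_random_instances(self, rng):
        """Oracle equivalence on 200 random small spike/stimulation layouts."""
        for _ in range(200):
            n_stims = int(rng.integers(1, 5))
            onsets = 1.0 + np.arange(n_stims) * 1.0
            spikes = np.sort(rng.uniform(0.0, n_stims + 1.5, size=rng.integers(0, 60)))
            train = SpikeTrain("u", spikes, n_stims + 2.0)
            protocol = StimulationProtocol(onsets=onsets, inter_stim_interval=1.0)
            bin_ms = float(rng.choice([1.0, 2.0, 5.0, 10.0]))
            pre, post = 5 * bin_ms, 20 * bin_ms
            psth = compute_psth(train, protocol, bin_ms, pre, post)
            oracle = brute_force_psth(spikes, onsets, bin_ms, pre, post)
            np.testing.assert_allclose(psth.rate_per_bin, oracle, atol=1e-9)

    def test_hand_counted_bin_rate(self):
        """3 spikes in one 2 ms bin over 2 trials -> 3 / (2 x 0.002) = 750 Hz."""
        onsets = np.array([1.0, 2.0])
        spikes = np.array([1.0105, 1.0112, 2.0111])
        train = SpikeTrain("u", spikes, 4.0)
        protocol = StimulationProtocol(onsets=onsets, inter_stim_interval=1.0)
        psth = compute_psth(train, protocol, 2.0, 20.0, 40.0)
        assert psth.rate_per_bin[psth.bin_index(10.0)] == pytest.approx(750.0)

    def test_empty_train_zero_psth(self):
        train = SpikeTrain("u", np.array([]), 5.0)
        protocol = StimulationProtocol(onsets=np.array([2.0]))
        psth = compute_psth(train, protocol, 2.0, 50.0, 100.0)
        assert np.all(psth.rate_per_bin == 0)
        assert psth.baseline_mean == 0.0

    def test_baseline_stats_use_only_baseline_window(self):
        train = SpikeTrain("u", np.array([1.96, 1.97, 1.98]), 5.0)
        protocol = StimulationProtocol(onsets=np.array([2.0]))
        psth = compute_psth(train, protocol, 2.0, 100.0, 100.0, baseline_window=20.0)
        # spikes at -40..-20 ms are outside the 20 ms baseline window
        assert psth.baseline_mean == 0.0

    def test_spacing_shorter_than_window_rejected(self):
        train = SpikeTrain("u", np.array([]), 5.0)
        protocol = StimulationProtocol(onsets=np.array([1.0, 1.1]))
        with pytest.raises(ValueError, match="spacing"):
            compute_psth(train, protocol, 2.0, 50.0, 100.0)


class TestDetection:
    def test_flat_psth_no_events(self):
        psth = make_psth(np.full(50, 50.0))
        assert detect_response_events(psth) == []

    def test_constructed_excitation_onset_and_offset(self):
        """Excitation planted in bins [10, 14) ms is recovered exactly."""
        rates = np.full(50, 50.0)
        rates[5:7] = 80.0  # post bins 5,6 -> 10-14 ms
        psth = make_psth(rates)
        events = detect_response_events(psth)
        assert len(events) == 1
        assert events[0].polarity == "excitation"
        assert events[0].onset_latency == pytest.approx(10.0)
        assert events[0].offset == pytest.approx(14.0)

    def test_single_bin_excursion_ignored(self):
        rates = np.full(50, 50.0)
        rates[5] = 200.0
        psth = make_psth(rates)
        assert detect_response_events(psth) == []

    def test_threshold_is_strict(self):
        """Bins exactly at mean + k*SD are non-responsive."""
        rates = np.full(50, 50.0)
        rates[5:9] = 50.0 + 2.5 * 2.0
        psth = make_psth(rates)
        assert detect_response_events(psth) == []

    def test_biphasic_sequence_detected_in_order(self):
        rates = np.full(60, 50.0)
        rates[5:10] = 90.0
        rates[12:18] = 20.0
        psth = make_psth(rates)
        events = detect_response_events(psth)
        assert [e.polarity for e in events] == ["excitation", "inhibition"]
        assert events[0].onset_latency < events[1].onset_latency

    def test_single_bin_dip_does_not_split_event(self):
        rates = np.full(50, 50.0)
        rates[5:12] = 90.0
        rates[8] = 50.0  # one in-band bin inside the excitation
        psth = make_psth(rates)
        events = detect_response_events(psth)
        assert len(events) == 1
        assert events[0].offset == pytest.approx((12 + 10) * 2.0 - 20.0)

    def test_two_inband_bins_end_event(self):
        rates = np.full(50, 50.0)
        rates[5:8] = 90.0
        rates[8:10] = 50.0
        rates[10:12] = 90.0
        psth = make_psth(rates)
        events = detect_response_events(psth)
        assert len(events) == 2

    def test_artifact_blank_excludes_early_bins(self):
        rates = np.full(50, 50.0)
        rates[0:2] = 500.0  # artifact in 0-4 ms
        psth = make_psth(rates)
        assert detect_response_events(psth, artifact_blank=4.0) == []

    def test_detection_invariant_to_constant_offset(self):
        rates = np.full(50, 50.0)
        rates[5:9] = 90.0
        p1 = make_psth(rates)
        p2 = make_psth(rates + 30.0, mean=80.0)
        e1 = detect_response_events(p1)
        e2 = detect_response_events(p2)
        assert [(e.onset_latency, e.offset, e.polarity) for e in e1] == [
            (e.onset_latency, e.offset, e.polarity) for e in e2
        ]

    def test_zero_sd_falls_back_to_poisson_band(self):
        rates = np.zeros(50)
        rates[5:9] = 100.0
        psth = make_psth(rates, mean=0.0, sd=0.0)
        with pytest.warns(UserWarning, match="floor"):
            events = detect_response_events(psth)
        assert len(events) == 1 and events[0].polarity == "excitation"

    def test_planted_runs_recovered_exactly(self, rng):
        """100 random constructions: onsets/offsets/polarities match exactly."""
        for _ in range(100):
            n_post = 60
            rates = np.full(n_post, 50.0)
            truth = []
            cursor = int(rng.integers(2, 6))
            while cursor < n_post - 3:
                length = int(rng.integers(2, 6))
                end = min(cursor + length, n_post)
                pol = rng.choice(["excitation", "inhibition"])
                rates[cursor:end] = 90.0 if pol == "excitation" else 20.0
                truth.append((pol, cursor, end))
                cursor = end + int(rng.integers(2, 7))  # >=2 in-band bins apart
            psth = make_psth(rates, bin_ms=2.0, pre_ms=20.0)
            events = detect_response_events(psth, artifact_blank=0.0)
            got = [
                (
                    e.polarity,
                    int(e.onset_latency / 2.0),
                    int(e.offset / 2.0),
                )
                for e in events
            ]
            assert got == truth


class TestQuantification:
    def test_no_events_latency_undefined(self):
        assert first_response_latency([]) is None

    def test_latency_is_min_onset(self):
        events = [
            ResponseEvent("inhibition", 30.0, 40.0, -0.2, 10.0),
            ResponseEvent("excitation", 20.0, 28.0, 0.5, 120.0),
        ]
        assert first_response_latency(sorted(events, key=lambda e: e.onset_latency)) == 20.0

    def test_rectangular_strength_closed_form(self):
        """100 Hz above baseline for 10 ms integrates to exactly 1.0 spike."""
        rates = np.full(50, 50.0)
        rates[5:10] = 150.0
        psth = make_psth(rates)
        events = detect_response_events(psth)
        assert response_strength(psth, events) == pytest.approx(1.0)

    def test_strength_without_excitation_is_zero_with_note(self):
        rates = np.full(50, 50.0)
        rates[5:10] = 20.0
        psth = make_psth(rates)
        events = detect_response_events(psth)
        with pytest.warns(UserWarning, match="no excitatory"):
            assert response_strength(psth, events) == 0.0

    def test_total_mode_sums_both_excitations(self):
        rates = np.full(60, 50.0)
        rates[5:10] = 150.0
        rates[20:25] = 100.0
        psth = make_psth(rates)
        events = detect_response_events(psth)
        first = response_strength(psth, events, mode="first_excitation")
        total = response_strength(psth, events, mode="total")
        assert first == pytest.approx(1.0)
        assert total == pytest.approx(1.5)

    def test_peak_rate_within_events_only(self):
        rates = np.full(50, 50.0)
        rates[5:9] = 90.0
        rates[9] = 300.0  # isolated spike after the event closed
        rates[10:12] = 50.0
        rates[20] = 400.0  # isolated artifact, not an event
        psth = make_psth(rates)
        events = detect_response_events(psth)
        assert len(events) == 1
        # the isolated 300 Hz bin extends the open event, so it counts;
        # the 400 Hz single bin outside any event never does
        assert peak_response_rate(psth, events) <= 300.0
        assert peak_response_rate(psth, events) != 400.0

    def test_peak_requires_events(self):
        psth = make_psth(np.full(50, 50.0))
        with pytest.raises(ValueError):
            peak_response_rate(psth, [])


class TestProfileAndPharmacology:
    @pytest.mark.parametrize(
        "pols,label",
        [
            ([], "none"),
            (["excitation"], "excitation_only"),
            (["excitation", "inhibition"], "biphasic"),
            (["inhibition", "excitation", "inhibition"], "triphasic"),
            (["inhibition"], "other"),
            (["excitation", "inhibition", "excitation"], "other"),
        ],
    )
    def test_taxonomy(self, pols, label):
        events = [
            ResponseEvent(p, 10.0 + 10 * i, 15.0 + 10 * i, 0.5 if p == "excitation" else -0.5, 100.0)
            for i, p in enumerate(pols)
        ]
        assert classify_profile(events) == label

    def test_percent_resting_response(self):
        assert percent_resting_response(0.5, 1.0) == pytest.approx(50.0)
        assert percent_resting_response(0.0, 1.0) == 0.0
        assert percent_resting_response(1.0, 1.0) == 100.0
        with pytest.raises(ValueError):
            percent_resting_response(0.5, 0.0)

    def test_compare_conditions_paired_and_unpaired(self):
        baseline = np.array([0.9, 1.1, 0.8, 1.3, 1.0, 0.7, 1.2, 0.95])
        drug = baseline * 0.2
        paired = compare_conditions(baseline, drug, paired=True)
        assert paired.p_value < 0.01
        unpaired = compare_conditions(baseline, drug, paired=False)
        assert unpaired.test == "wilcoxon_ranksum"
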