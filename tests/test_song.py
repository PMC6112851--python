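"""Envelope, spectrogram, motif/bout detection, segmentation, F0 estimation."""

import numpy as np
import pytest

from songcircuit.audio import AudioRecording
from songcircuit import song as sg
from songcircuit.synth.song import (
    MotifSpec,
    SyllableSpec,
    synthesize_bout,
    synthesize_motif,
    synthesize_syllable,
)

SR = 44100


def tone(freq, dur_s, sr=SR, amp=1.0):
    t = np.arange(int(dur_s * sr)) / sr
    return AudioRecording(samples=amp * np.sin(2 * np.pi * freq * t), sample_rate=sr)


class TestEnvelope:
    def test_silence(self):
        env = sg.compute_envelope(AudioRecording(np.zeros(SR)))
        assert np.allclose(env.values, 0.0)

    def test_unit_sine_rms(self):
        env = sg.compute_envelope(tone(1000.0, 0.5))
        steady = env.values[50:-50]
        assert steady.mean() == pytest.approx(1 / np.sqrt(2), rel=0.01)

    def test_tracks_slow_modulator(self):
        t = np.arange(SR) / SR
        modulator = 0.6 + 0.4 * np.sin(2 * np.pi * 3.0 * t)  # 3 Hz AM
        x = modulator * np.sin(2 * np.pi * 2000.0 * t)
        env = sg.compute_envelope(AudioRecording(x))
        expected = modulator[(np.arange(len(env.values)) / 1000 * SR).astype(int)]
        err = np.abs(env.values[20:-20] / (expected[20:-20] / np.sqrt(2)) - 1)
        assert np.max(err) < 0.05

    def test_window_longer_than_recording_rejected(self):
        with pytest.raises(ValueError, match="window"):
            sg.compute_envelope(AudioRecording(np.zeros(100)), smoothing_window_ms=50.0)


class TestSpectrogram:
    def test_tone_peak_bin(self):
        spec = sg.compute_spectrogram(tone(1000.0, 0.3))
        peak_freqs = spec.freqs[np.argmax(spec.magnitude, axis=0)]
        assert np.all(np.abs(peak_freqs - 1000.0) < SR / 256)

    def test_zeros_give_zero_magnitude(self):
        spec = sg.compute_spectrogram(AudioRecording(np.zeros(2048)))
        assert np.allclose(spec.magnitude, 0.0)

    def test_window_hop_defaults(self):
        spec = sg.compute_spectrogram(tone(500.0, 0.1))
        assert spec.window_length == 256
        assert spec.hop == 128

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            sg.compute_spectrogram(AudioRecording(np.zeros(100)))


class TestMotifDetection:
    def test_planted_copies_found(self, motif_spec, template, rng):
        """Template copies inserted in noise are each found within 10 ms."""
        motif_audio, _ = synthesize_motif(motif_spec, seed=0)
        n = int(5.0 * SR)
        noise = 0.001 * rng.standard_normal(n)
        true_starts = [0.5, 2.0, 3.8]
        for s in true_starts:
            i = int(s * SR)
            noise[i : i + len(motif_audio.samples)] += motif_audio.samples
        rec = AudioRecording(noise)
        occs = sg.detect_motif_candidates(rec, template)
        assert len(occs) == 3
        for occ, s in zip(occs, true_starts):
            assert abs(occ.start - s) < 0.010

    def test_pure_noise_no_detections(self, template, rng):
        rec = AudioRecording(0.001 * rng.standard_normal(3 * SR))
        assert sg.detect_motif_candidates(rec, template) == []

    def test_overlapping_copies_suppressed_to_one(self, motif_spec, template, rng):
        motif_audio, _ = synthesize_motif(motif_spec, seed=0)
        n = int(3.0 * SR)
        noise = 0.001 * rng.standard_normal(n)
        i0 = int(0.5 * SR)
        shift = int(0.3 * len(motif_audio.samples))  # overlap well inside one length
        noise[i0 : i0 + len(motif_audio.samples)] += motif_audio.samples
        noise[i0 + shift : i0 + shift + len(motif_audio.samples)] += motif_audio.samples
        occs = sg.detect_motif_candidates(AudioRecording(noise), template)
        assert len(occs) == 1


class TestSpectralSimilarity:
    def test_self_similarity_is_one(self, template):
        sim = sg.spectrogram_similarity(template.audio, template.spectrogram)
        assert sim == pytest.approx(1.0, abs=1e-9)

    def test_noise_rejected(self, template, rng):
        noise = AudioRecording(0.3 * rng.standard_normal(len(template.audio.samples)))
        sim = sg.spectrogram_similarity(noise, template.spectrogram)
        assert sim < sg.DEFAULT_SIMILARITY_THRESHOLD

    def test_gain_invariance(self, template):
        a = template.audio
        sim1 = sg.spectrogram_similarity(a, template.spectrogram)
        sim2 = sg.spectrogram_similarity(a.scaled(2.0), template.spectrogram)
        assert abs(sim1 - sim2) < 1e-6

    def test_symmetric_on_equal_length_inputs(self, template, rng):
        a = template.audio
        b = AudioRecording(
            a.samples + 0.05 * rng.standard_normal(len(a.samples))
        )
        assert sg.spectrogram_similarity(a, b) == pytest.approx(
            sg.spectrogram_similarity(b, a), abs=1e-6
        )

    def test_filter_accepts_template_and_rejects_noise(self, template, rng):
        dur = template.audio.duration
        pad = np.zeros(int(0.6 * SR))
        noise_seg = 0.3 * rng.standard_normal(len(template.audio.samples))
        rec = AudioRecording(
            np.concatenate([pad, template.audio.samples, pad, noise_seg, pad])
        )
        t0 = len(pad) / SR
        t1 = (2 * len(pad) + len(template.audio.samples)) / SR
        cands = [
            sg.MotifOccurrence(start=t0, end=t0 + dur, envelope_correlation=1.0),
            sg.MotifOccurrence(start=t1, end=t1 + dur, envelope_correlation=0.9),
        ]
        accepted = sg.filter_by_spectral_similarity(rec, cands, template)
        assert len(accepted) == 1
        assert cands[0].accepted and not cands[1].accepted


class TestBouts:
    def occ(self, start, end):
        return sg.MotifOccurrence(start=start, end=end, envelope_correlation=1.0)

    def test_400ms_gap_one_bout(self):
        bouts = sg.segment_bouts([self.occ(0.0, 0.6), self.occ(1.0, 1.6)])
        assert len(bouts) == 1
        assert len(bouts[0].motifs) == 2

    def test_600ms_gap_two_bouts(self):
        bouts = sg.segment_bouts([self.occ(0.0, 0.6), self.occ(1.2, 1.8)])
        assert len(bouts) == 2

    def test_single_motif_single_bout(self):
        bouts = sg.segment_bouts([self.occ(0.2, 0.8)])
        assert len(bouts) == 1
        assert bouts[0].start == 0.2 and bouts[0].end == 0.8

    def test_bout_partition_is_exact(self, rng):
        """Every motif lands in exactly one bout."""
        starts = np.sort(rng.uniform(0, 60, 40))
        occs = [self.occ(s, s + 0.4) for s in starts]
        bouts = sg.segment_bouts(occs)
        assigned = [m for b in bouts for m in b.motifs]
        assert sorted(id(m) for m in assigned) == sorted(id(o) for o in occs)


class TestSegmentation:
    def make_two_syllable_motif(self):
        motif = MotifSpec(
            syllables=[
                SyllableSpec("harmonic", 80.0, f0_hz=500.0, peak_amplitude=0.5),
                SyllableSpec("harmonic", 120.0, f0_hz=600.0, peak_amplitude=0.25),
            ],
            gaps_ms=[50.0],
            noise_floor=0.001,
        )
        pad = np.zeros(int(0.2 * SR))
        audio, truths = synthesize_motif(motif, SR, seed=1)
        rec = AudioRecording(np.concatenate([pad, audio.samples, pad]))
        return rec, truths, 0.2

    def test_two_syllables_recovered(self):
        rec, truths, offset = self.make_two_syllable_motif()
        env = sg.compute_envelope(rec)
        segs = sg.segment_syllables(env, (offset - 0.05, offset + 0.30))
        assert len(segs) == 2
        for seg, t in zip(segs, truths):
            assert seg.duration_ms == pytest.approx(t.duration_ms, abs=5.0)
            assert seg.onset == pytest.approx(t.onset + offset, abs=0.005)

    def test_silence_yields_no_segments(self):
        env = sg.Envelope(values=np.full(500, 1e-5))
        with pytest.warns(UserWarning, match="threshold"):
            segs = sg.segment_syllables(
                env, (0.0, 0.5), sg.ThresholdRule(background=1e-4)
            )
        assert segs == []

    def test_short_dip_not_split(self):
        """A 3 ms envelope dip inside a syllable does not split it."""
        values = np.full(400, 0.001)
        values[100:200] = 0.5
        values[148:151] = 0.0005  # 3 ms dip
        env = sg.Envelope(values=values)
        segs = sg.segment_syllables(env, (0.0, 0.4), sg.ThresholdRule(background=0.001))
        assert len(segs) == 1

    def test_longer_dip_splits(self):
        values = np.full(400, 0.001)
        values[100:200] = 0.5
        values[145:155] = 0.0005  # 10 ms dip
        env = sg.Envelope(values=values)
        segs = sg.segment_syllables(env, (0.0, 0.4), sg.ThresholdRule(background=0.001))
        assert len(segs) == 2

    def test_relative_amplitude(self):
        rec, truths, offset = self.make_two_syllable_motif()
        env = sg.compute_envelope(rec)
        segs = sg.segment_syllables(env, (offset - 0.05, offset + 0.30))
        motif_env = env.slice(offset - 0.05, offset + 0.30)
        rel = [sg.relative_amplitude(s, motif_env) for s in segs]
        assert rel[0] == pytest.approx(1.0, abs=0.01)
        assert rel[1] == pytest.approx(0.5, abs=0.05)
        assert all(r <= 1.0 for r in rel)

    def test_relative_amplitude_zero_peak_rejected(self):
        seg = sg.SyllableSegment(onset=0.0, offset=0.1, peak_envelope=0.1)
        with pytest.raises(ValueError):
            sg.relative_amplitude(seg, np.zeros(100))


class TestF0:
    def test_pure_tone(self):
        f0, harm = sg.estimate_f0_autocorrelation(tone(500.0, 0.1))
        assert f0 == pytest.approx(500.0, rel=0.002)
        assert harm > 0.9

    def test_harmonic_stack_within_one_percent(self):
        spec = SyllableSpec("harmonic", 100.0, f0_hz=650.0, n_harmonics=4)
        audio = synthesize_syllable(spec, SR)
        f0, harm = sg.estimate_f0_autocorrelation(audio)
        assert f0 == pytest.approx(650.0, rel=0.01)
        assert harm > sg.DEFAULT_HARMONICITY

    def test_white_noise_undefined(self, rng):
        noise = AudioRecording(rng.standard_normal(int(0.1 * SR)))
        f0, harm = sg.estimate_f0_autocorrelation(noise)
        assert f0 is None
        assert harm < sg.DEFAULT_HARMONICITY

    def test_polarity_flip_invariant(self):
        spec = SyllableSpec("harmonic", 100.0, f0_hz=520.0)
        audio = synthesize_syllable(spec, SR)
        f0a, _ = sg.estimate_f0_autocorrelation(audio)
        f0b, _ = sg.estimate_f0_autocorrelation(audio.scaled(-1.0))
        assert f0a == pytest.approx(f0b, abs=1e-9)

    def test_band_limits_validated(self):
        with pytest.raises(ValueError):
            sg.estimate_f0_autocorrelation(tone(500.0, 0.1), f_min=800.0, f_max=700.0)
        with pytest.raises(ValueError, match="window"):
            sg.estimate_f0_autocorrelation(
                tone(500.0, 0.1), f_min=50.0, f_max=1000.0, window_ms=10.0
            )


class TestPipelineInvariants:
    def test_gain_invariance_of_detection_scores(self, motif_spec, template):
        bout, _ = synthesize_bout(motif_spec, 2, seed=9)
        occ1 = sg.detect_motif_candidates(bout, template)
        occ2 = sg.detect_motif_candidates(bout.scaled(2.0), template)
        assert len(occ1) == len(occ2)
        for a, b in zip(occ1, occ2):
            assert abs(a.envelope_correlation - b.envelope_correlation) < 1e-6
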