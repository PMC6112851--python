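"""Song segmentation and acoustic feature extraction.

Continuous recordings are reduced to an RMS amplitude envelope on a 1 kHz
grid.  Motif occurrences are found by normalized cross-correlation of the
envelope against a clean template motif, then vetted by spectrogram
similarity; accepted motifs are grouped into bouts (inter-motif silence
< 500 ms), and syllables are cut at envelope threshold crossings.  Per
syllable the module measures duration, relative amplitude (peak envelope over
the motif peak) and, for harmonic stacks, the fundamental frequency from the
peak of the normalized autocorrelation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .audio import AudioRecording

ENVELOPE_RATE_HZ = 1000.0
DEFAULT_SMOOTHING_MS = 5.0
SPEC_WINDOW = 256  # Hanning window length, samples
SPEC_HOP = 128  # window step, samples
BOUT_GAP_S = 0.5  # motifs closer than this belong to one bout
DEFAULT_PEAK_THRESHOLD = 0.6  # envelope cross-correlation peak
DEFAULT_SIMILARITY_THRESHOLD = 0.5  # spectrogram similarity acceptance
DEFAULT_F_MIN = 300.0
DEFAULT_F_MAX = 1500.0
DEFAULT_HARMONICITY = 0.5
DEFAULT_F0_WINDOW_MS = 40.0
MIN_SYLLABLE_MS = 10.0
MIN_GAP_MS = 5.0


@dataclass
class Envelope:
    """RMS amplitude envelope evaluated on a uniform grid."""

    values: np.ndarray
    rate: float = ENVELOPE_RATE_HZ
    smoothing_window_ms: float = DEFAULT_SMOOTHING_MS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("envelope values must be non-negative")

    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.rate

    def slice(self, start_s: float, end_s: float) -> np.ndarray:
        i0 = max(0, int(np.floor(start_s * self.rate)))
        i1 = min(len(self.values), int(np.ceil(end_s * self.rate)))
        return self.values[i0:i1]


@dataclass
class Spectrogram:
    """Magnitude short-time Fourier transform (freq x time)."""

    magnitude: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    window_length: int = SPEC_WINDOW
    hop: int = SPEC_HOP


@dataclass
class MotifTemplate:
    """A clean, manually selected motif used to find motifs in recordings."""

    audio: AudioRecording
    envelope: Envelope = field(init=False)
    spectrogram: Spectrogram = field(init=False)

    def __post_init__(self) -> None:
        if not 0.2 <= self.audio.duration <= 2.0:
            raise ValueError("motif template must be 0.2-2 s long")
        self.envelope = compute_envelope(self.audio)
        self.spectrogram = compute_spectrogram(self.audio)


@dataclass
class MotifOccurrence:
    start: float  # s
    end: float  # s
    envelope_correlation: float
    spectral_similarity: float | None = None
    accepted: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("motif end must exceed start")


@dataclass
class SongBout:
    start: float
    end: float
    motifs: list[MotifOccurrence]


@dataclass
class SyllableSegment:
    onset: float  # s from recording start
    offset: float  # s
    peak_envelope: float
    relative_amplitude: float | None = None
    type_label: str | None = None
    f0_hz: float | None = None
    harmonicity: float | None = None

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ValueError("offset must exceed onset")

    @property
    def duration_ms(self) -> float:
        return (self.offset - self.onset) * 1000.0


def compute_envelope(
    audio: AudioRecording, smoothing_window_ms: float = DEFAULT_SMOOTHING_MS
) -> Envelope:
    """Sliding-window RMS of the waveform, sampled on a 1 kHz grid."""
    if smoothing_window_ms <= 0:
        raise ValueError("smoothing window must be positive")
    win = int(round(smoothing_window_ms * audio.sample_rate / 1000.0))
    if win > len(audio.samples):
        raise ValueError("smoothing window longer than the recording")
    win = max(win, 1)
    power = np.convolve(audio.samples**2, np.ones(win) / win, mode="same")
    rms = np.sqrt(np.maximum(power, 0.0))
    # resample onto the 1 kHz grid by nearest-sample lookup
    n_out = int(np.floor(len(audio.samples) / audio.sample_rate * ENVELOPE_RATE_HZ))
    idx = np.minimum(
        (np.arange(n_out) / ENVELOPE_RATE_HZ * audio.sample_rate).astype(int),
        len(rms) - 1,
    )
    return Envelope(values=rms[idx], smoothing_window_ms=smoothing_window_ms)


def compute_spectrogram(audio: AudioRecording) -> Spectrogram:
    """Magnitude STFT with a 256-point Hanning window and 128-point step."""
    if len(audio.samples) < SPEC_WINDOW:
        raise ValueError("recording shorter than one analysis window")
    freqs, times, stft = sps.stft(
        audio.samples,
        fs=audio.sample_rate,
        window="hann",
        nperseg=SPEC_WINDOW,
        noverlap=SPEC_WINDOW - SPEC_HOP,
        boundary=None,
        padded=False,
    )
    return Spectrogram(magnitude=np.abs(stft), freqs=freqs, times=times)


def _log_mag(spec: Spectrogram) -> np.ndarray:
    """Log-magnitude with per-column mean removal (spectral shape, not loudness)."""
    log = np.log10(spec.magnitude + 1e-10)
    return log - log.mean(axis=0, keepdims=True)


def _normalized_xcorr_peak(a: np.ndarray, b: np.ndarray, max_lag: int) -> float:
    """Peak over time lags of the normalized 2-D cross-correlation.

    ``a`` and ``b`` are (freq x time) matrices; ``b`` is slid along time.
    Normalization uses the overlapping columns of both matrices, so the score
    is 1.0 for identical content at some lag and gain-invariant throughout.
    """
    na, nb = a.shape[1], b.shape[1]
    best = -1.0
    for lag in range(-max_lag, max_lag + 1):
        a0, a1 = max(0, lag), min(na, nb + lag)
        if a1 - a0 < max(1, min(na, nb) // 2):  # require >=50% overlap
            continue
        b0 = a0 - lag
        asub = a[:, a0:a1]
        bsub = b[:, b0 : b0 + (a1 - a0)]
        denom = np.linalg.norm(asub) * np.linalg.norm(bsub)
        if denom == 0:
            continue
        best = max(best, float(np.sum(asub * bsub) / denom))
    return best


def spectrogram_similarity(
    a: AudioRecording | Spectrogram,
    b: AudioRecording | Spectrogram,
    max_lag_columns: int | None = None,
) -> float:
    """Peak normalized cross-correlation between two log-magnitude spectrograms."""
    sa = a if isinstance(a, Spectrogram) else compute_spectrogram(a)
    sb = b if isinstance(b, Spectrogram) else compute_spectrogram(b)
    if max_lag_columns is None:
        max_lag_columns = abs(sa.magnitude.shape[1] - sb.magnitude.shape[1]) + max(
            2, min(sa.magnitude.shape[1], sb.magnitude.shape[1]) // 4
        )
    return _normalized_xcorr_peak(_log_mag(sa), _log_mag(sb), max_lag_columns)


def detect_motif_candidates(
    audio: AudioRecording,
    template: MotifTemplate,
    peak_threshold: float = DEFAULT_PEAK_THRESHOLD,
) -> list[MotifOccurrence]:
    """Find putative motifs via envelope cross-correlation against the template.

    The sliding Pearson correlation between the recording envelope and the
    template envelope is scanned for local maxima above ``peak_threshold``,
    with non-maximum suppression over one template length.
    """
    env = compute_envelope(audio).values
    tmpl = template.envelope.values
    nt = len(tmpl)
    if nt >= len(env):
        raise ValueError("template is not shorter than the recording")
    t = tmpl - tmpl.mean()
    t_norm = np.linalg.norm(t)
    if t_norm == 0:
        raise ValueError("template envelope is constant")
    # sliding Pearson correlation via convolution identities
    ones = np.ones(nt)
    s1 = np.convolve(env, ones, mode="valid")
    s2 = np.convolve(env**2, ones, mode="valid")
    num = np.convolve(env, t[::-1], mode="valid")  # <env_window, t> (t zero-mean)
    var = np.maximum(s2 - s1**2 / nt, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.where(var > 0, num / (np.sqrt(var) * t_norm), 0.0)
    peaks, _ = sps.find_peaks(corr, height=peak_threshold, distance=nt)
    occs = []
    for p in peaks:
        start = p / ENVELOPE_RATE_HZ
        occs.append(
            MotifOccurrence(
                start=start,
                end=start + template.audio.duration,
                envelope_correlation=float(corr[p]),
            )
        )
    return occs


def filter_by_spectral_similarity(
    audio: AudioRecording,
    candidates: list[MotifOccurrence],
    template: MotifTemplate,
    threshold: float = DEFAULT_SIMILARITY_THRESHOLD,
) -> list[MotifOccurrence]:
    """Score candidates by spectrogram similarity to the template; keep >= threshold."""
    accepted = []
    sr = audio.sample_rate
    for occ in candidates:
        i0 = max(0, int(occ.start * sr))
        i1 = min(len(audio.samples), int(occ.end * sr))
        clip = AudioRecording(samples=audio.samples[i0:i1], sample_rate=sr)
        if len(clip.samples) < SPEC_WINDOW:
            occ.spectral_similarity = 0.0
            occ.accepted = False
            continue
        sim = spectrogram_similarity(clip, template.spectrogram)
        occ.spectral_similarity = sim
        occ.accepted = bool(sim >= threshold)
        if occ.accepted:
            accepted.append(occ)
    return accepted


def segment_bouts(occurrences: list[MotifOccurrence]) -> list[SongBout]:
    """Group motifs separated by less than 500 ms of silence into bouts."""
    occs = sorted(occurrences, key=lambda o: o.start)
    bouts: list[SongBout] = []
    for occ in occs:
        if bouts and occ.start - bouts[-1].end < BOUT_GAP_S:
            bouts[-1].motifs.append(occ)
            bouts[-1].end = max(bouts[-1].end, occ.end)
        else:
            bouts.append(SongBout(start=occ.start, end=occ.end, motifs=[occ]))
    return bouts


@dataclass
class ThresholdRule:
    """Per-motif syllable segmentation threshold.

    threshold = max(min envelope within the motif x ``margin``,
                    background RMS x ``noise_factor``)
    The minimum envelope inside the motif sits in the quietest inter-syllable
    gap; the margin and noise floor make the crossing robust to recording
    noise.  ``background`` defaults to the 10th percentile of the full
    recording envelope.
    """

    margin: float = 1.1
    noise_factor: float = 3.0
    background: float | None = None
    rel_floor: float = 2e-3  # background never below this fraction of the peak

    def threshold(self, motif_env: np.ndarray, full_env: np.ndarray) -> float:
        background = (
            self.background
            if self.background is not None
            else float(np.percentile(full_env, 10))
        )
        # digitally silent stretches would drive the background (and with it
        # the threshold) to zero; keep it above a small fraction of the peak
        background = max(background, self.rel_floor * float(np.max(full_env)))
        return max(
            float(np.min(motif_env)) * self.margin, background * self.noise_factor
        )


def segment_syllables(
    envelope: Envelope,
    motif_window: tuple[float, float],
    threshold_rule: ThresholdRule | None = None,
    min_syllable_ms: float = MIN_SYLLABLE_MS,
    min_gap_ms: float = MIN_GAP_MS,
) -> list[SyllableSegment]:
    """Cut syllables at envelope threshold crossings within one motif window.

    Maximal runs above the per-motif threshold become segments after closing
    sub-``min_gap_ms`` dips and dropping sub-``min_syllable_ms`` blips.
    Segment times are seconds from recording start, half-open [onset, offset).
    """
    rule = threshold_rule or ThresholdRule()
    start_s, end_s = motif_window
    rate = envelope.rate
    i0 = max(0, int(np.floor(start_s * rate)))
    i1 = min(len(envelope.values), int(np.ceil(end_s * rate)))
    if i1 <= i0:
        raise ValueError("motif window outside the envelope")
    motif_env = envelope.values[i0:i1]
    thr = rule.threshold(motif_env, envelope.values)
    above = motif_env > thr
    if not np.any(above):
        warnings.warn("threshold above the envelope maximum; no segments")
        return []

    # close dips shorter than min_gap_ms
    min_gap = int(round(min_gap_ms * rate / 1000.0))
    padded = np.concatenate([[False], above, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts, ends = edges[::2], edges[1::2]
    merged: list[list[int]] = []
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] < min_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    # the RMS window spreads a near-floor crossing outward by ~half the
    # window on each side; pull the boundaries back in by that amount
    shift_s = envelope.smoothing_window_ms / 2000.0
    min_len = int(round(min_syllable_ms * rate / 1000.0))
    segments = []
    for s, e in merged:
        if e - s < min_len:
            continue
        seg_env = motif_env[s:e]
        onset = (i0 + s) / rate + shift_s
        offset = (i0 + e) / rate - shift_s
        if offset <= onset:
            continue
        segments.append(
            SyllableSegment(
                onset=onset,
                offset=offset,
                peak_envelope=float(np.max(seg_env)),
            )
        )
    return segments


def relative_amplitude(
    segment: SyllableSegment, motif_envelope: np.ndarray
) -> float:
    """Peak envelope during the syllable over the peak envelope of the motif."""
    motif_peak = float(np.max(motif_envelope))
    if motif_peak <= 0:
        raise ValueError("motif envelope peak is zero")
    return min(segment.peak_envelope / motif_peak, 1.0)


def estimate_f0_autocorrelation(
    audio: AudioRecording,
    segment: SyllableSegment | None = None,
    f_min: float = DEFAULT_F_MIN,
    f_max: float = DEFAULT_F_MAX,
    harmonicity_threshold: float = DEFAULT_HARMONICITY,
    window_ms: float = DEFAULT_F0_WINDOW_MS,
    window_centers_s: list[float] | None = None,
) -> tuple[float | None, float]:
    """Fundamental frequency of a harmonic syllable from the autocorrelation.

    Per analysis window, the biased normalized autocorrelation is scanned over
    lags [1/f_max, 1/f_min]; F0 is the inverse of the lag of the highest peak,
    refined by parabolic interpolation.  Returns (f0, harmonicity) with
    f0 = None when the peak correlation falls below ``harmonicity_threshold``
    (no clear harmonic structure).  Multiple ``window_centers_s`` may be given
    for syllables whose sub-elements carry distinct fundamentals; the windowed
    estimates are averaged.
    """
    sr = audio.sample_rate
    if not f_min < f_max:
        raise ValueError("need f_min < f_max")
    if f_max > sr / 4:
        raise ValueError("f_max must stay below a quarter of the sample rate")
    lag_min = int(np.floor(sr / f_max))
    lag_max = int(np.ceil(sr / f_min))
    win = int(round(window_ms * sr / 1000.0))
    if win <= lag_max:
        raise ValueError("analysis window too short for the lowest frequency lag")

    if segment is not None:
        s0, s1 = int(segment.onset * sr), int(segment.offset * sr)
    else:
        s0, s1 = 0, len(audio.samples)
    if window_centers_s is None:
        centers = [(s0 + s1) / 2 / sr]
    else:
        centers = window_centers_s

    f0s, scores = [], []
    for c in centers:
        mid = int(c * sr)
        a = max(s0, mid - win // 2)
        x = audio.samples[a : min(s1, a + win)]
        if len(x) <= lag_max:
            continue
        x = x - np.mean(x)
        r0 = float(np.dot(x, x))
        if r0 == 0:
            continue
        # biased autocorrelation: decays with lag, favouring the true period
        # over its multiples
        lags = np.arange(lag_min, lag_max + 1)
        r = np.array([np.dot(x[:-l], x[l:]) for l in lags]) / r0
        peak_idx = int(np.argmax(r))
        score = float(r[peak_idx])
        scores.append(score)
        if score < harmonicity_threshold:
            continue
        # parabolic refinement around the peak
        lag = float(lags[peak_idx])
        if 0 < peak_idx < len(r) - 1:
            y0, y1, y2 = r[peak_idx - 1], r[peak_idx], r[peak_idx + 1]
            denom = y0 - 2 * y1 + y2
            if denom != 0:
                lag += 0.5 * (y0 - y2) / denom
        f0s.append(sr / lag)

    harmonicity = float(np.max(scores)) if scores else 0.0
    if not f0s:
        return None, harmonicity
    return float(np.mean(f0s)), harmonicity


def analyze_motif(
    audio: AudioRecording,
    occurrence: MotifOccurrence,
    envelope: Envelope | None = None,
    threshold_rule: ThresholdRule | None = None,
    estimate_f0: bool = True,
    f0_kwargs: dict | None = None,
    window_pad_s: float = 0.04,
) -> list[SyllableSegment]:
    """Segment one accepted motif and annotate each syllable with features.

    The segmentation window is padded by ``window_pad_s`` on both sides so a
    template-length window does not clip syllables of a rendition that sings
    slightly longer or starts slightly off the detected peak; the pad stays
    well under the shortest inter-motif silence.
    """
    env = envelope or compute_envelope(audio)
    segments = segment_syllables(
        env,
        (occurrence.start - window_pad_s, occurrence.end + window_pad_s),
        threshold_rule,
    )
    motif_env = env.slice(occurrence.start, occurrence.end)
    for i, seg in enumerate(segments):
        seg.type_label = f"syl{i}"
        seg.relative_amplitude = relative_amplitude(seg, motif_env)
        if estimate_f0:
            f0, harm = estimate_f0_autocorrelation(
                audio, segment=seg, **(f0_kwargs or {})
            )
            seg.f0_hz, seg.harmonicity = f0, harm
    return segments
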