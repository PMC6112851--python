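"""Synthetic zebra-finch-like song audio with exact ground truth.

Motifs are built from harmonic stacks (sums of harmonics of a fundamental in
the 400-800 Hz band) and band-limited noise syllables, shaped by trapezoidal
amplitude envelopes with sharp ramps so that envelope-threshold segmentation
has unambiguous ground truth.  Bouts contain 1-3 motifs separated by less
than 500 ms of silence, exercising the bout rule on both sides.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from ..audio import DEFAULT_SAMPLE_RATE, AudioRecording

NOISE_BAND_HZ = (1000.0, 8000.0)  # band of noise syllables
DEFAULT_RAMP_MS = 5.0
INTER_MOTIF_GAP_S = (0.1, 0.45)  # within-bout silence; always under the 500 ms rule
BOUT_PAD_S = 0.6  # silence framing each bout; over the 500 ms rule


@dataclass
class SyllableSpec:
    """Ground-truth description of one syllable."""

    kind: str  # "harmonic" | "noise"
    duration_ms: float
    f0_hz: float | None = None  # harmonic kind only
    n_harmonics: int = 4
    peak_amplitude: float = 0.5
    onset_ramp_ms: float = DEFAULT_RAMP_MS
    offset_ramp_ms: float = DEFAULT_RAMP_MS
    noise_mix: float = 0.0  # fraction of band noise blended into a harmonic syllable

    def __post_init__(self) -> None:
        if self.kind not in ("harmonic", "noise"):
            raise ValueError(f"bad syllable kind {self.kind!r}")
        if self.kind == "harmonic" and self.f0_hz is None:
            raise ValueError("harmonic syllable needs f0_hz")
        if self.duration_ms <= 2 * max(self.onset_ramp_ms, self.offset_ramp_ms):
            raise ValueError("duration must exceed twice the envelope ramps")
        if not 0.0 <= self.peak_amplitude <= 1.0:
            raise ValueError("peak_amplitude must be in [0, 1]")
        if not 0.0 <= self.noise_mix <= 1.0:
            raise ValueError("noise_mix must be in [0, 1]")


@dataclass
class MotifSpec:
    """Ordered syllables and the silent gaps between them."""

    syllables: list[SyllableSpec]
    gaps_ms: list[float]
    noise_floor: float = 0.001

    def __post_init__(self) -> None:
        if len(self.gaps_ms) != len(self.syllables) - 1:
            raise ValueError("need one gap fewer than syllables")
        if any(g <= 0 for g in self.gaps_ms):
            raise ValueError("gaps must be positive")
        if self.syllables and self.noise_floor >= min(
            s.peak_amplitude for s in self.syllables
        ):
            raise ValueError("noise floor must stay below the quietest syllable")

    @property
    def duration_ms(self) -> float:
        return sum(s.duration_ms for s in self.syllables) + sum(self.gaps_ms)


@dataclass
class TrueSyllable:
    """Ground-truth timing and pitch of one rendered syllable."""

    index: int
    kind: str
    onset: float  # s, absolute in the rendition
    offset: float  # s
    f0_hz: float | None
    motif_index: int = 0

    @property
    def duration_ms(self) -> float:
        return (self.offset - self.onset) * 1000.0


@dataclass
class RenditionTruth:
    """Everything the generator knows about one rendered bout."""

    day_dph: int
    rendition: int
    motif_starts: list[float]
    motif_duration_s: float
    syllables: list[TrueSyllable]


def _trapezoid(n: int, ramp_on: int, ramp_off: int) -> np.ndarray:
    env = np.ones(n)
    r_on = min(ramp_on, n // 2)
    r_off = min(ramp_off, n // 2)
    if r_on > 0:
        env[:r_on] = np.linspace(0.0, 1.0, r_on, endpoint=False)
    if r_off > 0:
        env[n - r_off :] = np.linspace(1.0, 0.0, r_off + 1)[1:]
    return env


def _band_noise(n: int, sample_rate: int, rng: np.random.Generator) -> np.ndarray:
    lo, hi = NOISE_BAND_HZ
    hi = min(hi, 0.45 * sample_rate)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=sample_rate, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n + 256))[256:]
    peak = np.max(np.abs(x))
    return x / peak if peak > 0 else x


def synthesize_syllable(
    spec: SyllableSpec,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    seed: int | np.random.Generator = 0,
) -> AudioRecording:
    """Render one syllable.

    Harmonic syllables are a 1/k-weighted sum of sinusoids at k*f0 under a
    trapezoidal envelope; noise syllables are band-limited noise bursts.  The
    output peak equals ``peak_amplitude``.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n = int(round(spec.duration_ms * sample_rate / 1000.0))
    if spec.kind == "harmonic":
        if sample_rate < 4 * spec.f0_hz * spec.n_harmonics:
            raise ValueError(
                "sample_rate below 4x the highest harmonic; aliasing risk"
            )
        t = np.arange(n) / sample_rate
        x = np.zeros(n)
        for k in range(1, spec.n_harmonics + 1):
            x += np.sin(2 * np.pi * k * spec.f0_hz * t) / k
        if spec.noise_mix > 0:
            x_peak = np.max(np.abs(x)) or 1.0
            noise = _band_noise(n, sample_rate, rng) * x_peak
            x = (1 - spec.noise_mix) * x + spec.noise_mix * noise
    else:
        x = _band_noise(n, sample_rate, rng)
    x *= _trapezoid(
        n,
        int(round(spec.onset_ramp_ms * sample_rate / 1000.0)),
        int(round(spec.offset_ramp_ms * sample_rate / 1000.0)),
    )
    peak = np.max(np.abs(x))
    if peak > 0:
        x = x / peak * spec.peak_amplitude
    else:
        x = np.zeros(n)
    return AudioRecording(samples=x, sample_rate=sample_rate)


def synthesize_motif(
    motif: MotifSpec,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    seed: int | np.random.Generator = 0,
) -> tuple[AudioRecording, list[TrueSyllable]]:
    """Render a motif (syllables + gaps + additive noise floor) with ground truth."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    chunks: list[np.ndarray] = []
    truths: list[TrueSyllable] = []
    cursor = 0
    for i, spec in enumerate(motif.syllables):
        syl = synthesize_syllable(spec, sample_rate, rng)
        onset = cursor / sample_rate
        cursor += len(syl.samples)
        truths.append(
            TrueSyllable(
                index=i,
                kind=spec.kind,
                onset=onset,
                offset=cursor / sample_rate,
                f0_hz=spec.f0_hz,
            )
        )
        chunks.append(syl.samples)
        if i < len(motif.gaps_ms):
            gap_n = int(round(motif.gaps_ms[i] * sample_rate / 1000.0))
            chunks.append(np.zeros(gap_n))
            cursor += gap_n
    samples = np.concatenate(chunks) if chunks else np.empty(0)
    if motif.noise_floor > 0:
        samples = samples + motif.noise_floor * rng.standard_normal(len(samples))
    return AudioRecording(samples=samples, sample_rate=sample_rate), truths


def synthesize_bout(
    motif: MotifSpec,
    n_motifs: int,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    seed: int | np.random.Generator = 0,
    day_dph: int | None = None,
    rendition: int = 0,
) -> tuple[AudioRecording, RenditionTruth]:
    """Render one bout: 1-3 motif renditions framed by >500 ms of silence."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    pad = int(round(BOUT_PAD_S * sample_rate))
    chunks = [np.zeros(pad)]
    cursor = pad
    motif_starts: list[float] = []
    syllables: list[TrueSyllable] = []
    motif_dur = 0.0
    for m in range(n_motifs):
        audio_m, truths_m = synthesize_motif(motif, sample_rate, rng)
        start = cursor / sample_rate
        motif_starts.append(start)
        motif_dur = audio_m.duration
        for t in truths_m:
            syllables.append(
                replace(t, onset=t.onset + start, offset=t.offset + start, motif_index=m)
            )
        chunks.append(audio_m.samples)
        cursor += len(audio_m.samples)
        if m < n_motifs - 1:
            gap_s = rng.uniform(*INTER_MOTIF_GAP_S)
            gap_n = int(round(gap_s * sample_rate))
            chunks.append(np.zeros(gap_n))
            cursor += gap_n
    chunks.append(np.zeros(pad))
    samples = np.concatenate(chunks)
    if motif.noise_floor > 0:
        # extend the noise floor over the silent padding as well
        silent = samples == 0
        noise = motif.noise_floor * rng.standard_normal(len(samples))
        samples = samples + np.where(silent, noise, 0.0)
    audio = AudioRecording(
        samples=samples, sample_rate=sample_rate, day_dph=day_dph, rendition=rendition
    )
    truth = RenditionTruth(
        day_dph=day_dph if day_dph is not None else -1,
        rendition=rendition,
        motif_starts=motif_starts,
        motif_duration_s=motif_dur,
        syllables=syllables,
    )
    return audio, truth


def default_motif(
    rng: np.random.Generator | None = None, n_syllables: int = 5
) -> MotifSpec:
    """A canonical 4-6 syllable motif: harmonic stacks and noise syllables.

    With an ``rng``, fundamentals and durations are jittered so each bird gets
    an individual motif within the species-typical ranges (F0 400-800 Hz,
    durations 30-200 ms, gaps 10-100 ms).
    """
    base = [
        SyllableSpec("harmonic", 90.0, f0_hz=600.0, peak_amplitude=0.55),
        SyllableSpec("noise", 60.0, peak_amplitude=0.45),
        SyllableSpec("harmonic", 130.0, f0_hz=450.0, peak_amplitude=0.6),
        SyllableSpec("harmonic", 70.0, f0_hz=750.0, peak_amplitude=0.5),
        SyllableSpec("noise", 110.0, peak_amplitude=0.4),
        SyllableSpec("harmonic", 160.0, f0_hz=520.0, peak_amplitude=0.5),
    ][:n_syllables]
    gaps = [40.0, 25.0, 55.0, 30.0, 45.0][: n_syllables - 1]
    if rng is not None:
        base = [
            replace(
                s,
                duration_ms=float(np.clip(s.duration_ms * rng.uniform(0.85, 1.15), 30, 200)),
                f0_hz=None
                if s.f0_hz is None
                else float(np.clip(s.f0_hz * rng.uniform(0.92, 1.08), 400, 800)),
            )
            for s in base
        ]
        gaps = [float(np.clip(g * rng.uniform(0.8, 1.2), 10, 100)) for g in gaps]
    return MotifSpec(syllables=base, gaps_ms=gaps)


def apply_rendition_variation(
    motif: MotifSpec,
    rng: np.random.Generator,
    duration_factors: np.ndarray | None = None,
    duration_jitter_pct: float = 0.0,
    f0_jitter_pct: float = 0.0,
    noise_mix: float = 0.0,
) -> MotifSpec:
    """Per-rendition copy of a motif with drift and jitter applied.

    ``duration_factors`` (one per syllable) model slow day-by-day drift;
    jitters model rendition-to-rendition variability; ``noise_mix`` degrades
    harmonic structure to emulate an imperfectly learned song.
    """
    n = len(motif.syllables)
    factors = np.ones(n) if duration_factors is None else np.asarray(duration_factors)
    new_syls = []
    for spec, f in zip(motif.syllables, factors):
        jitter = 1.0 + (
            rng.normal(0.0, duration_jitter_pct / 100.0) if duration_jitter_pct else 0.0
        )
        f0 = spec.f0_hz
        if f0 is not None and f0_jitter_pct:
            f0 = f0 * (1.0 + rng.normal(0.0, f0_jitter_pct / 100.0))
        new_syls.append(
            replace(
                spec,
                duration_ms=max(spec.duration_ms * f * jitter, 3 * DEFAULT_RAMP_MS),
                f0_hz=f0,
                noise_mix=noise_mix if spec.kind == "harmonic" else spec.noise_mix,
            )
        )
    return replace(motif, syllables=new_syls)


def synthesize_day(
    motif: MotifSpec,
    day_dph: int,
    n_renditions: int,
    seed: int | np.random.Generator = 0,
    duration_factors: np.ndarray | None = None,
    duration_jitter_pct: float = 2.0,
    f0_jitter_pct: float = 0.5,
    noise_mix: float = 0.0,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
) -> tuple[list[AudioRecording], list[RenditionTruth]]:
    """Render one day of singing: ``n_renditions`` bouts with ground truth."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    bouts, truths = [], []
    for r in range(n_renditions):
        varied = apply_rendition_variation(
            motif,
            rng,
            duration_factors=duration_factors,
            duration_jitter_pct=duration_jitter_pct,
            f0_jitter_pct=f0_jitter_pct,
            noise_mix=noise_mix,
        )
        n_motifs = int(rng.integers(1, 4))
        audio, truth = synthesize_bout(
            varied, n_motifs, sample_rate, rng, day_dph=day_dph, rendition=r
        )
        bouts.append(audio)
        truths.append(truth)
    return bouts, truths
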