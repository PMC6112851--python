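"""Audio container and WAV file IO.

All audio in the pipeline is mono, with samples in [-1, 1] and times in
seconds from the start of the recording.  Files are plain RIFF WAV, either
PCM-16 or float-32, read and written through :mod:`scipy.io.wavfile`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.io import wavfile

DEFAULT_SAMPLE_RATE = 44_100


@dataclass
class AudioRecording:
    """A mono waveform plus provenance metadata.

    Parameters
    ----------
    samples
        Float samples, expected within [-1, 1] after normalization.
    sample_rate
        Samples per second; must exceed twice the highest analysis frequency.
    day_dph
        Age of the bird (days post hatch) when the recording was made, if known.
    rendition
        Index of the rendition/bout within the day, if known.
    """

    samples: np.ndarray
    sample_rate: int = DEFAULT_SAMPLE_RATE
    day_dph: int | None = None
    rendition: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("AudioRecording requires mono (1-D) samples")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return len(self.samples) / self.sample_rate

    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sample_rate

    def scaled(self, gain: float) -> "AudioRecording":
        return replace(self, samples=self.samples * gain)


def read_wav(path: str | Path) -> AudioRecording:
    """Read a mono PCM-16 or float-32 WAV file.

    Raises
    ------
    ValueError
        For multichannel input, unsupported encodings, or a truncated /
        malformed file.
    """
    try:
        rate, data = wavfile.read(str(path))
    except ValueError as exc:  # scipy raises ValueError on bad RIFF chunks
        raise ValueError(f"could not parse WAV file {path}: {exc}") from exc
    if data.ndim != 1:
        raise ValueError(
            f"{path}: expected mono audio, got {data.shape[1]} channels"
        )
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32767.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise ValueError(f"{path}: unsupported WAV encoding {data.dtype}")
    return AudioRecording(samples=samples, sample_rate=int(rate))


def write_wav(
    path: str | Path, audio: AudioRecording, encoding: str = "float32"
) -> None:
    """Write audio as mono WAV (``encoding``: ``"float32"`` or ``"pcm16"``)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if encoding == "float32":
        wavfile.write(str(path), audio.sample_rate, audio.samples.astype(np.float32))
    elif encoding == "pcm16":
        clipped = np.clip(audio.samples, -1.0, 1.0)
        wavfile.write(
            str(path), audio.sample_rate, np.round(clipped * 32767).astype(np.int16)
        )
    else:
        raise ValueError(f"unsupported encoding {encoding!r}")
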