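"""Run configuration: one YAML document holding every pipeline parameter.

Defaults mirror the analysis conventions: 2 ms PSTH bins with a 50 ms
baseline window and a 2.5*SD / two-consecutive-bin detection rule for
high-rate units (10 ms bins, 100 ms baseline for low-rate structures); the
500 ms bout rule; 256-point Hanning / 128-point hop spectrograms; and the
F0 search band for zebra-finch harmonic stacks.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class EphysParams:
    bin_ms: float = 2.0
    pre_ms: float = 50.0
    post_ms: float = 300.0
    baseline_ms: float | None = None  # defaults to pre_ms
    k: float = 2.5
    min_consecutive: int = 2
    artifact_blank_ms: float = 2.0
    strength_mode: str = "first_excitation"


@dataclass
class SongParams:
    smoothing_ms: float = 5.0
    peak_threshold: float = 0.6
    similarity_threshold: float = 0.5
    threshold_margin: float = 1.1
    noise_factor: float = 3.0
    min_syllable_ms: float = 10.0
    min_gap_ms: float = 5.0
    f_min_hz: float = 300.0
    f_max_hz: float = 1500.0
    harmonicity_threshold: float = 0.5
    f0_window_ms: float = 40.0


@dataclass
class LearningParams:
    n_score_bouts: int = 50  # bouts sampled per condition for imitation scoring
    correction: str = "holm"
    test_family: list[str] = field(
        default_factory=lambda: ["duration", "cv_duration", "f0", "cv_f0", "amplitude"]
    )


@dataclass
class RunConfig:
    seed: int = 0
    sample_rate: int = 44_100
    ephys: EphysParams = field(default_factory=EphysParams)
    song: SongParams = field(default_factory=SongParams)
    learning: LearningParams = field(default_factory=LearningParams)
    simulation: dict = field(default_factory=dict)  # generator overrides

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML run configuration; missing keys keep their defaults."""
    cfg = RunConfig()
    if path is None:
        return cfg
    data = yaml.safe_load(Path(path).read_text()) or {}
    for section in ("ephys", "song", "learning"):
        if section in data:
            sub = getattr(cfg, section)
            for key, value in data[section].items():
                if not hasattr(sub, key):
                    raise ValueError(f"unknown {section} parameter {key!r}")
                setattr(sub, key, value)
    for key in ("seed", "sample_rate", "simulation"):
        if key in data:
            setattr(cfg, key, data[key])
    return cfg


def save_config(path: str | Path, cfg: RunConfig) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
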