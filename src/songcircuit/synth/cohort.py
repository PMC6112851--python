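"""Multi-day lesion/sham cohort simulation.

Each simulated bird sings an individual motif across a recording schedule
spanning two pre-surgery days, post-surgery days 1-6, and the crystallization
period (90-91 dph).  A :class:`DriftModel` controls how syllable durations
drift after surgery and how spectral song quality matures, as a function of
the group (sham vs lesion) and of the fraction of the lateral deep cerebellar
nucleus left intact.  The study conditions are the defaults:
surgery around 57 dph, learning-trajectory magnitudes of ~12% (sham) vs ~4%
(lesion) in syllable duration, and imitation improvement scaling with the
intact fraction.

The functional form mapping lesion size to drift is a modelling choice (no
quantitative map exists for the real circuit); it is deliberately simple:
piecewise-constant per-period multiplicative duration factors with
per-syllable signed magnitudes, and a linear intact-fraction -> spectral-
noise map for imitation quality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..audio import DEFAULT_SAMPLE_RATE, AudioRecording
from .song import MotifSpec, RenditionTruth, default_motif, synthesize_day

DEFAULT_RECORDING_DAYS = (55, 56, 58, 59, 60, 61, 62, 63, 90, 91)


@dataclass
class DriftModel:
    """How song changes with age, surgery and lesion size.

    Duration: each syllable carries a random sign and per-syllable magnitudes
    drawn around the group means; the multiplicative day factor is 1 before
    surgery, 1 +/- acute/100 on post days 1-6, and 1 +/- (acute+trajectory)/100
    at crystallization, so the recovered learning trajectory equals the
    configured trajectory by construction.

    Imitation: harmonic syllables are blended with band noise;
    the mix starts at ``immature_noise_mix`` and relaxes toward
    ``mature_noise_mix`` at crystallization by an amount proportional to the
    intact fraction of the lateral DCN.
    """

    acute_duration_pct: float = 2.0
    trajectory_sham_pct: float = 12.0
    trajectory_lesion_pct: float = 4.0
    syllable_trajectory_sd_pct: float = 2.0
    rendition_jitter_pct: float = 2.0
    f0_jitter_pct: float = 0.5
    immature_noise_mix: float = 0.5
    mature_noise_mix: float = 0.08
    learning_intact_gain: float = 1.0
    bird_noise_sd: float = 0.06

    def syllable_plan(
        self, group: str, n_syllables: int, rng: np.random.Generator
    ) -> dict:
        """Draw the per-bird, per-syllable drift magnitudes (fixed for life)."""
        traj_mean = (
            self.trajectory_sham_pct if group == "sham" else self.trajectory_lesion_pct
        )
        signs = rng.choice([-1.0, 1.0], size=n_syllables)
        acute = np.abs(
            rng.normal(self.acute_duration_pct, self.syllable_trajectory_sd_pct / 2, n_syllables)
        )
        traj = np.abs(
            rng.normal(traj_mean, self.syllable_trajectory_sd_pct, n_syllables)
        )
        return {"signs": signs, "acute_pct": acute, "trajectory_pct": traj}

    def duration_factors(
        self, plan: dict, day_dph: int, surgery_day: int
    ) -> np.ndarray:
        rel = day_dph - surgery_day
        if day_dph >= 90:
            change = plan["acute_pct"] + plan["trajectory_pct"]
        elif rel > 0:
            change = plan["acute_pct"]
        else:
            return np.ones(len(plan["signs"]))
        return 1.0 + plan["signs"] * change / 100.0

    def noise_mix(
        self, pct_intact: float, day_dph: int, surgery_day: int, bird_offset: float
    ) -> float:
        """Spectral noise blended into harmonic syllables on a given day."""
        if day_dph < 90:
            return self.immature_noise_mix
        learned = np.clip(
            self.learning_intact_gain * pct_intact / 100.0 + bird_offset, 0.0, 1.0
        )
        mix = self.immature_noise_mix - learned * (
            self.immature_noise_mix - self.mature_noise_mix
        )
        return float(np.clip(mix, 0.0, 0.95))


@dataclass
class CohortConfig:
    """Study design of a simulated lesion/sham cohort."""

    n_lesion: int = 10
    n_sham: int = 6
    surgery_day: int = 57
    recording_days: tuple[int, ...] = DEFAULT_RECORDING_DAYS
    renditions_per_day: int = 500
    intact_range_pct: tuple[float, float] = (30.0, 95.0)
    drift: DriftModel = field(default_factory=DriftModel)
    n_syllables: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        days = set(self.recording_days)
        pre = {self.surgery_day - 2, self.surgery_day - 1}
        post = {self.surgery_day + d for d in range(1, 7)}
        if not (pre <= days and post <= days and {90, 91} <= days):
            raise ValueError(
                "recording_days must cover the two pre days, post days 1-6 "
                "and days 90-91"
            )


@dataclass
class BirdRecord:
    """Per-bird ground truth: identity, lesion extent and drift plan."""

    bird_id: str
    group: str  # "lesion" | "sham"
    surgery_day: int
    pct_intact: float
    motif: MotifSpec
    plan: dict
    noise_offset: float


def _make_birds(config: CohortConfig, rng: np.random.Generator) -> list[BirdRecord]:
    birds = []
    for i in range(config.n_lesion + config.n_sham):
        group = "lesion" if i < config.n_lesion else "sham"
        pct = (
            float(rng.uniform(*config.intact_range_pct))
            if group == "lesion"
            else 100.0
        )
        motif = default_motif(rng, n_syllables=config.n_syllables)
        plan = config.drift.syllable_plan(group, config.n_syllables, rng)
        birds.append(
            BirdRecord(
                bird_id=f"{group[0]}{i:02d}",
                group=group,
                surgery_day=config.surgery_day,
                pct_intact=pct,
                motif=motif,
                plan=plan,
                noise_offset=float(rng.normal(0.0, config.drift.bird_noise_sd)),
            )
        )
    return birds


def simulate_cohort_features(
    config: CohortConfig,
) -> tuple[pd.DataFrame, list[BirdRecord]]:
    """Ground-truth feature table for a cohort, without audio synthesis.

    Emits one row per syllable rendition (bird, group, day_dph, rendition,
    syllable, duration_ms, rel_amplitude, f0_hz), drawn from the same drift
    and jitter model that drives the audio generator.  This is the fast path
    for statistical power studies where the acoustic front end is not under
    test.
    """
    rng = np.random.default_rng(config.seed)
    birds = _make_birds(config, rng)
    drift = config.drift
    rows = []
    for bird in birds:
        base_dur = np.array([s.duration_ms for s in bird.motif.syllables])
        base_f0 = np.array(
            [s.f0_hz if s.f0_hz is not None else np.nan for s in bird.motif.syllables]
        )
        base_amp = np.array([s.peak_amplitude for s in bird.motif.syllables])
        rel_amp = base_amp / base_amp.max()
        for day in config.recording_days:
            factors = drift.duration_factors(bird.plan, day, bird.surgery_day)
            n_syl = len(base_dur)
            jit_d = rng.normal(
                0.0, drift.rendition_jitter_pct / 100.0, (config.renditions_per_day, n_syl)
            )
            jit_f = rng.normal(
                0.0, drift.f0_jitter_pct / 100.0, (config.renditions_per_day, n_syl)
            )
            dur = base_dur * factors * (1.0 + jit_d)
            f0 = base_f0 * (1.0 + jit_f)
            for r in range(config.renditions_per_day):
                for s in range(n_syl):
                    rows.append(
                        (
                            bird.bird_id,
                            bird.group,
                            day,
                            r,
                            f"syl{s}",
                            dur[r, s],
                            rel_amp[s],
                            f0[r, s],
                        )
                    )
    table = pd.DataFrame(
        rows,
        columns=[
            "bird",
            "group",
            "day_dph",
            "rendition",
            "syllable",
            "duration_ms",
            "rel_amplitude",
            "f0_hz",
        ],
    )
    return table, birds


def generate_cohort(
    config: CohortConfig,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    render_days: tuple[int, ...] | None = None,
) -> tuple[dict[str, dict[int, list[AudioRecording]]], dict[str, dict[int, list[RenditionTruth]]], list[BirdRecord]]:
    """Render per-bird daily audio for the whole cohort.

    Returns (audio, truth, birds) where ``audio[bird_id][day]`` is the list of
    bout recordings.  Imitation quality (spectral noise mix) improves from the
    pre period to crystallization by an amount scaling with the intact
    fraction, so the lesion-size / imitation-score dependence downstream is
    positive by construction.  ``render_days`` restricts audio synthesis to a
    subset of the schedule (bird identities and drift plans are unaffected).
    """
    rng = np.random.default_rng(config.seed)
    birds = _make_birds(config, rng)
    days = config.recording_days if render_days is None else tuple(render_days)
    audio: dict[str, dict[int, list[AudioRecording]]] = {}
    truth: dict[str, dict[int, list[RenditionTruth]]] = {}
    for bird in birds:
        audio[bird.bird_id] = {}
        truth[bird.bird_id] = {}
        for day in days:
            factors = config.drift.duration_factors(bird.plan, day, bird.surgery_day)
            mix = config.drift.noise_mix(
                bird.pct_intact, day, bird.surgery_day, bird.noise_offset
            )
            day_seed = rng.integers(0, 2**31 - 1)
            bouts, truths = synthesize_day(
                bird.motif,
                day_dph=day,
                n_renditions=config.renditions_per_day,
                seed=int(day_seed),
                duration_factors=factors,
                duration_jitter_pct=config.drift.rendition_jitter_pct,
                f0_jitter_pct=config.drift.f0_jitter_pct,
                noise_mix=mix,
                sample_rate=sample_rate,
            )
            audio[bird.bird_id][day] = bouts
            truth[bird.bird_id][day] = truths
    return audio, truth, birds
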