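"""Inhomogeneous-Poisson spike-train simulator for stimulation sessions.

The firing rate is baseline + a sum of rectangular response kernels aligned
to each stimulation onset.  Spikes are generated by thinning a homogeneous
Poisson process at the peak rate, which is exact for piecewise-constant
rates.  Rectangular kernels make the expected response strength closed-form
(amplitude x duration), so downstream estimators can be tested analytically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ..ephys import SpikeTrain, StimulationProtocol


@dataclass
class ResponseKernelSpec:
    """Rectangular rate kernel locked to stimulation onset.

    ``amplitude`` (Hz) is added to the baseline over
    [latency, latency + duration) ms after each stimulation; inhibition uses
    ``polarity="inhibition"`` and subtracts it.
    """

    polarity: str  # "excitation" | "inhibition"
    latency_ms: float
    duration_ms: float
    amplitude_hz: float

    def __post_init__(self) -> None:
        if self.polarity not in ("excitation", "inhibition"):
            raise ValueError(f"bad polarity {self.polarity!r}")
        if self.latency_ms < 0 or self.duration_ms <= 0 or self.amplitude_hz < 0:
            raise ValueError("kernel timing/amplitude out of range")

    @property
    def signed_amplitude(self) -> float:
        return self.amplitude_hz if self.polarity == "excitation" else -self.amplitude_hz

    @property
    def end_ms(self) -> float:
        return self.latency_ms + self.duration_ms

    @property
    def expected_strength(self) -> float:
        """Expected excess spikes per stimulation (signed)."""
        return self.signed_amplitude * self.duration_ms / 1000.0


@dataclass
class EphysSimConfig:
    """Parameters of one simulated stimulation session.

    Defaults follow the in-vivo protocol: 1 ms pulses every 1.6 s, pallidal
    baseline rates in the tens of Hz.
    """

    baseline_rate: float = 35.0  # Hz
    kernels: list[ResponseKernelSpec] = field(default_factory=list)
    n_stimulations: int = 100
    inter_stim_interval: float = 1.6  # s
    stim_pulse_ms: float = 1.0
    intensity_ma: float = 1.0
    condition: str = "baseline"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be non-negative")
        if self.n_stimulations < 1:
            raise ValueError("need at least one stimulation")
        for k in self.kernels:
            if k.end_ms / 1000.0 > self.inter_stim_interval:
                raise ValueError("kernel extends past the inter-stimulation interval")
        # exact negativity check at the kernel breakpoints (rates are
        # piecewise constant, so extrema occur between breakpoints)
        edges = sorted(
            {0.0, self.inter_stim_interval * 1000.0}
            | {k.latency_ms for k in self.kernels}
            | {k.end_ms for k in self.kernels}
        )
        for a, b in zip(edges[:-1], edges[1:]):
            mid = 0.5 * (a + b)
            rate = self.baseline_rate + sum(
                k.signed_amplitude
                for k in self.kernels
                if k.latency_ms <= mid < k.end_ms
            )
            if rate < 0:
                raise ValueError(
                    f"instantaneous rate {rate:.1f} Hz < 0 at {mid:.1f} ms; "
                    "inhibition deeper than baseline"
                )

    @property
    def peak_rate(self) -> float:
        edges = sorted(
            {0.0, self.inter_stim_interval * 1000.0}
            | {k.latency_ms for k in self.kernels}
            | {k.end_ms for k in self.kernels}
        )
        peak = self.baseline_rate
        for a, b in zip(edges[:-1], edges[1:]):
            mid = 0.5 * (a + b)
            rate = self.baseline_rate + sum(
                k.signed_amplitude
                for k in self.kernels
                if k.latency_ms <= mid < k.end_ms
            )
            peak = max(peak, rate)
        return peak


def _rate_at(config: EphysSimConfig, rel_ms: np.ndarray) -> np.ndarray:
    """Instantaneous rate (Hz) at offsets ``rel_ms`` after a stimulation onset."""
    rate = np.full(rel_ms.shape, config.baseline_rate)
    for k in config.kernels:
        rate += k.signed_amplitude * (
            (rel_ms >= k.latency_ms) & (rel_ms < k.end_ms)
        )
    return rate


def generate_stim_spike_train(
    config: EphysSimConfig,
) -> tuple[SpikeTrain, StimulationProtocol]:
    """Simulate one stimulation session.

    The session starts one inter-stimulation interval before the first
    stimulation (so the pre-stimulation baseline window is always covered)
    and ends one interval after the last.
    """
    rng = np.random.default_rng(config.seed)
    isi = config.inter_stim_interval
    onsets = isi * (1.0 + np.arange(config.n_stimulations))
    duration = isi * (config.n_stimulations + 2)

    peak = config.peak_rate
    if peak == 0:
        spikes = np.empty(0)
    else:
        n_candidates = rng.poisson(peak * duration)
        candidates = np.sort(rng.uniform(0.0, duration, size=n_candidates))
        # offset of each candidate from the most recent stimulation onset
        prev = np.searchsorted(onsets, candidates, side="right") - 1
        rel_ms = np.where(
            prev >= 0, (candidates - onsets[np.clip(prev, 0, None)]) * 1000.0, np.inf
        )
        rate = np.where(np.isinf(rel_ms), config.baseline_rate, 0.0)
        finite = ~np.isinf(rel_ms)
        rate[finite] = _rate_at(config, rel_ms[finite])
        keep = rng.uniform(0.0, peak, size=len(candidates)) < rate
        spikes = candidates[keep]

    train = SpikeTrain(
        unit_id=f"sim-{config.seed}", spike_times=spikes, session_duration=duration
    )
    protocol = StimulationProtocol(
        onsets=onsets,
        pulse_duration_ms=config.stim_pulse_ms,
        inter_stim_interval=isi,
        intensity_ma=config.intensity_ma,
        condition=config.condition,
    )
    return train, protocol


def generate_condition_series(
    config: EphysSimConfig, scale_factors: list[float]
) -> list[tuple[SpikeTrain, StimulationProtocol]]:
    """One session per factor with kernel amplitudes scaled, baseline unchanged.

    Models a pharmacology sequence (e.g. baseline / drug / washout as
    factors [1, 0, 1]); factors must lie in [0, 1].
    """
    sessions = []
    for i, factor in enumerate(scale_factors):
        if not 0.0 <= factor <= 1.0:
            raise ValueError(f"scale factor {factor} outside [0, 1]")
        scaled = replace(
            config,
            kernels=[
                replace(k, amplitude_hz=k.amplitude_hz * factor)
                for k in config.kernels
            ],
            condition=("baseline", "drug", "washout")[i]
            if len(scale_factors) == 3
            else f"condition_{i}",
            seed=config.seed + i,
        )
        sessions.append(generate_stim_spike_train(scaled))
    return sessions
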