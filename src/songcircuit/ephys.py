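"""Peri-stimulus time histogram (PSTH) analysis of stimulation-evoked responses.

Extracellular spike trains recorded around single-pulse electrical stimulation
are binned into trial-averaged PSTHs.  A unit responds when at least
``min_consecutive`` (default 2) consecutive bins leave the baseline band
(baseline mean +/- k*SD, k = 2.5 by default); the response ends on the return
of two consecutive bins into the band.  From the detected events the module
derives onset latency, response strength (excess spikes per stimulation),
peak firing rate, and a response-profile label, and compares conditions
(baseline / drug / washout) with rank tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .stats import StatResult, wilcoxon_paired, wilcoxon_ranksum

#: PSTH bin width for high-rate structures (pallidal recordings), ms
DEFAULT_BIN_MS = 2.0
#: PSTH bin width for low-rate structures (cortical nuclei), ms
LOW_RATE_BIN_MS = 10.0
#: Baseline window preceding stimulation, ms (high-rate / low-rate structures)
DEFAULT_BASELINE_MS = 50.0
LOW_RATE_BASELINE_MS = 100.0
#: Threshold multiple of the baseline SD
DEFAULT_K = 2.5
#: Bins blanked after stimulus onset (stimulation artifact), ms
DEFAULT_ARTIFACT_BLANK_MS = 2.0
#: Default response search window after stimulus onset, ms
DEFAULT_SEARCH_MS = 300.0

PALLIDAL_RATE_HZ = 25.0  # spontaneous rate above which a unit counts as pallidal
LOW_RATE_HZ = 10.0  # units below this rate are excluded from response analysis


@dataclass
class SpikeTrain:
    """Sorted spike times of one unit over a recording session."""

    unit_id: str
    spike_times: np.ndarray
    session_duration: float

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.ndim != 1:
            raise ValueError("spike_times must be 1-D")
        if np.any(np.diff(self.spike_times) < 0):
            raise ValueError("spike_times must be ascending")
        if len(self.spike_times) and (
            self.spike_times[0] < 0 or self.spike_times[-1] > self.session_duration
        ):
            raise ValueError("spike times must lie within [0, session_duration]")


@dataclass
class StimulationProtocol:
    """Single-pulse stimulation events delivered during a session."""

    onsets: np.ndarray
    pulse_duration_ms: float = 1.0
    inter_stim_interval: float = 1.6
    intensity_ma: float = 1.0
    condition: str = "baseline"

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        if np.any(np.diff(self.onsets) < 0):
            raise ValueError("stimulation onsets must be ascending")

    @property
    def n_stimulations(self) -> int:
        return len(self.onsets)


@dataclass
class PSTH:
    """Trial-averaged firing rate around stimulation onset.

    ``rate_per_bin`` covers ``[-pre_window, post_window)`` ms around onset in
    ``bin_width`` ms bins.  Baseline statistics are computed only from bins
    fully inside the pre-stimulation ``baseline_window``.
    """

    bin_width: float  # ms
    pre_window: float  # ms
    post_window: float  # ms
    rate_per_bin: np.ndarray  # Hz
    n_trials: int
    baseline_mean: float  # Hz
    baseline_sd: float  # Hz
    baseline_window: float  # ms

    def __post_init__(self) -> None:
        self.rate_per_bin = np.asarray(self.rate_per_bin, dtype=float)
        n_expected = int(round((self.pre_window + self.post_window) / self.bin_width))
        if len(self.rate_per_bin) != n_expected:
            raise ValueError(
                f"expected {n_expected} bins, got {len(self.rate_per_bin)}"
            )
        if np.any(self.rate_per_bin < -1e-12):
            raise ValueError("PSTH rates must be non-negative")

    def bin_edges(self) -> np.ndarray:
        """Bin edges in ms relative to stimulation onset."""
        n = len(self.rate_per_bin)
        return -self.pre_window + self.bin_width * np.arange(n + 1)

    def bin_index(self, t_ms: float) -> int:
        """Index of the bin containing time ``t_ms`` (relative to onset)."""
        return int(np.floor((t_ms + self.pre_window) / self.bin_width))


@dataclass
class ResponseEvent:
    """One detected excitatory or inhibitory deviation from baseline."""

    polarity: str  # "excitation" | "inhibition"
    onset_latency: float  # ms after stimulation onset
    offset: float  # ms after stimulation onset
    strength: float  # excess spikes per stimulation (negative for inhibition)
    peak_rate: float  # Hz, extremal PSTH value within the event

    def __post_init__(self) -> None:
        if self.polarity not in ("excitation", "inhibition"):
            raise ValueError(f"bad polarity {self.polarity!r}")
        if not self.offset > self.onset_latency:
            raise ValueError("event offset must exceed onset")


@dataclass
class ResponseProfile:
    """Ordered response events of one unit plus the taxonomy label."""

    events: list[ResponseEvent]
    label: str = field(init=False)

    def __post_init__(self) -> None:
        self.label = classify_profile(self.events)


@dataclass
class UnitClass:
    label: str  # pallidal | low_rate | unclassified
    spontaneous_rate: float  # Hz


def spontaneous_rate(train: SpikeTrain, window: tuple[float, float]) -> float:
    """Mean firing rate (Hz) of a unit within ``window`` = (start_s, end_s)."""
    start, end = window
    if end <= start:
        raise ValueError("empty or inverted window")
    if start < 0 or end > train.session_duration:
        raise ValueError("window outside session")
    count = int(np.sum((train.spike_times >= start) & (train.spike_times < end)))
    return count / (end - start)


def classify_unit(rate: float) -> UnitClass:
    """Classify a unit by spontaneous rate.

    Spontaneously active units above 25 Hz are putative pallidal-like
    projection neurons; units under 10 Hz (striatal-like) are excluded from
    the evoked-response analysis; rates in between stay unclassified.
    """
    if rate < 0:
        raise ValueError("negative firing rate")
    if rate > PALLIDAL_RATE_HZ:
        label = "pallidal"
    elif rate < LOW_RATE_HZ:
        label = "low_rate"
    else:
        label = "unclassified"
    return UnitClass(label=label, spontaneous_rate=rate)


def compute_psth(
    train: SpikeTrain,
    protocol: StimulationProtocol,
    bin_width: float = DEFAULT_BIN_MS,
    pre: float = DEFAULT_BASELINE_MS,
    post: float = DEFAULT_SEARCH_MS,
    baseline_window: float | None = None,
) -> PSTH:
    """Build the trial-averaged PSTH around each stimulation onset.

    Parameters are in ms.  ``baseline_window`` defaults to the full
    pre-stimulation window; it may be shorter but not longer than ``pre``.
    """
    if protocol.n_stimulations < 1:
        raise ValueError("need at least one stimulation")
    n_bins_pre = (pre + 1e-9) / bin_width
    n_bins_post = (post + 1e-9) / bin_width
    if abs(n_bins_pre - round(n_bins_pre)) > 1e-6 or abs(
        n_bins_post - round(n_bins_post)
    ) > 1e-6:
        raise ValueError("bin_width must divide pre and post windows")
    if baseline_window is None:
        baseline_window = pre
    if baseline_window > pre:
        raise ValueError("baseline_window cannot exceed the pre window")
    if protocol.n_stimulations > 1:
        min_gap = float(np.min(np.diff(protocol.onsets)))
        if min_gap * 1000.0 < pre + post:
            raise ValueError(
                "stimulation spacing shorter than the analysis window"
            )

    n_bins = int(round(n_bins_pre + n_bins_post))
    counts = np.zeros(n_bins)
    pre_s, post_s = pre / 1000.0, post / 1000.0
    bin_s = bin_width / 1000.0
    spikes = train.spike_times
    for onset in protocol.onsets:
        rel = spikes[(spikes >= onset - pre_s) & (spikes < onset + post_s)] - onset
        idx = np.floor((rel + pre_s) / bin_s).astype(int)
        np.add.at(counts, np.clip(idx, 0, n_bins - 1), 1)
    rates = counts / (protocol.n_stimulations * bin_s)

    n_baseline_bins = int(round(baseline_window / bin_width))
    first_baseline = int(round(n_bins_pre)) - n_baseline_bins
    baseline = rates[first_baseline : int(round(n_bins_pre))]
    baseline_mean = float(np.mean(baseline))
    baseline_sd = float(np.std(baseline, ddof=0))
    return PSTH(
        bin_width=bin_width,
        pre_window=pre,
        post_window=post,
        rate_per_bin=rates,
        n_trials=protocol.n_stimulations,
        baseline_mean=baseline_mean,
        baseline_sd=baseline_sd,
        baseline_window=baseline_window,
    )


def _event_from_bins(
    psth: PSTH, polarity: str, first_bin: int, last_bin: int
) -> ResponseEvent:
    """Build a ResponseEvent from inclusive bin indices of the response run."""
    edges = psth.bin_edges()
    onset = float(edges[first_bin])
    offset = float(edges[last_bin + 1])
    seg = psth.rate_per_bin[first_bin : last_bin + 1]
    strength = float(np.sum(seg - psth.baseline_mean) * psth.bin_width / 1000.0)
    peak = float(np.max(seg)) if polarity == "excitation" else float(np.min(seg))
    return ResponseEvent(
        polarity=polarity,
        onset_latency=onset,
        offset=offset,
        strength=strength,
        peak_rate=peak,
    )


def detect_response_events(
    psth: PSTH,
    k: float = DEFAULT_K,
    min_consecutive: int = 2,
    artifact_blank: float = DEFAULT_ARTIFACT_BLANK_MS,
    search_window: float | None = None,
    sd_floor: str = "poisson",
) -> list[ResponseEvent]:
    """Detect excitatory/inhibitory responses in the post-stimulation PSTH.

    A response starts at the first of ``min_consecutive`` consecutive bins
    strictly beyond baseline mean +/- ``k``*SD and ends when two consecutive
    bins return inside the band (the event offset is the end of the last
    beyond-threshold bin).  Bins within ``artifact_blank`` ms after onset are
    excluded.  A single opposite-polarity bin inside a response does not split
    it; ``min_consecutive`` opposite bins terminate the current event and
    start a new one.

    The baseline SD is estimated from a few tens of baseline bins and is
    therefore noisy; when it is underestimated, the detection band narrows
    and noise bins leak through.  Spike counts can hardly be less dispersed
    than a Poisson process, so with ``sd_floor="poisson"`` (the default) the
    band never drops below the Poisson counting SD
    sqrt(mean / (n_trials * bin_s)); pass ``sd_floor="none"`` for the raw
    empirical band.  A silent (zero-SD, zero-mean) baseline falls back to a
    one-spike floor so the band never collapses entirely.
    """
    sd = psth.baseline_sd
    bin_s = psth.bin_width / 1000.0
    if sd_floor == "poisson":
        sd = max(
            sd,
            float(np.sqrt(max(psth.baseline_mean, 0.0) / (psth.n_trials * bin_s))),
        )
    elif sd_floor != "none":
        raise ValueError(f"unknown sd_floor {sd_floor!r}")
    if sd == 0 and not np.allclose(psth.rate_per_bin, psth.rate_per_bin[0]):
        # zero-mean baseline: unit Poisson floor of one spike
        sd = float(1.0 / (psth.n_trials * bin_s))
        warnings.warn(
            "baseline SD is zero; using a one-spike floor for the threshold"
        )
    hi = psth.baseline_mean + k * sd
    lo = psth.baseline_mean - k * sd

    if search_window is None:
        search_window = psth.post_window
    search_window = min(search_window, psth.post_window)
    first_bin = psth.bin_index(artifact_blank)
    if artifact_blank % psth.bin_width:  # partial bin touched by artifact: skip it
        first_bin += 1
    first_bin = max(first_bin, psth.bin_index(0.0))
    last_bin = psth.bin_index(search_window - 1e-9)

    # sign per bin: +1 above band, -1 below, 0 inside
    rates = psth.rate_per_bin
    signs = np.zeros(len(rates), dtype=int)
    signs[rates > hi] = 1
    signs[rates < lo] = -1

    events: list[ResponseEvent] = []
    i = first_bin
    cur_pol = 0  # polarity of the open event, 0 when idle
    cur_start = -1
    cur_last_beyond = -1

    def close_event() -> None:
        nonlocal cur_pol, cur_start, cur_last_beyond
        if cur_pol != 0:
            pol = "excitation" if cur_pol > 0 else "inhibition"
            events.append(_event_from_bins(psth, pol, cur_start, cur_last_beyond))
        cur_pol, cur_start, cur_last_beyond = 0, -1, -1

    while i <= last_bin:
        s = signs[i]
        if cur_pol == 0:
            run_ok = (
                s != 0
                and i + min_consecutive - 1 <= last_bin
                and np.all(signs[i : i + min_consecutive] == s)
            )
            if run_ok:
                cur_pol, cur_start, cur_last_beyond = s, i, i
            i += 1
            continue
        # an event is open
        if s == cur_pol:
            cur_last_beyond = i
            i += 1
        elif s == -cur_pol and i + min_consecutive - 1 <= last_bin and np.all(
            signs[i : i + min_consecutive] == s
        ):
            # sustained opposite excursion: new event starts immediately
            close_event()
            cur_pol, cur_start, cur_last_beyond = s, i, i
            i += 1
        elif s == 0 and (i + 1 > last_bin or signs[i + 1] != cur_pol):
            # two in-band (or non-same-polarity) bins end the response
            if i + 1 > last_bin or signs[i + 1] == 0:
                close_event()
                i += 1
            else:
                # single in-band bin followed by opposite excursion
                close_event()
                i += 1
        else:
            # single interrupting bin; response continues
            i += 1
    close_event()
    return events


def first_response_latency(profile: ResponseProfile | list[ResponseEvent]) -> float | None:
    """Onset latency (ms) of the earliest response event, or None if silent."""
    events = profile.events if isinstance(profile, ResponseProfile) else profile
    if not events:
        return None
    return min(e.onset_latency for e in events)


def response_strength(
    psth: PSTH,
    events: list[ResponseEvent],
    mode: str = "first_excitation",
) -> float:
    """Excess spikes per stimulation over the response period.

    ``mode="first_excitation"`` integrates PSTH-minus-baseline over the first
    excitatory event only (the convention for pallidal and premotor units,
    where responses rarely show a second peak); ``mode="total"`` sums every
    excitatory event (used for cortical units with bimodal responses).
    Returns 0.0 when no excitatory event exists.
    """
    if mode not in ("first_excitation", "total"):
        raise ValueError(f"bad mode {mode!r}")
    exc = [e for e in events if e.polarity == "excitation"]
    if not exc:
        warnings.warn("no excitatory event; response strength is 0")
        return 0.0
    if mode == "first_excitation":
        exc = exc[:1]
    return float(sum(e.strength for e in exc))


def peak_response_rate(psth: PSTH, events: list[ResponseEvent]) -> float:
    """Maximal PSTH value (Hz) within the excitatory response events."""
    exc = [e for e in events if e.polarity == "excitation"]
    if not exc:
        raise ValueError("no excitatory events")
    return float(max(e.peak_rate for e in exc))


def classify_profile(events: list[ResponseEvent]) -> str:
    """Label the event sequence per the response taxonomy.

    [] -> none; [exc] -> excitation_only; [exc, inh] -> biphasic;
    [inh, exc, inh] -> triphasic; anything else -> other.
    """
    pols = tuple(e.polarity[0] for e in events)  # 'e' / 'i'
    mapping = {
        (): "none",
        ("e",): "excitation_only",
        ("e", "i"): "biphasic",
        ("i", "e", "i"): "triphasic",
    }
    return mapping.get(pols, "other")


def percent_resting_response(
    strength_condition: float, strength_baseline: float
) -> float:
    """Response strength under a drug as a percentage of the baseline strength."""
    if strength_baseline <= 0:
        raise ValueError("baseline strength must be positive")
    return 100.0 * strength_condition / strength_baseline


def compare_conditions(values_a, values_b, paired: bool = True) -> StatResult:
    """Compare response measures between two conditions.

    Paired comparisons (same units, baseline vs drug) use the Wilcoxon
    signed-rank test; unpaired ones the rank-sum test.
    """
    if paired:
        return wilcoxon_paired(values_a, values_b)
    return wilcoxon_ranksum(values_a, values_b)


def analyze_unit(
    train: SpikeTrain,
    protocol: StimulationProtocol,
    bin_width: float = DEFAULT_BIN_MS,
    pre: float = DEFAULT_BASELINE_MS,
    post: float = DEFAULT_SEARCH_MS,
    baseline_window: float | None = None,
    k: float = DEFAULT_K,
    artifact_blank: float = DEFAULT_ARTIFACT_BLANK_MS,
    strength_mode: str = "first_excitation",
) -> dict:
    """Full single-unit analysis: PSTH, events, profile, latency, strength, peak."""
    psth = compute_psth(train, protocol, bin_width, pre, post, baseline_window)
    events = detect_response_events(psth, k=k, artifact_blank=artifact_blank)
    profile = ResponseProfile(events=events)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        strength = response_strength(psth, events, mode=strength_mode)
    peak = None
    if any(e.polarity == "excitation" for e in events):
        peak = peak_response_rate(psth, events)
    return {
        "unit_id": train.unit_id,
        "condition": protocol.condition,
        "psth": psth,
        "events": events,
        "profile": profile,
        "label": profile.label,
        "latency_ms": first_response_latency(profile),
        "strength_spikes": strength,
        "peak_hz": peak,
    }
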