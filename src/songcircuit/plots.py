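"""Diagnostic figures: PSTHs with confidence bands, segmentation overlays,
latency histograms and per-period feature distributions.

Plots are best-effort diagnostics; failures are logged, never fatal.
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .ephys import PSTH, ResponseEvent
from .song import Envelope, SyllableSegment

log = logging.getLogger(__name__)


def plot_psth(
    psth: PSTH,
    events: list[ResponseEvent] | None = None,
    k: float = 2.5,
    path: str | Path | None = None,
    title: str = "",
):
    """PSTH bar plot with the baseline mean and the +/- k*SD confidence band."""
    fig, ax = plt.subplots(figsize=(7, 3.5))
    edges = psth.bin_edges()
    centers = 0.5 * (edges[:-1] + edges[1:])
    ax.bar(centers, psth.rate_per_bin, width=psth.bin_width, color="0.3")
    ax.axhline(psth.baseline_mean, color="k", ls="--", lw=1, label="baseline mean")
    for sign in (1, -1):
        ax.axhline(
            psth.baseline_mean + sign * k * psth.baseline_sd,
            color="r",
            ls=":",
            lw=1,
            label=f"mean ± {k}·SD" if sign == 1 else None,
        )
    if events:
        for e in events:
            ax.axvspan(
                e.onset_latency,
                e.offset,
                color="tab:orange" if e.polarity == "excitation" else "tab:blue",
                alpha=0.2,
            )
    ax.axvline(0, color="g", lw=1)
    ax.set_xlabel("time from stimulation (ms)")
    ax.set_ylabel("firing rate (Hz)")
    ax.set_title(title)
    ax.legend(loc="upper right", fontsize=8)
    return _finish(fig, path)


def plot_latency_histogram(latencies_ms, path=None, bin_ms: float = 2.0):
    fig, ax = plt.subplots(figsize=(5, 3.5))
    lat = np.asarray([x for x in latencies_ms if x is not None])
    if len(lat):
        ax.hist(lat, bins=np.arange(0, lat.max() + bin_ms, bin_ms), color="0.4")
    ax.set_xlabel("response latency (ms)")
    ax.set_ylabel("units")
    return _finish(fig, path)


def plot_segmentation(
    envelope: Envelope,
    segments: list[SyllableSegment],
    threshold: float | None = None,
    path=None,
):
    """Envelope with syllable onset/offset markers at the threshold crossings."""
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.plot(envelope.times(), envelope.values, color="0.2", lw=0.8)
    if threshold is not None:
        ax.axhline(threshold, color="r", ls=":", lw=1)
    for seg in segments:
        ax.axvline(seg.onset, color="tab:green", lw=0.8)
        ax.axvline(seg.offset, color="tab:red", lw=0.8)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("envelope (RMS)")
    return _finish(fig, path)


def plot_feature_by_period(trajectories, column: str, path=None):
    """Distribution of a per-syllable measure split by group (sham vs lesion)."""
    fig, ax = plt.subplots(figsize=(4, 3.5))
    groups = ["sham", "lesion"]
    data = [
        trajectories.loc[trajectories["group"] == g, column].dropna().to_numpy()
        for g in groups
    ]
    if any(len(d) for d in data):
        ax.boxplot([d for d in data if len(d)], tick_labels=[g for g, d in zip(groups, data) if len(d)])
    ax.set_ylabel(column)
    return _finish(fig, path)


def _finish(fig, path):
    if path is None:
        return fig
    try:
        fig.tight_layout()
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        fig.savefig(path, dpi=110)
    except Exception:  # pragma: no cover - plotting must never kill a run
        log.exception("failed to render %s", path)
    finally:
        plt.close(fig)
    return None
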