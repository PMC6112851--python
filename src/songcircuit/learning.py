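"""Learning-trajectory and cohort statistics for song features.

Per-syllable features are grouped into experimental periods (two pre-surgery
days; post days 1-2, 3-4, 5-6; crystallization at 90-91 dph).  For each
syllable type the module computes the relative change of a feature against
the pre period (|post/pre - 1| x 100, a percent change), rendition-to-
rendition variability (CV), and the learning trajectory (relative change at
crystallization minus relative change at post days 5-6).  Imitation quality
is measured by a spectrogram cross-correlation similarity score against the
tutor motif, normalized as crystallization / pre; the dependence of that
ratio on lesion size is tested with Pearson correlation, and group contrasts
with rank tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .audio import AudioRecording
from .song import MotifTemplate, Spectrogram, spectrogram_similarity
from .stats import StatResult, pearson_correlation, run_test

PERIODS = ("pre", "post_1_2", "post_3_4", "post_5_6", "crystallization")
CRYSTALLIZATION_DAYS = (90, 91)


@dataclass
class PeriodSummary:
    """Per-syllable-type feature statistics within one period."""

    syllable: str
    period: str
    mean: float
    sd: float
    cv: float
    n: int


@dataclass
class RelativeChange:
    """Percent change of a feature vs the pre period (absolute value)."""

    syllable: str
    period: str
    value_pct: float  # 100 * |post/pre - 1|
    ratio: float  # raw post/pre ratio, sign-preserving


@dataclass
class TrajectoryResult:
    """Learning trajectory: signed difference of relative changes (pct points)."""

    syllable: str
    trajectory_pct: float


@dataclass
class LesionRecord:
    """Cohort metadata plus imitation scores for one bird."""

    bird_id: str
    group: str  # lesion | sham
    pct_intact: float
    imitation_pre: float | None = None
    imitation_crystallization: float | None = None

    def __post_init__(self) -> None:
        if self.group == "sham" and self.pct_intact != 100.0:
            raise ValueError("sham birds have 100% intact DCN")

    @property
    def normalized_score(self) -> float | None:
        if self.imitation_pre is None or self.imitation_crystallization is None:
            return None
        return normalized_imitation(self.imitation_pre, self.imitation_crystallization)


def assign_periods(table: pd.DataFrame, surgery_day: int | dict) -> pd.DataFrame:
    """Label feature rows with experimental periods.

    ``surgery_day`` is a dph integer or a {bird: dph} mapping.  Pre covers the
    two days before surgery; post windows are day offsets from surgery;
    crystallization is 90-91 dph; other days get an empty label.  Birds with
    no pre-period rows are flagged in the ``missing_pre`` attribute.
    """
    out = table.copy()
    if isinstance(surgery_day, dict):
        sday = out["bird"].map(surgery_day)
    else:
        sday = pd.Series(surgery_day, index=out.index)
    rel = out["day_dph"] - sday
    period = pd.Series("", index=out.index, dtype=object)
    period[out["day_dph"].isin(CRYSTALLIZATION_DAYS)] = "crystallization"
    period[(rel >= -2) & (rel <= -1)] = "pre"
    period[(rel >= 1) & (rel <= 2)] = "post_1_2"
    period[(rel >= 3) & (rel <= 4)] = "post_3_4"
    period[(rel >= 5) & (rel <= 6)] = "post_5_6"
    out["period"] = period
    missing = [
        b
        for b, g in out.groupby("bird")
        if not (g["period"] == "pre").any()
    ]
    out.attrs["missing_pre"] = missing
    return out


def summarize_periods(
    table: pd.DataFrame, feature: str = "duration_ms"
) -> list[PeriodSummary]:
    """Per (bird, syllable, period) mean/SD/CV of one feature column."""
    labeled = table[table["period"] != ""]
    summaries = []
    for (bird, syl, period), g in labeled.groupby(["bird", "syllable", "period"]):
        vals = g[feature].dropna().to_numpy()
        if len(vals) == 0:
            continue
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        summaries.append(
            PeriodSummary(
                syllable=f"{bird}:{syl}",
                period=period,
                mean=mean,
                sd=sd,
                cv=sd / mean if mean else np.nan,
                n=len(vals),
            )
        )
    return summaries


def relative_change(pre: PeriodSummary, post: PeriodSummary) -> RelativeChange:
    """Percent change of the post-period mean against the pre-period mean.

    The value is the absolute percent change |post/pre - 1| x 100 (reported
    changes are small percentages); the raw sign-preserving ratio is kept
    alongside.
    """
    if pre.syllable != post.syllable:
        raise ValueError("pre and post summaries describe different syllables")
    if pre.mean == 0:
        raise ValueError("pre-period mean is zero")
    ratio = post.mean / pre.mean
    return RelativeChange(
        syllable=pre.syllable,
        period=post.period,
        value_pct=100.0 * abs(ratio - 1.0),
        ratio=ratio,
    )


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Sample SD over mean; scale-invariant rendition-to-rendition variability."""
    vals = np.asarray(values, dtype=float)
    if len(vals) < 2:
        raise ValueError("need at least 2 values")
    mean = float(np.mean(vals))
    if mean <= 0:
        raise ValueError("CV undefined for non-positive mean")
    return float(np.std(vals, ddof=1)) / mean


def learning_trajectory(
    rel_cryst: RelativeChange, rel_post56: RelativeChange
) -> TrajectoryResult:
    """Relative change at crystallization minus relative change at post days 5-6."""
    if rel_cryst.syllable != rel_post56.syllable:
        raise ValueError("relative changes describe different syllables")
    return TrajectoryResult(
        syllable=rel_cryst.syllable,
        trajectory_pct=rel_cryst.value_pct - rel_post56.value_pct,
    )


def feature_trajectories(
    table: pd.DataFrame, feature: str = "duration_ms"
) -> pd.DataFrame:
    """Per-syllable relative changes and learning trajectory for one feature.

    Returns one row per (bird, syllable) with the group label, the relative
    change at each post period, and the trajectory (crystallization minus
    post days 5-6).  Syllables lacking a pre, post_5_6 or crystallization
    summary are dropped.
    """
    summaries = summarize_periods(table, feature)
    by_syl: dict[str, dict[str, PeriodSummary]] = {}
    for s in summaries:
        by_syl.setdefault(s.syllable, {})[s.period] = s
    groups = table.drop_duplicates("bird").set_index("bird")["group"].to_dict()
    rows = []
    for syl, periods in by_syl.items():
        if "pre" not in periods:
            continue
        pre = periods["pre"]
        changes = {
            p: relative_change(pre, periods[p]) for p in PERIODS[1:] if p in periods
        }
        if "post_5_6" not in changes or "crystallization" not in changes:
            continue
        traj = learning_trajectory(changes["crystallization"], changes["post_5_6"])
        bird = syl.split(":")[0]
        rows.append(
            {
                "bird": bird,
                "group": groups.get(bird, ""),
                "syllable": syl,
                **{f"rel_{p}_pct": c.value_pct for p, c in changes.items()},
                "trajectory_pct": traj.trajectory_pct,
                "cv_pre": pre.cv,
                "cv_post_5_6": periods["post_5_6"].cv,
            }
        )
    return pd.DataFrame(rows)


def compare_trajectories(
    trajectories: pd.DataFrame, column: str = "trajectory_pct"
) -> StatResult:
    """Sham vs lesion contrast of per-syllable trajectories (rank-sum test).

    Groups contain different birds, so the unpaired rank-sum variant is used.
    """
    sham = trajectories.loc[trajectories["group"] == "sham", column].to_numpy()
    lesion = trajectories.loc[trajectories["group"] == "lesion", column].to_numpy()
    return run_test((sham, lesion), kind="wilcoxon_ranksum")


def spectrogram_similarity_score(
    songs: Sequence[AudioRecording],
    template: MotifTemplate | Spectrogram,
    n_sample: int | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Similarity of each song to the tutor motif, and the mean over songs.

    Per song: peak over time lag of the normalized cross-correlation between
    the log-magnitude spectrograms of song and template.  When ``n_sample``
    is given, that many songs are sampled without replacement with a seeded
    generator (the analysis convention is 50-100 clean bouts per condition).
    """
    spec = template.spectrogram if isinstance(template, MotifTemplate) else template
    songs = list(songs)
    if n_sample is not None and n_sample < len(songs):
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(songs), size=n_sample, replace=False)
        songs = [songs[i] for i in sorted(idx)]
    scores = np.array([spectrogram_similarity(s, spec) for s in songs])
    return scores, float(np.mean(scores)) if len(scores) else float("nan")


def normalized_imitation(score_pre: float, score_cryst: float) -> float:
    """Imitation score at crystallization over the pre-surgery score (>1 = improved)."""
    if score_pre <= 0:
        raise ValueError("pre-surgery imitation score must be positive")
    return score_cryst / score_pre


def lesion_size_correlation(records: Sequence[LesionRecord]) -> StatResult:
    """Pearson correlation between intact DCN fraction and normalized imitation."""
    pairs = [
        (r.pct_intact, r.normalized_score)
        for r in records
        if r.normalized_score is not None
    ]
    if len(pairs) < 3:
        raise ValueError("need at least 3 birds with both scores")
    x, y = zip(*pairs)
    return pearson_correlation(np.array(x), np.array(y))


def pooling_homogeneity(
    table: pd.DataFrame, feature: str = "duration_ms"
) -> dict[str, StatResult]:
    """Kruskal-Wallis checks that variability is homogeneous across birds and
    syllable types before pooling syllables within a group.

    CVs are computed on the pre period only, where no surgery-related drift
    can inflate the spread for some birds but not others.
    """
    labeled = table[table["period"] == "pre"] if "period" in table else table
    cvs = []
    for (bird, syl), g in labeled.groupby(["bird", "syllable"]):
        vals = g[feature].dropna().to_numpy()
        if len(vals) > 1 and np.mean(vals) > 0:
            cvs.append((bird, syl, coefficient_of_variation(vals)))
    frame = pd.DataFrame(cvs, columns=["bird", "syllable", "cv"])
    by_bird = [g["cv"].to_numpy() for _, g in frame.groupby("bird")]
    by_syl = [g["cv"].to_numpy() for _, g in frame.groupby("syllable")]
    out = {}
    if len(by_bird) >= 2 and all(len(g) >= 1 for g in by_bird):
        out["between_birds"] = run_test(by_bird, kind="kruskal_wallis")
    if len(by_syl) >= 2 and all(len(g) >= 1 for g in by_syl):
        out["between_syllables"] = run_test(by_syl, kind="kruskal_wallis")
    return out
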