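"""Leader timelines, score increments and tweak/leap classification.

Throughout, *lower scores are better* — the contest convention.  The
"current leader" at an entry's submission is the best-scoring entry
submitted strictly before it; an entry "takes the lead" when its score
is strictly better than that leader's.  Ties keep the incumbent.

Every entry after the first is compared to the leader in place just
before its submission: for a non-leading entry that is the current
leader it failed to beat, for a leading entry it is the previous leader
it displaced.  An entry whose similarity to that reference exceeds the
high threshold is a *tweak* (an incremental refinement of the dominant
solution); one below the low threshold is a *leap* (a substantially
novel solution).  The dual-threshold mode (default 0.1 / 0.9) leaves a
middle band unclassified; a single-cut mode splits at one boundary.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from codeculture.corpus import CanonicalEntry, Contest
from codeculture.similarity import UndefinedSimilarityError, czekanowski

logger = logging.getLogger(__name__)

Label = Literal["tweak", "leap", "unclassified"]


@dataclass
class LeaderTimeline:
    """Best entry seen so far, per submission index.

    ``leader_index[i]`` is the index (into the contest's entries) of
    the best-scoring entry among entries ``0..i``; ``leader_score`` is
    its score.  Strictly-better comparison, so ties keep the earlier
    entry and the score sequence is non-increasing.
    """

    contest_id: str
    leader_index: np.ndarray
    leader_score: np.ndarray
    entry_ids: list[str]

    @property
    def leader_entry_ids(self) -> list[str]:
        return [self.entry_ids[i] for i in self.leader_index]

    def leader_before(self, i: int) -> int:
        """Index of the current leader at the time entry ``i`` was submitted."""
        if i == 0:
            raise ValueError("the first entry has no leader before it")
        return int(self.leader_index[i - 1])


def compute_leader_timeline(contest: Contest) -> LeaderTimeline:
    """Running best (prefix argmin of score) over submission order."""
    if not contest.entries:
        raise ValueError("empty contest")
    scores = np.array([e.score for e in contest.entries])
    leader_idx = np.empty(len(scores), dtype=int)
    leader_score = np.empty(len(scores))
    best_i, best_s = 0, scores[0]
    for i, s in enumerate(scores):
        if s < best_s:  # strict: ties keep the incumbent
            best_i, best_s = i, s
        leader_idx[i] = best_i
        leader_score[i] = best_s
    return LeaderTimeline(
        contest.contest_id, leader_idx, leader_score, [e.entry_id for e in contest.entries]
    )


def log_transform_scores(scores: Sequence[float], offset: float = 10.0) -> np.ndarray:
    """log(score + offset), the plotting transform for zero-heavy scores."""
    arr = np.asarray(scores, dtype=float) + offset
    if np.any(arr <= 0):
        raise ValueError("score + offset must be positive for the log transform")
    return np.log(arr)


@dataclass
class ScoreIncrement:
    """Absolute score difference of an entry to the current leader."""

    entry_id: str
    raw_delta: float
    normalised_delta: float


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = float(np.min(values)), float(np.max(values))
    if hi == lo:
        logger.warning("degenerate min-max normalisation (all values equal); returning zeros")
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def score_increments(contest: Contest, timeline: LeaderTimeline | None = None) -> list[ScoreIncrement]:
    """Per-entry |score - current leader score|, min-max normalised within the contest.

    The first entry has no leader and is excluded.
    """
    if timeline is None:
        timeline = compute_leader_timeline(contest)
    entries = contest.entries
    if len(entries) < 2:
        return []
    raw = np.array(
        [abs(entries[i].score - timeline.leader_score[i - 1]) for i in range(1, len(entries))]
    )
    norm = _minmax(raw)
    return [
        ScoreIncrement(entries[i].entry_id, float(raw[i - 1]), float(norm[i - 1]))
        for i in range(1, len(entries))
    ]


@dataclass
class ClassificationConfig:
    """Thresholds mapping leader-relative similarity to tweak/leap labels."""

    mode: Literal["dual_threshold", "single_cut"] = "dual_threshold"
    leap_below: float = 0.1
    tweak_above: float = 0.9
    single_cut_at: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.leap_below < self.tweak_above <= 1.0):
            raise ValueError("need 0 <= leap_below < tweak_above <= 1")
        if self.mode not in ("dual_threshold", "single_cut"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def label(self, similarity: float) -> Label:
        if math.isnan(similarity):
            return "unclassified"
        if self.mode == "single_cut":
            return "leap" if similarity < self.single_cut_at else "tweak"
        if similarity < self.leap_below:
            return "leap"
        if similarity > self.tweak_above:
            return "tweak"
        return "unclassified"


@dataclass
class TweakLeapLabel:
    """An entry's leader-relative similarity, label and lead status."""

    entry_id: str
    similarity_to_leader: float
    label: Label
    took_lead: bool
    raw_delta: float
    normalised_delta: float


def classify_contest(
    contest: Contest,
    config: ClassificationConfig | None = None,
    timeline: LeaderTimeline | None = None,
    similarity_fn: Callable[[CanonicalEntry, CanonicalEntry], float] = czekanowski,
) -> list[TweakLeapLabel]:
    """Classify every entry after the first relative to the leader it saw.

    The reference entry is the leader immediately before submission: the
    current leader for entries that did not take the lead, equivalently
    the previous leader for entries that did.
    """
    config = config or ClassificationConfig()
    if timeline is None:
        timeline = compute_leader_timeline(contest)
    increments = {inc.entry_id: inc for inc in score_increments(contest, timeline)}
    labels: list[TweakLeapLabel] = []
    for i in range(1, len(contest.entries)):
        entry = contest.entries[i]
        ref = contest.entries[timeline.leader_before(i)]
        try:
            sim = similarity_fn(entry, ref)
        except UndefinedSimilarityError:
            sim = float("nan")
        took_lead = entry.score < timeline.leader_score[i - 1]
        inc = increments[entry.entry_id]
        labels.append(
            TweakLeapLabel(
                entry_id=entry.entry_id,
                similarity_to_leader=sim,
                label=config.label(sim),
                took_lead=took_lead,
                raw_delta=inc.raw_delta,
                normalised_delta=inc.normalised_delta,
            )
        )
    return labels


@dataclass
class RatioResult:
    """Tweak:leap count ratio over a selection of labelled entries."""

    n_tweaks: int
    n_leaps: int
    leading_only: bool

    @property
    def is_infinite(self) -> bool:
        return self.n_leaps == 0 and self.n_tweaks > 0

    @property
    def ratio(self) -> float:
        if self.n_leaps == 0:
            return float("inf") if self.n_tweaks else float("nan")
        return self.n_tweaks / self.n_leaps


def tweak_leap_ratio(
    labels: Sequence[TweakLeapLabel], leading_only: bool = False
) -> RatioResult:
    """Ratio of tweak to leap counts, over all entries or leading entries only.

    Labels may be pooled across contests before calling.  A selection
    with no leaps yields an infinite-ratio flag rather than an error.
    """
    selected = [l for l in labels if l.took_lead] if leading_only else list(labels)
    n_tweaks = sum(1 for l in selected if l.label == "tweak")
    n_leaps = sum(1 for l in selected if l.label == "leap")
    if n_leaps == 0:
        logger.warning("no leaps in selection (%d tweaks): ratio is infinite", n_tweaks)
    return RatioResult(n_tweaks, n_leaps, leading_only)


@dataclass
class CorrelationResult:
    """Spearman rank correlation with a two-sided p-value."""

    rho: float
    p_value: float
    n: int
    undefined: bool = False


def rank_correlation(
    x: Sequence[float],
    y: Sequence[float],
    permutation_threshold: int = 50,
    n_resamples: int = 10_000,
    seed: int | None = 0,
) -> CorrelationResult:
    """Spearman's rho (average ranks for ties) with a two-sided p-value.

    For n above ``permutation_threshold`` the p-value is the usual
    large-sample approximation; at or below it, a permutation test of
    the pairing is used (exhaustive for very small n, otherwise Monte
    Carlo with ``n_resamples`` draws from the given seed).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3 for a rank correlation")
    if np.all(x == x[0]) or np.all(y == y[0]):
        logger.warning("constant input: rank correlation undefined")
        return CorrelationResult(float("nan"), float("nan"), n, undefined=True)
    if n > permutation_threshold:
        res = stats.spearmanr(x, y)
        return CorrelationResult(float(res.statistic), float(res.pvalue), n)
    rho = float(stats.spearmanr(x, y).statistic)
    perm = stats.permutation_test(
        (x, y),
        lambda a, b: stats.spearmanr(a, b).statistic,
        permutation_type="pairings",
        alternative="two-sided",
        n_resamples=n_resamples,
        rng=np.random.default_rng(seed),
    )
    return CorrelationResult(rho, float(perm.pvalue), n)


def labels_frame(labels: Sequence[TweakLeapLabel]) -> pd.DataFrame:
    """Per-entry results table (one row per classified entry)."""
    return pd.DataFrame(
        {
            "entry_id": [l.entry_id for l in labels],
            "took_lead": [l.took_lead for l in labels],
            "similarity_to_leader": [l.similarity_to_leader for l in labels],
            "label": [l.label for l in labels],
            "raw_delta": [l.raw_delta for l in labels],
            "normalised_delta": [l.normalised_delta for l in labels],
        }
    )


def dynamics_summary(labels: Sequence[TweakLeapLabel]) -> dict:
    """Headline dynamics statistics over a pooled set of labelled entries.

    Returns tweak:leap ratios (all entries and leading only) and the two
    leader-relative correlations: among leading entries, similarity to
    the previous leader vs. the normalised score improvement; among
    non-leading entries, similarity to the current leader vs. the raw
    score deficit.
    """
    leaders = [l for l in labels if l.took_lead and not math.isnan(l.similarity_to_leader)]
    others = [l for l in labels if not l.took_lead and not math.isnan(l.similarity_to_leader)]
    out: dict = {
        "ratio_all": tweak_leap_ratio(labels, leading_only=False),
        "ratio_leading": tweak_leap_ratio(labels, leading_only=True),
    }
    if len(leaders) >= 3:
        out["corr_leading_sim_vs_improvement"] = rank_correlation(
            [l.similarity_to_leader for l in leaders],
            [l.normalised_delta for l in leaders],
        )
    if len(others) >= 3:
        out["corr_nonleading_sim_vs_deficit"] = rank_correlation(
            [l.similarity_to_leader for l in others],
            [l.raw_delta for l in others],
        )
    tweak_incs = [l.normalised_delta for l in leaders if l.label == "tweak"]
    leap_incs = [l.normalised_delta for l in leaders if l.label == "leap"]
    if tweak_incs:
        out["leading_tweak_increment_mean"] = float(np.mean(tweak_incs))
        out["leading_tweak_increment_sd"] = float(np.std(tweak_incs, ddof=1)) if len(tweak_incs) > 1 else 0.0
    if leap_incs:
        out["leading_leap_increment_mean"] = float(np.mean(leap_incs))
        out["leading_leap_increment_sd"] = float(np.std(leap_incs, ddof=1)) if len(leap_incs) > 1 else 0.0
    return out
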