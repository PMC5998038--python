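"""Line provenance: original introducers, recent carriers, recombination.

Each canonical line of each entry is traced back to the *original
source* — the earliest entry in the contest to contain that line — and
to the *recent source* — the most recent prior entry containing it.
Aggregating to distinct entries gives, per entry, the number of
original sources it recombines, the number of immediate sources it
drew on, and how many distinct authors those sources span.  Lines an
entry is itself the first to carry are *novel*, not sourced.

Source counting is per distinct line, aggregated to distinct entries:
an earlier entry contributing many lines still counts as one source.
Because entries are totally ordered (timestamp, then entry id), "most
recent prior carrier" is always unique.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from codeculture.corpus import CanonicalEntry, Contest
from codeculture.dynamics import CorrelationResult, TweakLeapLabel, rank_correlation

logger = logging.getLogger(__name__)


@dataclass
class ProvenanceIndex:
    """Per-line first introducer and time-ordered carrier list.

    Both mappings use entry *indices* into the contest's submission
    order; ``first_introducer[line]`` is always ``carriers[line][0]``.
    """

    contest_id: str
    first_introducer: dict[str, int]
    carriers: dict[str, list[int]]


def build_provenance_index(contest: Contest) -> ProvenanceIndex:
    """Single chronological pass recording who first and who last carried each line."""
    first: dict[str, int] = {}
    carriers: dict[str, list[int]] = {}
    for i, entry in enumerate(contest.entries):
        for line in entry.lines:
            if line not in first:
                first[line] = i
            carriers.setdefault(line, []).append(i)
    return ProvenanceIndex(contest.contest_id, first, carriers)


@dataclass
class SourceProfile:
    """Recombination statistics of one entry."""

    entry_id: str
    n_original_sources: int
    n_recent_sources: int
    n_source_authors: int
    n_novel_lines: int  # occurrences of lines this entry introduced
    n_novel_distinct: int  # distinct lines this entry introduced
    total_lines: int

    @property
    def novel_fraction(self) -> float:
        if self.total_lines == 0:
            return float("nan")
        return self.n_novel_lines / self.total_lines


def _entry_index(contest: Contest, entry: CanonicalEntry | int) -> int:
    if isinstance(entry, int):
        return entry
    return contest.index_of(entry.entry_id)


def recent_sources(
    contest: Contest, entry: CanonicalEntry | int, index: ProvenanceIndex
) -> int:
    """Distinct entries that most recently carried this entry's non-novel lines."""
    i = _entry_index(contest, entry)
    e = contest.entries[i]
    recent: set[int] = set()
    for line in e.lines:
        if index.first_introducer[line] == i:
            continue  # novel line, no prior carrier
        carriers = index.carriers[line]
        pos = bisect_left(carriers, i)
        if pos > 0:
            recent.add(carriers[pos - 1])
    return len(recent)


def source_profile(
    contest: Contest,
    entry: CanonicalEntry | int,
    index: ProvenanceIndex,
    exclude_same_author: bool = False,
) -> SourceProfile:
    """Original/recent source counts and novelty statistics for one entry.

    ``exclude_same_author`` drops source entries by the same author
    (self-refinement) from the original-source count; by default an
    author's own earlier entries do count as sources.
    """
    i = _entry_index(contest, entry)
    e = contest.entries[i]
    original: set[int] = set()
    novel_occurrences = 0
    novel_distinct = 0
    for line, count in e.lines.items():
        intro = index.first_introducer[line]
        if intro == i:
            novel_occurrences += count
            novel_distinct += 1
        else:
            original.add(intro)
    if exclude_same_author:
        original = {k for k in original if contest.entries[k].author_id != e.author_id}
    authors = {contest.entries[k].author_id for k in original}
    return SourceProfile(
        entry_id=e.entry_id,
        n_original_sources=len(original),
        n_recent_sources=recent_sources(contest, i, index),
        n_source_authors=len(authors),
        n_novel_lines=novel_occurrences,
        n_novel_distinct=novel_distinct,
        total_lines=e.total_lines,
    )


def source_profiles(
    contest: Contest,
    index: ProvenanceIndex | None = None,
    exclude_same_author: bool = False,
) -> list[SourceProfile]:
    """Source profile of every entry of a contest, in submission order."""
    if index is None:
        index = build_provenance_index(contest)
    return [
        source_profile(contest, i, index, exclude_same_author)
        for i in range(len(contest.entries))
    ]


def profiles_frame(profiles: Sequence[SourceProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "entry_id": [p.entry_id for p in profiles],
            "n_original_sources": [p.n_original_sources for p in profiles],
            "n_recent_sources": [p.n_recent_sources for p in profiles],
            "n_source_authors": [p.n_source_authors for p in profiles],
            "n_novel_lines": [p.n_novel_lines for p in profiles],
            "novel_fraction": [p.novel_fraction for p in profiles],
        }
    )


def recombination_trend(
    contest: Contest,
    profiles: Sequence[SourceProfile] | None = None,
    labels: Sequence[TweakLeapLabel] | None = None,
) -> dict:
    """Trend and summary statistics of recombination over a contest.

    Returns the Spearman correlation of original-source counts with
    submission index, mean ± SD of original and recent source counts,
    and — when tweak/leap labels are supplied — the same means split by
    label among entries that took the lead.
    """
    if len(contest.entries) < 3:
        raise ValueError("need >=3 entries for a recombination trend")
    if profiles is None:
        profiles = source_profiles(contest)
    orig = np.array([p.n_original_sources for p in profiles], dtype=float)
    rec = np.array([p.n_recent_sources for p in profiles], dtype=float)
    idx = np.arange(len(profiles), dtype=float)
    out: dict = {
        "original_sources_mean": float(orig.mean()),
        "original_sources_sd": float(orig.std(ddof=1)),
        "recent_sources_mean": float(rec.mean()),
        "recent_sources_sd": float(rec.std(ddof=1)),
    }
    if np.all(orig == orig[0]):
        logger.warning("all original-source counts equal; trend correlation undefined")
        out["trend_original_vs_time"] = CorrelationResult(
            float("nan"), float("nan"), len(orig), undefined=True
        )
    else:
        out["trend_original_vs_time"] = rank_correlation(idx, orig)
        out["trend_recent_vs_time"] = rank_correlation(idx, rec)
    if labels is not None:
        by_id = {p.entry_id: p for p in profiles}
        for label_name in ("tweak", "leap"):
            vals = [
                by_id[l.entry_id].n_original_sources
                for l in labels
                if l.took_lead and l.label == label_name and l.entry_id in by_id
            ]
            if vals:
                out[f"leading_{label_name}_original_sources_mean"] = float(np.mean(vals))
            rvals = [
                by_id[l.entry_id].n_recent_sources
                for l in labels
                if l.took_lead and l.label == label_name and l.entry_id in by_id
            ]
            if rvals:
                out[f"leading_{label_name}_recent_sources_mean"] = float(np.mean(rvals))
    return out
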