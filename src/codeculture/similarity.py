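"""Czekanowski similarity between entries and contest-wide matrices.

The Czekanowski index is the multiset (abundance) generalisation of the
Sørensen–Dice coefficient: for two entries with line counts ``x_a`` and
``x_b`` over the union of their distinct lines,

    CZ(a, b) = 2 * sum_j min(x_aj, x_bj) / sum_j (x_aj + x_bj)

It is 1 exactly when the multisets are equal and 0 when they share no
line.  Similarity of two empty entries is undefined and raised (or
recorded as a missing value in matrices), never silently 0 — a genuine
0 means "fully novel", which is a different statement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from codeculture.corpus import CanonicalEntry, Contest, PHASE_DARKNESS

logger = logging.getLogger(__name__)


class UndefinedSimilarityError(ValueError):
    """Both entries are empty: the Czekanowski index has a 0/0 form."""


def shared_line_count(a: CanonicalEntry, b: CanonicalEntry) -> int:
    """Total number of lines two entries have in common, multiplicities included."""
    small, large = (a.lines, b.lines) if len(a.lines) <= len(b.lines) else (b.lines, a.lines)
    return sum(min(c, large[line]) for line, c in small.items() if line in large)


def czekanowski(a: CanonicalEntry, b: CanonicalEntry) -> float:
    """Czekanowski similarity between two entries, in [0, 1]."""
    denom = a.total_lines + b.total_lines
    if denom == 0:
        raise UndefinedSimilarityError(
            f"similarity undefined: entries {a.entry_id!r} and {b.entry_id!r} are both empty"
        )
    return 2.0 * shared_line_count(a, b) / denom


@dataclass
class SimilarityMatrix:
    """Dense symmetric pairwise similarity matrix in submission order.

    ``values[i, j]`` is the similarity of the i-th and j-th entries of
    the contest (chronological order).  Undefined pairs (both entries
    empty) hold NaN.  Diagonal is 1 for non-empty entries.
    """

    contest_id: str
    entry_ids: list[str]
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.entry_ids, columns=self.entry_ids)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    def plot_heatmap(self, path, cmap: str = "viridis") -> None:
        """Chronological heatmap of the matrix (earliest entry top-left)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 6))
        im = ax.imshow(self.values, vmin=0, vmax=1, cmap=cmap, interpolation="nearest")
        ax.set_xlabel("entry (chronological)")
        ax.set_ylabel("entry (chronological)")
        ax.set_title(f"contest {self.contest_id}: pairwise code similarity")
        fig.colorbar(im, ax=ax, shrink=0.8, label="Czekanowski similarity")
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)


def shared_line_matrix(entries: list[CanonicalEntry]) -> np.ndarray:
    """All-pairs shared-line counts via an inverted line index.

    For each distinct line the index holds the entries carrying it and
    their counts; the line contributes ``min(c_i, c_j)`` to every pair
    of carriers.  Cost is the sum of squared carrier-set sizes, far
    below the dense all-pairs-all-lines product for the sparse,
    long-tailed line distributions contests produce.
    """
    inverted: dict[str, tuple[list[int], list[int]]] = {}
    for i, e in enumerate(entries):
        for line, c in e.lines.items():
            idx, cnt = inverted.setdefault(line, ([], []))
            idx.append(i)
            cnt.append(c)
    n = len(entries)
    shared = np.zeros((n, n))
    for idx, cnt in inverted.values():
        if len(idx) == 1:
            i = idx[0]
            shared[i, i] += cnt[0]
            continue
        ii = np.asarray(idx)
        cc = np.asarray(cnt, dtype=float)
        shared[np.ix_(ii, ii)] += np.minimum.outer(cc, cc)
    return shared


def pairwise_matrix(contest: Contest) -> SimilarityMatrix:
    """Pairwise Czekanowski similarity for every entry pair of a contest."""
    entries = contest.entries
    if len(entries) < 2:
        raise ValueError(f"contest {contest.contest_id}: need >=2 entries for a matrix")
    shared = shared_line_matrix(entries)
    totals = np.array([e.total_lines for e in entries], dtype=float)
    denom = totals[:, None] + totals[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        values = 2.0 * shared / denom
    empty = totals == 0
    n_undef = int(empty.sum())
    if n_undef:
        logger.warning(
            "contest %s: %d empty entries; their mutual similarities are NaN",
            contest.contest_id,
            n_undef,
        )
        values[np.ix_(empty, empty)] = np.nan
        # empty vs non-empty is a well-defined 0
        values[np.ix_(empty, ~empty)] = 0.0
        values[np.ix_(~empty, empty)] = 0.0
    np.fill_diagonal(values, np.where(empty, np.nan, 1.0))
    return SimilarityMatrix(contest.contest_id, [e.entry_id for e in entries], values)


def baseline_similarity_distribution(
    contest: Contest, bins: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of pairwise similarities among darkness-phase entries.

    With no social information, entries are independent inventions and
    the distribution is the contest's similarity baseline (skewed to
    zero in real corpora).  Returns ``(counts, bin_edges)`` with
    ``bins`` equal-width bins on [0, 1].
    """
    dark = [e for e in contest.phase_entries(PHASE_DARKNESS) if not e.is_empty]
    edges = np.linspace(0.0, 1.0, bins + 1)
    if len(dark) < 2:
        logger.warning(
            "contest %s: %d non-empty darkness entries; baseline distribution empty",
            contest.contest_id,
            len(dark),
        )
        return np.zeros(bins, dtype=int), edges
    shared = shared_line_matrix(dark)
    totals = np.array([e.total_lines for e in dark], dtype=float)
    iu = np.triu_indices(len(dark), k=1)
    sims = 2.0 * shared[iu] / (totals[:, None] + totals[None, :])[iu]
    counts, _ = np.histogram(sims, bins=edges)
    return counts, edges


def pairwise_values(contest: Contest) -> np.ndarray:
    """Upper-triangle similarity values (all pairs, chronological order)."""
    m = pairwise_matrix(contest)
    iu = np.triu_indices(len(m.entry_ids), k=1)
    return m.values[iu]
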