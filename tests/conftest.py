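"""Shared fixtures: tiny hand-built contests and entry factories."""

from __future__ import annotations

from collections import Counter

import pytest

from codeculture.corpus import CanonicalEntry, Contest


@pytest.fixture
def make_entry():
    """Factory for canonical entries from an explicit line multiset."""

    def _make(
        entry_id: str,
        lines: dict[str, int] | list[str],
        score: float = 1.0,
        timestamp: float | None = None,
        author_id: str = "alice",
        phase: str = "daylight",
        contest_id: str = "c1",
    ) -> CanonicalEntry:
        counts = Counter(lines) if isinstance(lines, list) else Counter(dict(lines))
        ts = timestamp if timestamp is not None else float(int(entry_id.lstrip("e") or 0))
        return CanonicalEntry(
            contest_id=contest_id,
            entry_id=entry_id,
            author_id=author_id,
            timestamp=ts,
            score=score,
            phase=phase,
            lines=counts,
        )

    return _make


@pytest.fixture
def make_contest(make_entry):
    """Factory for a contest from (entry_id, lines, score[, author]) tuples."""

    def _make(rows, contest_id: str = "c1", phase: str = "daylight") -> Contest:
        entries = []
        for t, row in enumerate(rows):
            entry_id, lines, score = row[0], row[1], row[2]
            author = row[3] if len(row) > 3 else f"author{t}"
            entries.append(
                make_entry(
                    entry_id,
                    lines,
                    score=score,
                    timestamp=float(t),
                    author_id=author,
                    phase=phase,
                    contest_id=contest_id,
                )
            )
        return Contest(contest_id, entries)

    return _make
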