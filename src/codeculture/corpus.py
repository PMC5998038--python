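"""Corpus ingestion: canonical lines, entry multisets, contest containers.

An entry's source text is reduced to a multiset of *canonical lines*:
each physical line is lowercased and stripped of all whitespace, so two
lines count as the same cultural trait when they consist of the same
characters, in the same order, ignoring spacing and capitalisation.
Lines that canonicalize to the empty string are dropped — they carry no
content and would otherwise make every entry resemble every other.

Contests arrive as delimited-text manifests (one row per entry) with the
source either inline (``source_text`` column, quoted newlines) or in a
per-entry file referenced by a ``source_path`` column relative to the
manifest.  Entries are sorted by timestamp, ties broken by entry id, so
every downstream "who came first" question has a deterministic answer.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PHASE_DARKNESS = "darkness"
PHASE_DAYLIGHT = "daylight"
_KNOWN_PHASES = {PHASE_DARKNESS, "twilight", PHASE_DAYLIGHT}

_WS_RE = re.compile(r"\s+")

MANIFEST_COLUMNS = ["contest_id", "entry_id", "author_id", "timestamp", "score", "phase"]


def canonicalize_line(raw: str) -> str:
    """Canonical form of one physical source line.

    All whitespace (any Unicode whitespace, not just ASCII spaces and
    tabs) is removed and all characters are lowercased; character order
    is preserved.  Idempotent by construction.

    Raises
    ------
    ValueError
        If ``raw`` contains a newline — it is then not a single line.
    """
    if "\n" in raw or "\r" in raw:
        raise ValueError(f"canonicalize_line expects a single line, got embedded newline: {raw!r}")
    return _WS_RE.sub("", raw).lower()


def build_line_multiset(source_text: str) -> Counter:
    """Multiset of canonical lines of a source text.

    Splits on newlines, canonicalizes each line and counts
    multiplicities.  Lines that canonicalize to the empty string
    (blank or whitespace-only lines) are dropped.
    """
    counts: Counter = Counter()
    if not source_text:
        return counts
    # only \n / \r\n / \r delimit lines; other vertical whitespace
    # (form feed, NEL, ...) is stripped by canonicalization instead
    normalized = source_text.replace("\r\n", "\n").replace("\r", "\n")
    for raw in normalized.split("\n"):
        key = canonicalize_line(raw)
        if key:
            counts[key] += 1
    return counts


@dataclass(frozen=True)
class CanonicalEntry:
    """One contest entry: metadata plus its canonical-line multiset."""

    contest_id: str
    entry_id: str
    author_id: str
    timestamp: float
    score: float
    phase: str
    lines: Counter = field(compare=False)

    def __post_init__(self) -> None:
        if not np.isfinite(self.score):
            raise ValueError(f"entry {self.entry_id}: score must be finite, got {self.score}")
        if self.phase not in (PHASE_DARKNESS, PHASE_DAYLIGHT):
            raise ValueError(f"entry {self.entry_id}: unknown phase {self.phase!r}")

    @property
    def total_lines(self) -> int:
        """Number of non-blank physical lines (multiplicities counted)."""
        return sum(self.lines.values())

    @property
    def n_unique_lines(self) -> int:
        return len(self.lines)

    @property
    def is_empty(self) -> bool:
        return not self.lines

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CanonicalEntry):
            return NotImplemented
        return (
            self.contest_id == other.contest_id
            and self.entry_id == other.entry_id
            and self.author_id == other.author_id
            and self.timestamp == other.timestamp
            and self.score == other.score
            and self.phase == other.phase
            and self.lines == other.lines
        )


@dataclass
class Contest:
    """A contest: entries in submission order plus phase layout.

    Entries are sorted by timestamp with ties broken by entry id; the
    darkness phase (if any) is a contiguous prefix and daylight a
    contiguous suffix.
    """

    contest_id: str
    entries: list[CanonicalEntry]

    def __post_init__(self) -> None:
        keys = [(e.timestamp, e.entry_id) for e in self.entries]
        if keys != sorted(keys):
            raise ValueError(f"contest {self.contest_id}: entries not sorted by (timestamp, entry_id)")
        ids = [e.entry_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"contest {self.contest_id}: duplicate entry_id {dup!r}")
        phases = [e.phase for e in self.entries]
        first_daylight = next((i for i, p in enumerate(phases) if p == PHASE_DAYLIGHT), len(phases))
        if any(p == PHASE_DARKNESS for p in phases[first_daylight:]):
            logger.warning(
                "contest %s: daylight entries do not form a contiguous suffix", self.contest_id
            )

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def phase_boundaries(self) -> dict[str, range]:
        """Index range of each phase present, in submission order."""
        out: dict[str, range] = {}
        phases = [e.phase for e in self.entries]
        for phase in (PHASE_DARKNESS, PHASE_DAYLIGHT):
            idx = [i for i, p in enumerate(phases) if p == phase]
            if idx:
                out[phase] = range(min(idx), max(idx) + 1)
        return out

    def phase_entries(self, phase: str) -> list[CanonicalEntry]:
        return [e for e in self.entries if e.phase == phase]

    def daylight_view(self) -> "Contest":
        """Sub-contest restricted to daylight entries (cross-contest stats)."""
        return Contest(self.contest_id, self.phase_entries(PHASE_DAYLIGHT))

    def index_of(self, entry_id: str) -> int:
        for i, e in enumerate(self.entries):
            if e.entry_id == entry_id:
                return i
        raise KeyError(entry_id)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Contest):
            return NotImplemented
        return self.contest_id == other.contest_id and self.entries == other.entries


def _entry_from_row(row: Mapping, source_text: str) -> CanonicalEntry:
    phase = str(row["phase"]).strip().lower()
    if phase not in _KNOWN_PHASES:
        raise ValueError(f"entry {row['entry_id']}: unknown phase {phase!r}")
    if phase == "twilight":
        # Rank-only information is not code visibility; treated as darkness.
        phase = PHASE_DARKNESS
    try:
        score = float(row["score"])
    except (TypeError, ValueError) as exc:
        raise ValueError(f"entry {row['entry_id']}: non-numeric score {row['score']!r}") from exc
    return CanonicalEntry(
        contest_id=str(row["contest_id"]),
        entry_id=str(row["entry_id"]),
        author_id=str(row["author_id"]),
        timestamp=float(row["timestamp"]),
        score=score,
        phase=phase,
        lines=build_line_multiset(source_text),
    )


def _read_manifest(manifest_path: str | Path) -> pd.DataFrame:
    path = Path(manifest_path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path}: missing required column(s) {missing}")
    if "source_text" not in df.columns and "source_path" not in df.columns:
        raise ValueError(f"manifest {path}: need a source_text or source_path column")
    return df


def _row_source(row: Mapping, base_dir: Path) -> str:
    text = row.get("source_text", "")
    if text:
        return text
    rel = row.get("source_path", "")
    if rel:
        return (base_dir / rel).read_text(encoding="utf-8")
    return ""


def load_contests(manifest_path: str | Path) -> dict[str, Contest]:
    """Load every contest found in a manifest, keyed by contest id."""
    path = Path(manifest_path)
    df = _read_manifest(path)
    base = path.parent
    contests: dict[str, Contest] = {}
    for contest_id, group in df.groupby("contest_id", sort=False):
        dupes = group["entry_id"][group["entry_id"].duplicated()]
        if len(dupes):
            raise ValueError(
                f"contest {contest_id}: duplicate entry_id {dupes.iloc[0]!r} in manifest"
            )
        entries = [
            _entry_from_row(row, _row_source(row, base)) for row in group.to_dict("records")
        ]
        entries.sort(key=lambda e: (e.timestamp, e.entry_id))
        contests[str(contest_id)] = Contest(str(contest_id), entries)
        logger.info("contest %s: loaded %d entries", contest_id, len(entries))
    if not contests:
        raise ValueError(f"manifest {path}: no entries")
    return contests


def load_contest(manifest_path: str | Path, contest_id: str | None = None) -> Contest:
    """Load a single contest from a manifest.

    If the manifest holds several contests, ``contest_id`` selects one.
    """
    contests = load_contests(manifest_path)
    if contest_id is not None:
        try:
            return contests[str(contest_id)]
        except KeyError:
            raise KeyError(f"contest {contest_id!r} not in manifest ({sorted(contests)})")
    if len(contests) > 1:
        raise ValueError(f"manifest holds {len(contests)} contests; pass contest_id")
    return next(iter(contests.values()))


def canonical_source(entry: CanonicalEntry) -> str:
    """Deterministic source text regenerated from the canonical multiset.

    Lines come out sorted; re-canonicalizing reproduces the same
    multiset (the round-trip identity), but the original formatting is
    gone.
    """
    parts: list[str] = []
    for line in sorted(entry.lines):
        parts.extend([line] * entry.lines[line])
    return "\n".join(parts)


def write_manifest(
    contests: Iterable[Contest] | Contest,
    manifest_path: str | Path,
    source_texts: Mapping[str, str] | None = None,
) -> None:
    """Write contests back to a single-file manifest (inline sources).

    ``source_texts`` maps entry id to original source text; entries not
    covered are serialised from their canonical multiset, which reloads
    to an equal `Contest`.
    """
    if isinstance(contests, Contest):
        contests = [contests]
    rows = []
    for contest in contests:
        for e in contest.entries:
            text = (source_texts or {}).get(e.entry_id) or canonical_source(e)
            rows.append(
                {
                    "contest_id": e.contest_id,
                    "entry_id": e.entry_id,
                    "author_id": e.author_id,
                    "timestamp": repr(e.timestamp),
                    "score": repr(e.score),
                    "phase": e.phase,
                    "source_text": text,
                }
            )
    path = Path(manifest_path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def entry_table(contest: Contest) -> pd.DataFrame:
    """Canonical entry table: one row of metadata and line counts per entry."""
    return pd.DataFrame(
        {
            "contest_id": [e.contest_id for e in contest.entries],
            "entry_id": [e.entry_id for e in contest.entries],
            "author_id": [e.author_id for e in contest.entries],
            "timestamp": [e.timestamp for e in contest.entries],
            "score": [e.score for e in contest.entries],
            "phase": [e.phase for e in contest.entries],
            "total_lines": [e.total_lines for e in contest.entries],
            "n_unique_lines": [e.n_unique_lines for e in contest.entries],
        }
    )
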