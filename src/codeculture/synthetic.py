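"""Synthetic contest generator with planted ground truth.

The generator emulates the statistical structure of an online
programming contest as a cultural-evolutionary system, without
simulating code semantics.  Lines are opaque tokens; every downstream
statistic operates on line multisets only, so nothing is lost by the
abstraction.

Dynamics
--------
* **Darkness phase** (first ``darkness_fraction`` of entries): agents
  submit independent inventions — lines sampled from a shared base
  vocabulary — with no copying, giving the no-social-information
  similarity baseline.
* **Daylight phase**: with probability ``1 - p_leap`` an entry is a
  *tweak*: it copies the current leader's lines and applies a few
  line-level edits (replace / insert / delete).  With probability
  ``p_leap`` it is a *leap*: a solution off the current consensus,
  mixing freshly invented lines with lines *repurposed* from old
  themes — lines introduced by darkness or earlier leap entries and
  absent from the current leader, so a leap's similarity to the leader
  stays low.  The novel share of a leap declines linearly over the
  contest (from ``leap_novel_fraction`` to ``leap_novel_final``): as
  the pool of existing ideas grows, innovators increasingly recombine
  rather than invent, which is what drives cultural diversity down
  and the count of original sources up over time.

Scores (lower is better) follow a local-search quality model.  Every
line carries a latent quality drawn once when the line is invented; an
entry's score is ``score_scale`` times the mean quality of its lines,
times a small multiplicative observation noise.  Innovation quality is
relative to the solution being modified: a tweak's new lines scatter
around the parent entry's mean quality, so tweaks move the score by a
fraction of a line's worth — small variance either way.  A leap draws
a fresh solution "concept" spread widely (log-normally) around the
current leader's mean with a penalty drift, so most leaps score worse
than the leader but a few are dramatically better — the high-variance,
usually-failing innovation profile the analysis is designed to detect.
The leader score, a running minimum, improves multiplicatively over
the contest.

Every entry records its generating process, the entries it copied
from, and its novel lines (`PlantedTruth`), so classifiers and
provenance statistics can be validated against a known answer.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from codeculture.corpus import (
    CanonicalEntry,
    Contest,
    PHASE_DARKNESS,
    PHASE_DAYLIGHT,
    build_line_multiset,
)
from codeculture.diversity import bin_entries
from codeculture.dynamics import ClassificationConfig, classify_contest, compute_leader_timeline
from codeculture.provenance import source_profiles
from codeculture.similarity import baseline_similarity_distribution


@dataclass
class SimulationConfig:
    """Generator parameters; defaults emulate a mid-sized contest.

    ``n_agents`` and ``n_entries`` follow the scale of one real
    contest population (on the order of a hundred participants and a
    few thousand entries); tests and quick runs pass smaller values.
    """

    seed: int = 0
    n_agents: int = 120
    n_entries: int = 2000
    darkness_fraction: float = 0.1
    vocabulary_size: int = 5000
    entry_length: int = 50
    p_leap: float = 0.25
    tweak_edit_rate: float = 1.0  # mean extra edits beyond the mandatory one
    leap_novel_fraction: float = 0.9  # novel share of a leap at daylight start
    leap_novel_final: float = 0.2  # novel share of a leap at contest end
    base_quality_sd: float = 0.3  # log-sd of base-vocabulary line quality
    tweak_quality_sd: float = 0.5  # log-sd of a tweak's new lines around the parent mean
    leap_spread: float = 0.8  # log-sd of a leap concept around the leader mean
    leap_penalty: float = 0.8  # log-drift making most leaps worse than the leader
    score_noise_sd: float = 0.05  # multiplicative observation noise (log scale)
    score_scale: float = 100.0
    contest_days: float = 7.0
    contest_id: str = "synthetic"
    success_bias: bool = True  # False: tweaks copy a uniform random prior entry

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_leap <= 1.0):
            raise ValueError("p_leap must be in [0, 1]")
        if not (0.0 <= self.darkness_fraction < 1.0):
            raise ValueError("darkness_fraction must be in [0, 1)")
        if not (0.0 <= self.leap_novel_final <= self.leap_novel_fraction <= 1.0):
            raise ValueError("need 0 <= leap_novel_final <= leap_novel_fraction <= 1")
        if self.n_agents < 1 or self.n_entries < self.n_agents:
            raise ValueError("need n_entries >= n_agents >= 1")
        if self.entry_length < 2:
            raise ValueError("entry_length must be >= 2")
        if self.vocabulary_size < self.entry_length:
            raise ValueError("vocabulary_size must be >= entry_length")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        return cls(**yaml.safe_load(Path(path).read_text(encoding="utf-8")))


@dataclass
class PlantedTruth:
    """Ground-truth generating process of every synthetic entry."""

    process: dict[str, str]  # entry_id -> darkness | tweak | leap
    copied_from: dict[str, list[str]]  # entry_id -> source entry ids
    novel_lines: dict[str, set[str]]  # entry_id -> lines drawn fresh


class _LineFactory:
    """Deterministic opaque line tokens with latent qualities."""

    def __init__(self, config: SimulationConfig, rng: np.random.Generator):
        self.rng = rng
        self.quality: dict[str, float] = {}
        sd = config.base_quality_sd
        self.base = [
            self._new(f"v{i:06d}", float(np.exp(sd * rng.standard_normal())))
            for i in range(config.vocabulary_size)
        ]
        self._novel_counter = 0

    def _new(self, token: str, quality: float) -> str:
        self.quality[token] = quality
        return token

    def novel(self, quality: float) -> str:
        self._novel_counter += 1
        return self._new(f"n{self._novel_counter:07d}", quality)

    def mean_quality(self, lines: list[str]) -> float:
        return float(np.mean([self.quality[l] for l in lines]))


def simulate_contest(config: SimulationConfig) -> tuple[Contest, PlantedTruth]:
    """Generate one contest and its planted truth, reproducibly from the seed."""
    rng = np.random.default_rng(config.seed)
    factory = _LineFactory(config, rng)
    L = config.entry_length

    n_dark = int(round(config.darkness_fraction * config.n_entries))
    entries: list[CanonicalEntry] = []
    line_lists: list[list[str]] = []  # parallel to entries
    process: dict[str, str] = {}
    copied_from: dict[str, list[str]] = {}
    novel_lines: dict[str, set[str]] = {}
    # lines available for repurposing by leaps: introduced by darkness or
    # leap entries, mapped to the entry that first carried them
    theme_pool: dict[str, str] = {}

    best_idx, best_score = -1, np.inf

    for i in range(config.n_entries):
        entry_id = f"e{i:05d}"
        author = f"a{int(rng.integers(config.n_agents)):04d}"
        timestamp = config.contest_days * i / max(config.n_entries - 1, 1)
        progress = i / max(config.n_entries - 1, 1)
        if i < n_dark or best_idx < 0:
            # independent invention from the base vocabulary
            lines = [str(t) for t in rng.choice(factory.base, size=L, replace=False)]
            proc, sources, novel = "darkness", [], set()
            for l in lines:
                theme_pool.setdefault(l, entry_id)
        elif rng.random() < config.p_leap:
            lines, sources, novel = _make_leap(
                config, rng, factory, theme_pool, line_lists[best_idx], progress
            )
            for l in novel:
                theme_pool.setdefault(l, entry_id)
            proc = "leap"
        else:
            src_idx = best_idx if config.success_bias else int(rng.integers(i))
            lines, novel = _make_tweak(config, rng, factory, line_lists[src_idx])
            proc, sources = "tweak", [entries[src_idx].entry_id]
        score = float(
            config.score_scale
            * factory.mean_quality(lines)
            * np.exp(config.score_noise_sd * rng.standard_normal())
        )
        phase = PHASE_DARKNESS if i < n_dark else PHASE_DAYLIGHT
        entries.append(
            CanonicalEntry(
                contest_id=config.contest_id,
                entry_id=entry_id,
                author_id=author,
                timestamp=timestamp,
                score=score,
                phase=phase,
                lines=build_line_multiset("\n".join(lines)),
            )
        )
        line_lists.append(lines)
        process[entry_id] = proc
        copied_from[entry_id] = sources
        novel_lines[entry_id] = novel
        # darkness scores are hidden from agents, but the analysis leader
        # timeline sees them, so the generator tracks the true running best
        if score < best_score:
            best_idx, best_score = i, score

    contest = Contest(config.contest_id, entries)
    return contest, PlantedTruth(process, copied_from, novel_lines)


def _make_tweak(
    config: SimulationConfig,
    rng: np.random.Generator,
    factory: _LineFactory,
    parent_lines: list[str],
) -> tuple[list[str], set[str]]:
    """Copy a parent entry and apply a small number of line edits.

    New lines scatter log-normally around the parent's mean quality
    (local search); deletions stop at half the nominal entry length so
    entries cannot erode away over a long lineage.
    """
    lines = list(parent_lines)
    parent_mean = factory.mean_quality(parent_lines)
    n_edits = 1 + int(rng.poisson(config.tweak_edit_rate))
    novel: set[str] = set()

    def fresh() -> str:
        q = parent_mean * float(np.exp(config.tweak_quality_sd * rng.standard_normal()))
        tok = factory.novel(q)
        novel.add(tok)
        return tok

    for _ in range(n_edits):
        op = rng.choice(("replace", "insert", "delete"))
        if op == "delete" and len(lines) > config.entry_length // 2:
            lines.pop(int(rng.integers(len(lines))))
        elif op == "insert":
            lines.insert(int(rng.integers(len(lines) + 1)), fresh())
        else:
            lines[int(rng.integers(len(lines)))] = fresh()
    return lines, novel


def _make_leap(
    config: SimulationConfig,
    rng: np.random.Generator,
    factory: _LineFactory,
    theme_pool: dict[str, str],
    leader_lines: list[str],
    progress: float,
) -> tuple[list[str], list[str], set[str]]:
    """A low-leader-similarity entry mixing invention and repurposed old code.

    The leap's solution concept has quality spread log-normally around
    the current leader's mean with a penalty drift: usually worse,
    occasionally far better.  Its novel share interpolates from
    ``leap_novel_fraction`` down to ``leap_novel_final`` over the
    contest; the remainder is drawn from old themes (lines introduced
    by darkness or leap entries) that the current leader does not
    carry, so the entry stays dissimilar to the consensus solution.
    """
    L = config.entry_length
    leader_mean = factory.mean_quality(leader_lines)
    concept = leader_mean * float(
        np.exp(config.leap_penalty + config.leap_spread * rng.standard_normal())
    )
    novel_frac = (
        config.leap_novel_fraction
        + (config.leap_novel_final - config.leap_novel_fraction) * progress
    )
    leader_set = set(leader_lines)
    candidates = [l for l in theme_pool if l not in leader_set]
    n_reuse = min(L - int(round(novel_frac * L)), len(candidates))
    lines: list[str] = []
    sources: set[str] = set()
    if n_reuse > 0:
        take = rng.choice(len(candidates), size=n_reuse, replace=False)
        for t in take:
            line = candidates[t]
            lines.append(line)
            sources.add(theme_pool[line])
    novel = {
        factory.novel(concept * float(np.exp(0.2 * rng.standard_normal())))
        for _ in range(L - n_reuse)
    }
    lines.extend(sorted(novel))
    return lines, sorted(sources), novel


def emergent_property_report(
    contest: Contest, truth: PlantedTruth, classification: ClassificationConfig | None = None
) -> dict:
    """Check the qualitative signatures the analysis expects of a contest.

    Reports, for the given simulated contest: the darkness similarity
    baseline (median of pairwise values — low when invention is
    independent), bimodality of similarity to the current leader (mass
    below the leap threshold plus mass above the tweak threshold),
    leader score improvement (first over final leader score), the sign
    of a quick least-squares trend of logit diversity over bins, the
    original/recent source-count trends over submission order
    (Spearman rho), and agreement of the dual-threshold classifier
    with the planted labels.
    """
    from scipy.special import logit as _logit
    from scipy.stats import spearmanr

    cfg = classification or ClassificationConfig()
    timeline = compute_leader_timeline(contest)
    labels = classify_contest(contest, cfg, timeline)
    sims = np.array([l.similarity_to_leader for l in labels])
    sims = sims[~np.isnan(sims)]

    counts, edges = baseline_similarity_distribution(contest, bins=100)
    centers = (edges[:-1] + edges[1:]) / 2
    dark_median = (
        float(centers[np.searchsorted(np.cumsum(counts), counts.sum() / 2)])
        if counts.sum()
        else float("nan")
    )

    bins = bin_entries(contest)
    div = np.clip(np.array([b.diversity for b in bins]), 1e-9, 1 - 1e-9)
    xs = np.arange(len(bins), dtype=float)
    div_slope = float(np.polyfit(xs, _logit(div), 1)[0]) if len(bins) >= 3 else float("nan")

    profiles = source_profiles(contest)
    orig = [p.n_original_sources for p in profiles]
    rec = [p.n_recent_sources for p in profiles]
    idx = np.arange(len(profiles))
    rho_orig = float(spearmanr(idx, orig).statistic)
    rho_rec = float(spearmanr(idx, rec).statistic)

    daylight = [
        (lab.label, truth.process[lab.entry_id])
        for lab in labels
        if truth.process[lab.entry_id] in ("tweak", "leap")
    ]
    agree = sum(1 for got, want in daylight if got == want)

    leader_incs = {
        "tweak": [l.normalised_delta for l in labels if l.took_lead and l.label == "tweak"],
        "leap": [l.normalised_delta for l in labels if l.took_lead and l.label == "leap"],
    }
    inc_var = {
        k: (float(np.var(v, ddof=1)) if len(v) > 1 else float("nan"))
        for k, v in leader_incs.items()
    }

    return {
        "darkness_similarity_median": dark_median,
        "similarity_mass_below_leap": float(np.mean(sims < cfg.leap_below)) if len(sims) else float("nan"),
        "similarity_mass_above_tweak": float(np.mean(sims > cfg.tweak_above)) if len(sims) else float("nan"),
        "leader_score_first": float(timeline.leader_score[0]),
        "leader_score_final": float(timeline.leader_score[-1]),
        "leader_improved": bool(timeline.leader_score[-1] < timeline.leader_score[0]),
        "diversity_logit_slope": div_slope,
        "original_sources_trend_rho": rho_orig,
        "recent_sources_trend_rho": rho_rec,
        "leading_increment_variance": inc_var,
        "planted_label_agreement": agree / len(daylight) if daylight else float("nan"),
        "n_daylight_classifiable": len(daylight),
    }
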