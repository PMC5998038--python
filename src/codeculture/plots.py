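"""Figure export for analysis runs (static matplotlib, Agg backend)."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from codeculture.corpus import Contest
from codeculture.diversity import PosteriorSummary
from codeculture.dynamics import TweakLeapLabel, compute_leader_timeline, log_transform_scores


def scores_over_time(contests: Sequence[Contest], path: str | Path) -> None:
    """Log-transformed scores per entry with the leading-entry trajectory."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for contest in contests:
        t = np.array([e.timestamp for e in contest.entries])
        s = log_transform_scores([e.score for e in contest.entries])
        ax.plot(t, s, ".", ms=2, alpha=0.3)
        timeline = compute_leader_timeline(contest)
        ax.plot(t, log_transform_scores(timeline.leader_score), "r-", lw=1)
    ax.set_xlabel("time (days from contest start)")
    ax.set_ylabel("log(score + 10)")
    ax.set_title("scores over time (red: leading entries)")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def similarity_to_leader_hist(labels: Sequence[TweakLeapLabel], path: str | Path) -> None:
    """Distribution of entry similarity to the current leader."""
    sims = np.array([l.similarity_to_leader for l in labels])
    sims = sims[~np.isnan(sims)]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(sims, bins=np.linspace(0, 1, 101), color="tab:red")
    ax.set_xlabel("similarity to current leader")
    ax.set_ylabel("entries")
    ax.set_title("similarity to the current leader at submission")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def baseline_similarity(
    hists: dict[str, tuple[np.ndarray, np.ndarray]], path: str | Path
) -> None:
    """Pooled darkness-phase (no social information) similarity baseline."""
    fig, ax = plt.subplots(figsize=(6, 4))
    total = None
    edges = None
    for counts, e in hists.values():
        total = counts if total is None else total + counts
        edges = e
    centers = (edges[:-1] + edges[1:]) / 2
    ax.bar(centers, total, width=edges[1] - edges[0], color="tab:blue")
    ax.set_xlabel("pairwise similarity (darkness phase)")
    ax.set_ylabel("entry pairs")
    ax.set_title("baseline similarity without social information")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def diversity_predictions(
    bin_df: pd.DataFrame, posterior: PosteriorSummary, path: str | Path
) -> None:
    """Observed binned diversity with per-contest and overall model curves."""
    from scipy.special import expit

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for cid, grp in bin_df.groupby("contest_id"):
        ax.plot(grp["bin_index"], grp["diversity"], ".", ms=3, alpha=0.3)
        a = posterior.param_mean(f"alpha[{cid}]")
        b = posterior.param_mean(f"beta[{cid}]")
        ax.plot(grp["bin_index"], expit(a + b * grp["x"]), "k-", lw=0.8)
    xs = bin_df.sort_values("bin_index")
    ax.plot(
        xs["bin_index"],
        expit(posterior.param_mean("mu_int") + posterior.param_mean("mu_slope") * xs["x"]),
        "r-",
        lw=2,
        label="overall estimate",
    )
    ax.set_xlabel("chronological bin")
    ax.set_ylabel("diversity")
    ax.set_title("cultural diversity over contest progress")
    ax.legend()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def sources_over_time(profiles_df: pd.DataFrame, path: str | Path) -> None:
    """Mean original and recent source counts over submission deciles."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    df = profiles_df.copy()
    df["decile"] = df.groupby("contest_id").cumcount()
    df["decile"] = df.groupby("contest_id")["decile"].transform(
        lambda s: np.minimum((10 * s / max(len(s), 1)).astype(int), 9)
    )
    agg = df.groupby("decile")[["n_original_sources", "n_recent_sources"]].mean()
    ax.plot(agg.index + 1, agg["n_original_sources"], "o-", label="original sources")
    ax.plot(agg.index + 1, agg["n_recent_sources"], "s-", label="recent sources")
    ax.set_xlabel("contest decile (submission order)")
    ax.set_ylabel("mean sources per entry")
    ax.set_title("recombination over time")
    ax.legend()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
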