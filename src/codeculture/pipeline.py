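"""End-to-end analysis runs: ingest → similarity → dynamics → provenance
→ diversity → model → report.

A run consumes one or more contests (loaded from manifests or freshly
simulated), applies the per-contest analyses, pools the cross-contest
statistics, fits the diversity model when at least one contest has
enough bins, and writes every table, plot and a machine-readable
summary into an output directory.  Cross-contest statistics use only
daylight entries by default — the condition in which participants can
see (and copy) each other's code — while darkness entries feed the
baseline similarity distribution.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from codeculture import plots
from codeculture.corpus import Contest, entry_table, load_contests
from codeculture.diversity import (
    BetaGLMMConfig,
    bin_entries,
    bins_frame,
    fit_beta_glmm,
    prediction_curves,
)
from codeculture.dynamics import (
    ClassificationConfig,
    classify_contest,
    compute_leader_timeline,
    dynamics_summary,
    labels_frame,
)
from codeculture.provenance import profiles_frame, recombination_trend, source_profiles
from codeculture.similarity import baseline_similarity_distribution, pairwise_matrix
from codeculture.synthetic import SimulationConfig, simulate_contest

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full analysis run."""

    output_dir: str | Path = "codeculture_run"
    manifest: str | Path | None = None
    simulations: list[SimulationConfig] = field(default_factory=list)
    classification: ClassificationConfig = field(default_factory=ClassificationConfig)
    bin_fraction: float = 0.01
    mcmc: BetaGLMMConfig = field(default_factory=BetaGLMMConfig)
    seed: int = 0
    daylight_only: bool = True
    # diversity is a population snapshot: by default bins cover every
    # phase, so the diverse no-visibility period anchors the trend the
    # way early full-visibility entries do in corpora without phases
    diversity_all_phases: bool = True
    fit_model: bool = True
    make_plots: bool = True
    max_matrix_entries: int = 3000  # pairwise-matrix plots skipped above this

    def validate(self) -> None:
        if self.manifest is None and not self.simulations:
            raise ValueError("RunConfig needs a manifest or at least one simulation")
        if self.manifest is not None and not Path(self.manifest).exists():
            raise FileNotFoundError(f"manifest not found: {self.manifest}")


def _gather_contests(config: RunConfig) -> dict[str, Contest]:
    contests: dict[str, Contest] = {}
    if config.manifest is not None:
        contests.update(load_contests(config.manifest))
    for k, sim in enumerate(config.simulations):
        sim = dataclasses.replace(
            sim,
            seed=sim.seed + config.seed,
            contest_id=sim.contest_id if sim.contest_id not in contests else f"{sim.contest_id}_{k}",
        )
        contest, _ = simulate_contest(sim)
        contests[contest.contest_id] = contest
    return contests


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if math.isfinite(v) else repr(v)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def run_full_analysis(config: RunConfig) -> dict:
    """Execute every stage of the analysis and write the report bundle.

    Returns the top-level summary (also written to ``summary.json``).
    Raises on stage failure; partial outputs written so far remain in
    the output directory.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    contests = _gather_contests(config)
    logger.info("stage ingest: %d contests, %d entries", len(contests), sum(len(c) for c in contests.values()))

    analysis_views: dict[str, Contest] = {}
    for cid, contest in contests.items():
        view = contest.daylight_view() if config.daylight_only else contest
        if not view.entries:
            logger.warning("contest %s: no daylight entries; using all phases", cid)
            view = contest
        logger.info(
            "contest %s: %d entries, %d in analysis view", cid, len(contest), len(view)
        )
        analysis_views[cid] = view

    pd.concat([entry_table(c) for c in contests.values()]).to_csv(
        out / "entries.csv", index=False
    )

    # --- per-contest dynamics and provenance, pooled ----------------------
    all_labels = []
    label_frames = []
    profile_frames = []
    recomb: dict[str, dict] = {}
    baseline_hists: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for cid, view in analysis_views.items():
        timeline = compute_leader_timeline(view)
        labels = classify_contest(view, config.classification, timeline)
        all_labels.extend(labels)
        lf = labels_frame(labels)
        lf.insert(0, "contest_id", cid)
        label_frames.append(lf)
        profiles = source_profiles(view)
        pf = profiles_frame(profiles)
        pf.insert(0, "contest_id", cid)
        profile_frames.append(pf)
        recomb[cid] = recombination_trend(view, profiles, labels)
        full = contests[cid]
        if full.phase_entries("darkness"):
            baseline_hists[cid] = baseline_similarity_distribution(full)
    pd.concat(label_frames).to_csv(out / "labels.csv", index=False)
    pd.concat(profile_frames).to_csv(out / "source_profiles.csv", index=False)
    logger.info("stage dynamics+provenance: %d labelled entries", len(all_labels))

    dyn = dynamics_summary(all_labels)

    # --- diversity bins and the beta mixed model --------------------------
    diversity_sources = contests if config.diversity_all_phases else analysis_views
    bins_by_contest = {
        cid: bin_entries(c, config.bin_fraction) for cid, c in diversity_sources.items()
    }
    bin_df = bins_frame(bins_by_contest)
    bin_df.to_csv(out / "diversity_bins.csv", index=False)

    posterior = None
    if config.fit_model:
        logger.info("stage model: fitting beta GLMM on %d bins", len(bin_df))
        posterior = fit_beta_glmm(bin_df, config.mcmc)
        posterior.summary.to_csv(out / "posterior_summary.csv")
        prediction_curves(posterior, n_bins=max(len(b) for b in bins_by_contest.values())).to_csv(
            out / "prediction_curves.csv", index=False
        )

    # --- plots -------------------------------------------------------------
    if config.make_plots:
        plots.scores_over_time(list(analysis_views.values()), out / "scores_over_time.png")
        plots.similarity_to_leader_hist(all_labels, out / "similarity_to_leader.png")
        if baseline_hists:
            plots.baseline_similarity(baseline_hists, out / "baseline_similarity.png")
        for cid, view in analysis_views.items():
            if 2 <= len(view) <= config.max_matrix_entries:
                pairwise_matrix(view).plot_heatmap(out / f"similarity_matrix_{cid}.png")
        if posterior is not None:
            plots.diversity_predictions(bin_df, posterior, out / "diversity_predictions.png")
        plots.sources_over_time(pd.concat(profile_frames), out / "sources_over_time.png")

    # --- summary ------------------------------------------------------------
    summary: dict = {
        "seed": config.seed,
        "n_contests": len(contests),
        "n_entries": int(sum(len(c) for c in contests.values())),
        "n_entries_analysed": int(sum(len(v) for v in analysis_views.values())),
        "classification": dataclasses.asdict(config.classification),
        "dynamics": dyn,
        "recombination": recomb,
    }
    if posterior is not None:
        summary["diversity_model"] = {
            "mu_slope_mean": posterior.param_mean("mu_slope"),
            "mu_slope_ci95": posterior.param_ci("mu_slope"),
            "mu_int_mean": posterior.param_mean("mu_int"),
            "phi_mean": posterior.param_mean("phi"),
            "converged": posterior.converged,
            "max_rhat": posterior.max_rhat,
        }
    (out / "summary.json").write_text(
        json.dumps(_jsonable(summary), indent=2), encoding="utf-8"
    )
    if posterior is not None and not posterior.converged:
        logger.warning("diversity model flagged non-converged (max R-hat %.4f)", posterior.max_rhat)
    return summary
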