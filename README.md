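# codeculture

Cumulative cultural evolution in programming-contest corpora.

Online programming contests are a natural laboratory for cumulative
culture: a population of participants repeatedly submits scored
solutions, everyone can see (and copy) everyone else's code, and the
population's best solution improves far beyond what any individual
produces alone.  `codeculture` is a tested, reusable pipeline for
analysing such corpora — and, because the original contest datasets
are not always at hand, it ships a synthetic contest generator with
planted ground truth for every statistic it computes.

The package is aimed at researchers in cultural evolution and social
learning who want line-level, population-scale measurements of
copying, innovation, diversity and recombination from any corpus of
timestamped, scored text entries.

## What it measures

**Lines as cultural traits.**  Each entry's source text is reduced to
a multiset of canonical lines (whitespace removed, case folded).  Two
entries are compared with the Czekanowski index, the multiset
generalisation of the Sørensen–Dice coefficient:

```
CZ(a, b) = 2 · Σ_j min(x_aj, x_bj) / Σ_j (x_aj + x_bj)
```

where `x_aj` is the number of occurrences of line `j` in entry `a`.

**Tweaks and leaps.**  Every entry is compared with the best-scoring
entry at the moment of its submission (lower score = better).
Similarity above 0.9 marks a *tweak* — an incremental refinement of
the consensus solution; below 0.1 a *leap* — a substantially novel
solution.  The pipeline reports tweak:leap ratios (all entries and
lead-taking entries), and Spearman correlations between
leader-similarity and score change.

**Cultural diversity.**  Entries are binned chronologically (1% of
the contest per bin); a bin's diversity is its count of distinct
lines divided by the contest's total line count.  The trend over bins
is fit with a Bayesian beta mixed-effects regression,

```
Y_ij ~ Beta(mu_ij, phi),   var(Y_ij) = mu_ij (1 - mu_ij) / (phi + 1)
logit(mu_ij) = alpha_j + beta_j · Bin_ij
alpha_j ~ N(mu_int, sigma_int²),   beta_j ~ N(mu_slope, sigma_slope²)
```

with contest-level random intercepts and slopes, sampled by ensemble
MCMC with convergence diagnostics (R-hat, effective sample size).
The bin covariate is scaled so `mu_slope` is the change in the logit
of diversity per additional 10% of a contest.

**Recombination.**  Every line of every entry is traced to the
earliest entry that introduced it (its *original source*) and to the
most recent prior entry carrying it (its *recent source*), giving
per-entry counts of sources drawn on, distinct source authors, and
novel lines.

## Worked example

```python
from codeculture import (SimulationConfig, simulate_contest, classify_contest,
                         tweak_leap_ratio, rank_correlation, recombination_trend)

config = SimulationConfig(seed=7, n_entries=800, n_agents=80)
contest, truth = simulate_contest(config)
daylight = contest.daylight_view()          # entries with social information

labels = classify_contest(daylight)
r_all = tweak_leap_ratio(labels)
r_lead = tweak_leap_ratio(labels, leading_only=True)
print(f"tweak:leap ratio (all entries):     {r_all.ratio:.2f}  ({r_all.n_tweaks}:{r_all.n_leaps})")
print(f"tweak:leap ratio (leading entries): {r_lead.ratio:.2f}  ({r_lead.n_tweaks}:{r_lead.n_leaps})")

leaders = [l for l in labels if l.took_lead]
corr = rank_correlation([l.similarity_to_leader for l in leaders],
                        [l.normalised_delta for l in leaders])
print(f"leading entries, similarity vs improvement: rho = {corr.rho:.2f} (n={corr.n})")

trend = recombination_trend(daylight, labels=labels)
print(f"original sources: mean {trend['original_sources_mean']:.1f} "
      f"(trend rho = {trend['trend_original_vs_time'].rho:.2f})")
```

prints

```
tweak:leap ratio (all entries):     3.14  (543:173)
tweak:leap ratio (leading entries): 12.33  (37:3)
leading entries, similarity vs improvement: rho = -0.34 (n=40)
original sources: mean 11.6 (trend rho = 0.92)
```

Read: most entries are small refinements of the current leader
(ratio ≈ the generator's 3:1 tweak:leap odds), but among entries that
actually *took the lead* tweaks dominate far more strongly — leaps
usually fail.  When a leap does take the lead, it tends to bring a
bigger improvement (negative rho between similarity and improvement).
Entries draw on more and more original sources as the contest
progresses (trend rho 0.92): the population recombines an increasing
share of previously introduced ideas.

A command-line interface wraps the same pipeline:

```
codeculture simulate --seed 4 --n-entries 800 --out contest.csv
codeculture analyze contest.csv --out run/
codeculture report --simulate 3 --out run/       # full pipeline incl. MCMC
```

`analyze` ingests any corpus in manifest form: a CSV/TSV with columns
`contest_id, entry_id, author_id, timestamp, score, phase` and either
inline `source_text` or a `source_path` per entry.

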