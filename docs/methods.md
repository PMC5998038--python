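# Methods

This note documents the measurement conventions, the statistical
model, the synthetic contest generator, and the numerical choices made
where the design was genuinely open.

## Canonical lines

The unit of cultural transmission is the canonical source line: all
whitespace removed (any Unicode whitespace), all characters
lowercased, order preserved.  Two lines are the same trait exactly
when their canonical forms are equal.  Only `\n`, `\r\n` and `\r`
delimit lines; other vertical whitespace (form feed, NEL) is treated
as whitespace within a line.  Lines that canonicalize to the empty
string are dropped from entry multisets — they carry no content and
would otherwise make every entry resemble every other.  Comments and
code are treated identically: the rule operates on raw character
content, with no parsing of the underlying language, and no stripping
of trailing semicolons or comment markers.  Canonicalization is
idempotent, which makes the manifest round-trip (write a contest,
reload it) an exact identity on the canonical representation.

Entries within a contest are totally ordered by `(timestamp,
entry_id)`.  Every "who came first" statistic — leader timelines,
original and recent sources — inherits this order, so results are
deterministic even with tied timestamps.

## Similarity

The Czekanowski index (multiset Sørensen–Dice) between entries `a`
and `b` is `2 Σ min(x_aj, x_bj) / Σ (x_aj + x_bj)`, with sums over the
union of their distinct lines.  It is 1 iff the multisets are equal
and 0 iff they share no line.  The similarity of two empty entries is
a 0/0 form and is raised (or stored as NaN in matrices), never
reported as 0: a genuine 0 means "fully novel", which is a different
statement.  An empty entry against a non-empty one is a well-defined 0.

Full pairwise matrices use an inverted line index (line → carrying
entries); the cost is the sum of squared carrier-set sizes, far below
the dense product for the long-tailed line distributions contests
produce.  The dense symmetric matrix, ordered chronologically, is the
exported artifact.

## Leader-relative dynamics

Lower scores are better throughout; corpora scored in the opposite
direction should be sign-flipped at ingest.  The leader timeline is
the prefix argmin of score with strictly-better comparison, so ties
keep the incumbent.  Every entry after the first is compared with the
leader in place immediately before its submission — for a non-leading
entry this is the current leader it failed to beat; for a leading
entry, the previous leader it displaced.  Both cases reduce to the
same reference (the leader at index i−1), which is also why the first
entry of a contest is excluded: it has no reference.

Classification is dual-threshold by default: similarity < 0.1 → leap,
> 0.9 → tweak, otherwise unclassified.  A single-cut mode (default
0.5, ≥ cut → tweak) is provided because the middle band is genuinely
ambiguous and ratio statistics are sensitive to how it is resolved;
ratios should be reported under both when the band is heavily
populated.  Classification is monotone in similarity by construction.

Score increments are `|score − leader score at submission|`, min-max
normalised within each contest (degenerate zero-range contests yield
zeros with a warning).  Spearman correlations use average ranks; for
n ≤ 50 the two-sided p-value comes from a seeded Monte Carlo
permutation test of the pairing (10,000 resamples; exhaustive
enumeration is used automatically when the sample is small enough
that 10,000 exceeds n!), otherwise from the large-sample
approximation.  Exact permutation for every n ≤ 50 is impossible
(50! pairings), so small-sample p-values carry Monte Carlo error of
order 0.005.

## Provenance

A line's *original source* is the earliest entry in the contest
containing it, gaps notwithstanding (a line that vanishes and
reappears keeps its original introducer).  A line's *recent source*
for entry i is the latest carrier strictly before i; under the total
submission order this is unique.  Source counts aggregate to distinct
entries: an earlier entry contributing fifty lines is still one
source.  Lines an entry is itself first to carry are novel; an
entry's `n_novel_lines` counts their occurrences (so a first entry
has novel fraction 1 even with repeated lines) and `n_novel_distinct`
counts them once each (these sum to the contest's distinct-line count
across entries).  An author's own earlier entries count as sources by
default; `exclude_same_author` removes self-refinement from the
original-source count for corpora where one prolific participant
would otherwise dominate.

## Cultural diversity and the beta mixed model

Entries are partitioned chronologically into bins of 1% of the
contest (sizes differ by at most one; the first `n mod 100` bins take
the extra entry).  Bin diversity = distinct canonical lines appearing
in the bin ÷ total lines submitted in the whole contest (with
multiplicity).  Bin number, not wall-clock time, is the progress
covariate, making contests with different submission rates
comparable.

Diversity is a proportion, so the trend is modelled with a beta
likelihood in mean–precision form (`var = μ(1−μ)/(φ+1)`), logit link,
and contest-level Gaussian random intercepts and slopes.  The bin
covariate is centred and scaled so one unit is 10% of a contest;
`mu_slope` then reads directly as "change in the logit of diversity
per additional 10% of contest entries".  Responses are squeezed onto
the open interval with the standard `(y(n−1) + 0.5)/n` compression
(n = number of observations) since exact-zero bins can occur.

Priors: N(0, 10²) on `mu_int` and `mu_slope`; uniform(0, 10) on each
sigma; uniform(0, 2000) on phi.  The scale parameters are sampled on
the log scale (with the corresponding Jacobian) for better geometry.

Sampling uses an affine-invariant ensemble (emcee) with an 80/20
mixture of differential-evolution and snooker moves, which mixes far
better than the stretch move at this dimensionality (5
hyperparameters + 2 random effects per contest; 43 dimensions at 19
contests).  Three independent ensembles of 96 walkers are run from
jittered per-contest least-squares starts (1,000 burn-in + 500
retained steps each by default, ≈ 144,000 retained draws); each
ensemble's pooled draws form one chain for split-R-hat and ESS.  The
convergence gate is R-hat < 1.01 on the five hyperparameters; a fit
failing the gate is returned flagged, never silently.  With a single
contest the random-effect scales are unidentified; the model is still
sampled but flagged, and the hyper-means then track that contest's
own intercept and slope.

Validation: on data simulated from the model at 19 contests × 100
bins (slope −0.15 per 10%, precision 50), the posterior mean of the
slope is recovered within ±0.05 with 95% CI coverage across seeded
replicates (see the test suite); the reduced sampler settings used
there (2 ensembles, 500 + 250 steps) are already sufficient for the
hyperparameters, and heavier runs only sharpen the per-contest
effects.

## The synthetic contest generator

The generator emulates the statistical structure the analysis
assumes, with planted ground truth (per-entry process label, copied
sources, novel lines).  Lines are opaque tokens — every downstream
statistic operates on line multisets, so nothing is lost.

Defaults follow the scale of a mid-sized real contest population: 120
agents, 2,000 entries (tests and quick runs use fewer), entries of 50
lines, a 7-day clock, and a no-social-information ("darkness") phase
covering the first 10% of entries in which agents submit independent
draws from a shared 5,000-line base vocabulary.  In the daylight
phase an entry is, with probability 0.75, a *tweak* — a copy of the
current leader with 1 + Poisson(1) line edits (replace/insert/delete;
deletions stop at half the nominal length so lineages cannot erode
away) — and with probability 0.25 a *leap*.

A leap mixes freshly invented lines with lines repurposed from old
themes: the reuse pool is every line introduced by darkness or leap
entries, minus the current leader's lines, so leaps stay dissimilar
to the consensus.  The novel share of a leap declines linearly from
0.9 at the start to 0.2 at the end of the contest — as the pool of
existing ideas grows, innovators increasingly recombine rather than
invent.  This single ramp is what produces, simultaneously, the
declining bin diversity and the rising original-source counts that
copy-heavy populations show, while recent-source counts stay low and
flat (tweaks always draw on the immediate leader lineage).

Scores follow a local-search quality model.  Every line carries a
latent quality drawn once at invention; an entry's score is 100 ×
mean line quality × exp(0.05·ε) observation noise, lower better.
Tweak edits draw new-line quality log-normally (sd 0.5) around the
parent's mean, so a tweak moves the score by a fraction of one line's
worth; a leap draws a solution "concept" log-normally around the
current leader's mean with spread 0.8 and penalty drift +0.8, and its
novel lines scatter (sd 0.2) around that concept.  Most leaps
therefore score worse than the leader, a few dramatically better —
the high-variance innovation profile the classifier is meant to
detect — and the leader score, a running minimum, improves
multiplicatively over the contest.  An earlier additive design
(score = sum of positive line qualities) was abandoned: it makes
deleting lines universally beneficial, so selection collapses entries
to a single line and every emergent signature breaks.

What the generator does *not* emulate: real code structure and
functional coherence between lines; participant-level strategy
heterogeneity and identity (authors are drawn uniformly per entry);
score components such as execution speed or code-complexity
penalties; submission-rate variation over the week; entry
disqualification.  Passing tests on synthetic contests therefore
demonstrate that the pipeline measures what it claims on corpora with
this copying structure — not that any particular real corpus has that
structure.

## Phase handling

Cross-contest, leader-relative statistics (classification, ratios,
correlations, provenance) use daylight entries only: they presuppose
that participants could see the code they are measured against.
Rank-only ("twilight") phases are conservatively treated as darkness
at ingest, since no code is visible.  Darkness entries feed the
baseline similarity distribution — the no-copying null.

Diversity binning, by contrast, defaults to spanning all phases
(`diversity_all_phases`): diversity is a population snapshot, not a
leader-relative measure, and the diverse independent-invention period
anchors the downward trend the way early entries do in corpora where
everyone could always see everything.  In the generator, daylight
begins with the population already converged on the darkness-phase
best, so a daylight-only fit understates the decline; on real corpora
with a long daylight phase either setting is reasonable and the flag
makes the choice explicit.

## Problem sizes

Default analysis runs and the reproduction script use five simulated
contests of 800 entries and MCMC runs of 2–3 ensembles × (1,000
burn-in + 500 retained); these sizes give stable headline statistics
(classification agreement above 99%, slope CIs a few hundredths wide)
while keeping a full run in the minutes range on one CPU.  The
package itself has no scale assumptions beyond memory: pairwise
matrices are quadratic in contest size and are the only stage worth
skipping on very large contests (the pipeline skips matrix *plots*
above 3,000 entries by default).
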