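"""Binned cultural diversity and the Bayesian beta mixed-effects model.

Diversity of a chronological slice of a contest is the number of
distinct canonical lines appearing in that slice divided by the total
number of lines submitted over the whole contest (multiplicities
counted).  Entries are sorted by submission and partitioned into bins
each holding 1% of the contest's entries, so bin number measures
progress through the contest independently of submission rate.

The trend of diversity over bins is fit with a beta mixed-effects
regression: with ``Y_ij`` the diversity of bin ``i`` in contest ``j``,

    Y_ij ~ Beta(mu_ij, phi)        (mean-precision parameterisation,
                                    var = mu (1 - mu) / (phi + 1))
    logit(mu_ij) = alpha_j + beta_j * Bin_ij
    alpha_j ~ N(mu_int, sigma_int^2),  beta_j ~ N(mu_slope, sigma_slope^2)

Contests differ in task and population, so both intercept and slope
are contest-level random effects.  The bin covariate is centred and
scaled so that one unit equals 10% of a contest, making ``mu_slope``
the average change in the logit of diversity per additional 10% of
contest entries.  Priors are weakly informative: N(0, 10^2) on the two
mu parameters, flat uniforms on phi and each sigma.

Posterior sampling uses an affine-invariant ensemble sampler (emcee)
over the joint parameter vector (5 hyperparameters plus the
per-contest intercepts and slopes), with convergence checked via
split-R-hat and effective sample size computed across walkers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import arviz as az
import emcee
import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, logit

from codeculture.corpus import Contest

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# binning and the diversity measure
# ---------------------------------------------------------------------------


@dataclass
class DiversityBin:
    """One chronological bin of a contest and its diversity value."""

    contest_id: str
    bin_index: int  # 1-based
    n_entries: int
    unique_lines_in_bin: int
    total_lines_in_contest: int

    @property
    def diversity(self) -> float:
        """Raw diversity in [0, 1] (before interval squeezing)."""
        return self.unique_lines_in_bin / self.total_lines_in_contest


def bin_entries(contest: Contest, bin_fraction: float = 0.01) -> list[DiversityBin]:
    """Partition a contest chronologically into bins of ``bin_fraction`` entries.

    Bin sizes differ by at most one entry (the first ``n % n_bins`` bins
    take the extra entry).  Contests with fewer entries than bins get
    one bin per entry, with a warning.
    """
    if not contest.entries:
        raise ValueError(f"contest {contest.contest_id}: cannot bin an empty contest")
    if not (0.0 < bin_fraction <= 1.0):
        raise ValueError("bin_fraction must be in (0, 1]")
    n = len(contest.entries)
    n_bins = max(1, round(1.0 / bin_fraction))
    if n < n_bins:
        logger.warning(
            "contest %s: %d entries < %d bins; using %d single-entry bins",
            contest.contest_id,
            n,
            n_bins,
            n,
        )
        n_bins = n
    total_lines = sum(e.total_lines for e in contest.entries)
    if total_lines == 0:
        raise ValueError(f"contest {contest.contest_id}: no lines submitted")
    sizes = np.full(n_bins, n // n_bins, dtype=int)
    sizes[: n % n_bins] += 1
    bins: list[DiversityBin] = []
    start = 0
    for b, size in enumerate(sizes, start=1):
        chunk = contest.entries[start : start + size]
        unique = set()
        for e in chunk:
            unique.update(e.lines)
        bins.append(
            DiversityBin(
                contest_id=contest.contest_id,
                bin_index=b,
                n_entries=size,
                unique_lines_in_bin=len(unique),
                total_lines_in_contest=total_lines,
            )
        )
        start += size
    return bins


def squeeze_unit_interval(y: float | np.ndarray, n: int) -> float | np.ndarray:
    """Compress [0, 1] onto the open interval: (y (n - 1) + 0.5) / n.

    The standard transformation for beta likelihoods when exact 0 or 1
    can occur; ``n`` is the number of observations in the dataset.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    y = np.asarray(y, dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("y must lie in [0, 1]")
    out = (y * (n - 1) + 0.5) / n
    return float(out) if out.ndim == 0 else out


def bins_frame(bins_by_contest: dict[str, list[DiversityBin]]) -> pd.DataFrame:
    """Stack per-contest bins into the model's long-format data table.

    Adds the squeezed response ``y`` and the centred covariate ``x``
    (one unit = 10% of the contest's bins).
    """
    rows = []
    for contest_id, bins in bins_by_contest.items():
        n_bins = len(bins)
        for b in bins:
            rows.append(
                {
                    "contest_id": contest_id,
                    "bin_index": b.bin_index,
                    "n_entries": b.n_entries,
                    "unique_lines_in_bin": b.unique_lines_in_bin,
                    "total_lines_in_contest": b.total_lines_in_contest,
                    "diversity": b.diversity,
                    "x": (b.bin_index - (n_bins + 1) / 2.0) / (n_bins / 10.0),
                }
            )
    df = pd.DataFrame(rows)
    df["y"] = squeeze_unit_interval(df["diversity"].to_numpy(), len(df))
    return df


# ---------------------------------------------------------------------------
# the beta GLMM
# ---------------------------------------------------------------------------


@dataclass
class BetaGLMMConfig:
    """Sampler and prior configuration for the beta mixed model.

    ``n_chains`` independent walker ensembles are run from jittered
    starts; each ensemble's pooled post-burn-in draws form one chain
    for the R-hat/ESS diagnostics.  Ensemble moves are an 80/20
    mixture of differential-evolution and snooker proposals, which mix
    far better than the default stretch move at this dimensionality
    (five hyperparameters plus two random effects per contest).
    """

    n_chains: int = 3
    n_walkers: int = 96
    n_burn: int = 1000
    n_steps: int = 500
    thin: int = 1
    mu_prior_sd: float = 10.0
    sigma_upper: float = 10.0
    phi_upper: float = 2000.0
    rhat_threshold: float = 1.01
    seed: int = 0


@dataclass
class PosteriorSummary:
    """Posterior draws and convergence diagnostics of a fitted model."""

    summary: pd.DataFrame  # index: parameter; mean, median, CI bounds, ess, r_hat
    idata: az.InferenceData
    contest_ids: list[str]
    converged: bool
    max_rhat: float
    single_contest: bool = False

    def param_mean(self, name: str) -> float:
        return float(self.summary.loc[name, "mean"])

    def param_ci(self, name: str) -> tuple[float, float]:
        return (
            float(self.summary.loc[name, "ci_2.5%"]),
            float(self.summary.loc[name, "ci_97.5%"]),
        )

    def draws(self, name: str) -> np.ndarray:
        return self.idata.posterior[name].to_numpy().ravel()


def _beta_loglik(y_log: np.ndarray, y1_log: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Beta log-likelihood in mean-precision form, summed over observations.

    Shape parameters a = mu * phi, b = (1 - mu) * phi; phi broadcasts
    over walkers.
    """
    a = mu * phi
    b = (1.0 - mu) * phi
    ll = (
        gammaln(a + b)
        - gammaln(a)
        - gammaln(b)
        + (a - 1.0) * y_log
        + (b - 1.0) * y1_log
    )
    return ll.sum(axis=-1)


class _BetaGLMMPosterior:
    """Vectorised log-posterior over walker batches.

    Parameter vector layout:
    [mu_int, mu_slope, log_sigma_int, log_sigma_slope, log_phi,
     alpha_1..alpha_J, beta_1..beta_J]

    The scale parameters are sampled on the log scale (better geometry
    for the ensemble moves); the flat-uniform priors on the natural
    scale pick up the corresponding log-Jacobian term.
    """

    def __init__(self, y: np.ndarray, x: np.ndarray, contest_idx: np.ndarray, n_contests: int, cfg: BetaGLMMConfig):
        self.y_log = np.log(y)
        self.y1_log = np.log1p(-y)
        self.x = x
        self.idx = contest_idx
        self.J = n_contests
        self.cfg = cfg
        self.ndim = 5 + 2 * n_contests

    def __call__(self, theta: np.ndarray) -> np.ndarray:
        single = theta.ndim == 1
        th = np.atleast_2d(theta)
        W = th.shape[0]
        mu_int, mu_slope = th[:, 0], th[:, 1]
        log_sig_int, log_sig_slope, log_phi = th[:, 2], th[:, 3], th[:, 4]
        alpha = th[:, 5 : 5 + self.J]
        beta = th[:, 5 + self.J :]
        sig_int = np.exp(log_sig_int)
        sig_slope = np.exp(log_sig_slope)
        phi = np.exp(log_phi)

        lp = np.full(W, -np.inf)
        ok = (sig_int < self.cfg.sigma_upper) & (sig_slope < self.cfg.sigma_upper) & (phi < self.cfg.phi_upper)
        if not np.any(ok):
            return lp[0] if single else lp

        # priors
        prior = -0.5 * (mu_int**2 + mu_slope**2) / self.cfg.mu_prior_sd**2
        # uniform prior on sigma/phi + log-scale Jacobian
        prior = prior + log_sig_int + log_sig_slope + log_phi
        # random effects
        prior = prior - 0.5 * ((alpha - mu_int[:, None]) ** 2 / sig_int[:, None] ** 2).sum(axis=1)
        prior = prior - self.J * log_sig_int
        prior = prior - 0.5 * ((beta - mu_slope[:, None]) ** 2 / sig_slope[:, None] ** 2).sum(axis=1)
        prior = prior - self.J * log_sig_slope

        eta = alpha[:, self.idx] + beta[:, self.idx] * self.x[None, :]
        mu = expit(eta)
        # guard against underflow at extreme linear predictors
        mu = np.clip(mu, 1e-12, 1.0 - 1e-12)
        ll = _beta_loglik(self.y_log[None, :], self.y1_log[None, :], mu, phi[:, None])
        lp_ok = prior + ll
        lp[ok] = lp_ok[ok]
        return lp[0] if single else lp


def _initial_state(df: pd.DataFrame, contest_codes: np.ndarray, J: int, cfg: BetaGLMMConfig, rng: np.random.Generator) -> np.ndarray:
    """Walker initialisation from per-contest least squares on logit(y)."""
    z = logit(np.clip(df["y"].to_numpy(), 1e-6, 1 - 1e-6))
    x = df["x"].to_numpy()
    alpha0 = np.zeros(J)
    beta0 = np.zeros(J)
    resid_var = []
    for j in range(J):
        m = contest_codes == j
        if m.sum() >= 3 and np.ptp(x[m]) > 0:
            coef = np.polyfit(x[m], z[m], 1)
            beta0[j], alpha0[j] = coef[0], coef[1]
            resid_var.append(np.var(z[m] - np.polyval(coef, x[m])))
        else:
            alpha0[j] = z[m].mean() if m.any() else 0.0
    mu_int0, mu_slope0 = alpha0.mean(), beta0.mean()
    sig_int0 = max(alpha0.std(), 0.05)
    sig_slope0 = max(beta0.std(), 0.02)
    # var(logit y) ~ 1 / (mu (1 - mu) (phi + 1)) near mu: crude moment start
    mu_bar = float(np.mean(df["y"]))
    v = float(np.mean(resid_var)) if resid_var else 0.1
    phi0 = min(max(1.0 / max(v * mu_bar * (1 - mu_bar), 1e-6) - 1.0, 2.0), cfg.phi_upper / 2)
    center = np.concatenate(
        [
            [mu_int0, mu_slope0, np.log(sig_int0), np.log(sig_slope0), np.log(phi0)],
            alpha0,
            beta0,
        ]
    )
    scale = np.concatenate(
        [[0.1, 0.05, 0.2, 0.2, 0.2], np.full(J, 0.05), np.full(J, 0.02)]
    )
    return center[None, :] + scale[None, :] * rng.standard_normal((cfg.n_walkers, center.size))


def fit_beta_glmm(
    bins_by_contest: dict[str, list[DiversityBin]] | pd.DataFrame,
    config: BetaGLMMConfig | None = None,
) -> PosteriorSummary:
    """Fit the beta mixed-effects diversity regression by ensemble MCMC.

    Accepts either the per-contest bin lists or a prepared long-format
    frame with columns ``contest_id``, ``y`` (response in the open unit
    interval) and ``x`` (centred covariate, one unit = 10% of contest).

    With a single contest the random-effect scales are unidentified;
    the model is still sampled but flagged, and hyper-means then track
    that contest's own intercept and slope.
    """
    cfg = config or BetaGLMMConfig()
    df = bins_by_contest if isinstance(bins_by_contest, pd.DataFrame) else bins_frame(bins_by_contest)
    if not {"contest_id", "y", "x"}.issubset(df.columns):
        raise ValueError("model frame needs columns contest_id, y, x")
    y = df["y"].to_numpy(dtype=float)
    if np.any((y <= 0) | (y >= 1)):
        raise ValueError("response must lie strictly inside (0, 1); apply squeeze_unit_interval")
    contest_ids = list(pd.unique(df["contest_id"]))
    codes = pd.Categorical(df["contest_id"], categories=contest_ids).codes.astype(int)
    J = len(contest_ids)
    single_contest = J < 2
    if single_contest:
        logger.warning("single contest: random-effect scales are not identified")

    logpost = _BetaGLMMPosterior(y, df["x"].to_numpy(dtype=float), codes, J, cfg)
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    chains = []
    for c in range(cfg.n_chains):
        chain_seed = cfg.seed + 1_000_003 * c
        rng = np.random.default_rng(chain_seed)
        p0 = _initial_state(df, codes, J, cfg, rng)
        sampler = emcee.EnsembleSampler(
            cfg.n_walkers, logpost.ndim, logpost, vectorize=True, moves=moves
        )
        sampler.random_state = np.random.RandomState(chain_seed % (2**32)).get_state()
        state = sampler.run_mcmc(p0, cfg.n_burn, progress=False)
        sampler.reset()
        sampler.run_mcmc(state, cfg.n_steps, thin_by=cfg.thin, progress=False)
        chains.append(sampler.get_chain())  # (steps, walkers, ndim)

    names = (
        ["mu_int", "mu_slope", "sigma_int", "sigma_slope", "phi"]
        + [f"alpha[{c}]" for c in contest_ids]
        + [f"beta[{c}]" for c in contest_ids]
    )
    # one pooled chain per ensemble, walker-contiguous so within-walker
    # autocorrelation is preserved for the ESS estimate; natural scale
    # for the three log-sampled parameters
    posterior = {}
    for k, name in enumerate(names):
        per_chain = []
        for ch in chains:
            d = ch[:, :, k].T.reshape(-1)  # (walkers*steps,)
            per_chain.append(np.exp(d) if 2 <= k <= 4 else d)
        posterior[name] = np.stack(per_chain)  # (chains, draws)
    idata = az.from_dict(posterior=posterior)

    rows = []
    for name in names:
        draws = posterior[name]
        flat = draws.ravel()
        rhat = float(az.rhat(az.convert_to_dataset({name: draws}))[name].values)
        ess = float(az.ess(az.convert_to_dataset({name: draws}))[name].values)
        lo, hi = np.percentile(flat, [2.5, 97.5])
        rows.append(
            {
                "parameter": name,
                "mean": float(flat.mean()),
                "median": float(np.median(flat)),
                "sd": float(flat.std(ddof=1)),
                "ci_2.5%": float(lo),
                "ci_97.5%": float(hi),
                "ess": ess,
                "r_hat": rhat,
            }
        )
    summary = pd.DataFrame(rows).set_index("parameter")
    hyper = ["mu_int", "mu_slope", "sigma_int", "sigma_slope", "phi"]
    max_rhat = float(summary.loc[hyper, "r_hat"].max())
    converged = bool(max_rhat < cfg.rhat_threshold)
    if not converged:
        logger.warning("MCMC not converged: max hyperparameter R-hat = %.4f", max_rhat)
    return PosteriorSummary(
        summary=summary,
        idata=idata,
        contest_ids=contest_ids,
        converged=converged,
        max_rhat=max_rhat,
        single_contest=single_contest,
    )


def predicted_diversity_change(
    summary: PosteriorSummary, from_diversity: float, delta_bins: float
) -> float:
    """Posterior-mean plug-in prediction of diversity after a covariate shift.

    ``delta_bins`` is in covariate units (one unit = 10% of a contest):
    returns inverse-logit(logit(d) + mu_slope * delta_bins).
    """
    if not (0.0 < from_diversity < 1.0):
        raise ValueError("from_diversity must be strictly inside (0, 1)")
    slope = summary.param_mean("mu_slope")
    return float(expit(logit(from_diversity) + slope * delta_bins))


def prediction_curves(summary: PosteriorSummary, n_bins: int = 100) -> pd.DataFrame:
    """Per-contest and overall posterior-mean diversity curves over bins."""
    xs = (np.arange(1, n_bins + 1) - (n_bins + 1) / 2.0) / (n_bins / 10.0)
    rows = {}
    for cid in summary.contest_ids:
        a = summary.param_mean(f"alpha[{cid}]")
        b = summary.param_mean(f"beta[{cid}]")
        rows[cid] = expit(a + b * xs)
    rows["overall"] = expit(summary.param_mean("mu_int") + summary.param_mean("mu_slope") * xs)
    out = pd.DataFrame(rows)
    out.insert(0, "bin_index", np.arange(1, n_bins + 1))
    return out


def simulate_diversity_dataset(
    mu_int: float = -2.0,
    mu_slope: float = -0.15,
    sigma_int: float = 0.3,
    sigma_slope: float = 0.05,
    phi: float = 50.0,
    n_contests: int = 19,
    n_bins: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a bin-level diversity dataset directly from the model.

    Used for parameter-recovery and calibration checks: contest-level
    intercepts/slopes from their normal population distributions, then
    beta responses around the logit-linear mean.  Returns the long
    format `fit_beta_glmm` accepts.
    """
    rng = np.random.default_rng(seed)
    xs = (np.arange(1, n_bins + 1) - (n_bins + 1) / 2.0) / (n_bins / 10.0)
    rows = []
    for j in range(n_contests):
        alpha = rng.normal(mu_int, sigma_int)
        beta = rng.normal(mu_slope, sigma_slope)
        mu = expit(alpha + beta * xs)
        y = rng.beta(mu * phi, (1 - mu) * phi)
        y = np.clip(y, 1e-9, 1 - 1e-9)
        for b in range(n_bins):
            rows.append(
                {
                    "contest_id": f"sim{j:02d}",
                    "bin_index": b + 1,
                    "x": xs[b],
                    "y": y[b],
                    "diversity": y[b],
                }
            )
    return pd.DataFrame(rows)
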