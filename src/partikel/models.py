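"""Bayesian models for reading-time and cloze data.

Three model families are implemented:

* Hierarchical Gaussian reading-time models with crossed participant and item
  random effects, on either the reciprocal scale (speed = 1000/rt, words per
  second; self-paced reading) or the log-ms scale (eye-tracking measures).
  The Gaussian random effects are integrated out analytically, so the sampler
  only explores the fixed effects and the variance parameters.  This keeps the
  posterior low-dimensional, which makes both MCMC (emcee's affine-invariant
  ensemble) and bridge-sampling marginal likelihoods cheap and stable.

* A zero/one-inflated Beta (ZOIB) regression for target-particle cloze
  probabilities, which places point masses at 0 and 1 atop a Beta distribution
  with a logit-linear mean.

* A hurdle-lognormal regression for per-item entropies, with a point mass at
  zero and a lognormal for positive values.

Box-Cox transform selection and the prior-predictive arithmetic used to
justify the priors are also provided.

Contrast coding throughout: small set / short distance = -0.5, large set /
long distance = +0.5; the interaction is the product.  On the reciprocal
scale a positive slope therefore means *faster* reading (more words per
second); on the log scale a positive slope means *slower* reading.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

import arviz as az
import emcee

Scale = Literal["reciprocal_speed", "log_ms"]

_LOG_2PI = float(np.log(2 * np.pi))


class ModelError(ValueError):
    """Invalid model input or configuration."""


class UnconvergedError(RuntimeError):
    """A downstream consumer refused a fit flagged as unconverged."""


# ---------------------------------------------------------------------------
# Contrast coding and priors


@dataclass
class ContrastCoding:
    """Sum-to-zero +-0.5 effect codes for the 2x2 design."""

    set_size: dict = field(default_factory=lambda: {"small": -0.5, "large": 0.5})
    distance: dict = field(default_factory=lambda: {"short": -0.5, "long": 0.5})
    center_entropy: bool = True

    def __post_init__(self) -> None:
        for name, mapping in (("set_size", self.set_size),
                              ("distance", self.distance)):
            if abs(sum(mapping.values())) > 1e-12:
                raise ModelError(f"{name} codes must sum to zero")


@dataclass
class PriorSpec:
    """Priors of the hierarchical reading-time model.

    intercept ~ Normal(intercept_loc, intercept_scale) on the analysis scale;
    slopes ~ Normal(0, slope_scale); random-effect SDs and the residual SD get
    half-Normal(0, .) priors.  ``lkj_eta`` records the LKJ concentration for
    random-effect correlation matrices; the marginal sampler treats random
    effects as independent (see docs), so the value is carried for reporting
    only.
    """

    intercept_loc: float
    intercept_scale: float
    slope_scale: float = 0.5
    re_sd_scale: float = 0.25
    resid_sd_scale: float = 0.25
    lkj_eta: float = 2.0

    def __post_init__(self) -> None:
        for name in ("intercept_scale", "slope_scale", "re_sd_scale",
                     "resid_sd_scale"):
            if getattr(self, name) <= 0:
                raise ModelError(f"{name} must be positive")
        if self.lkj_eta < 1:
            raise ModelError("lkj_eta must be >= 1")

    @classmethod
    def self_paced_reading(cls, **overrides) -> "PriorSpec":
        """Reciprocal-scale priors: mean speed ~3 words/s, 95% in [2, 4]."""
        base = dict(intercept_loc=3.0, intercept_scale=0.5, slope_scale=0.5,
                    re_sd_scale=0.25, resid_sd_scale=0.25)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def eye_tracking(cls, **overrides) -> "PriorSpec":
        """Log-scale priors: mean duration ~300 ms (5.7), 95% in [110, 812]."""
        base = dict(intercept_loc=5.7, intercept_scale=0.5, slope_scale=0.5,
                    re_sd_scale=1.0, resid_sd_scale=1.0)
        base.update(overrides)
        return cls(**base)


def _round_half_up(x: float) -> float:
    return float(np.floor(x + 0.5))


@dataclass
class PriorPredictiveBounds:
    response_low: float
    response_high: float
    prior_mean_response: float
    effect_slowdown: float
    effect_speedup: float


def prior_predictive_bounds(
    prior: PriorSpec, scale: Scale, k_sd: float = 2.0
) -> PriorPredictiveBounds:
    """Back-transform the intercept and slope priors to the response scale.

    The interval is mean +- k_sd prior SDs of the intercept, back-transformed
    (exp for log_ms, identity for the words-per-second reciprocal scale) and
    rounded half-up to integers.  Effect bounds are the differences between
    the back-transformed intercept +- k_sd slope-prior SDs and the prior-mean
    response.
    """
    if k_sd < 0:
        raise ModelError("k_sd must be non-negative")
    back = np.exp if scale == "log_ms" else (lambda x: x)
    mu = prior.intercept_loc
    lo = _round_half_up(back(mu - k_sd * prior.intercept_scale))
    hi = _round_half_up(back(mu + k_sd * prior.intercept_scale))
    center = _round_half_up(back(mu))
    slow = _round_half_up(back(mu + k_sd * prior.slope_scale)) - center
    speed = center - _round_half_up(back(mu - k_sd * prior.slope_scale))
    return PriorPredictiveBounds(
        response_low=lo,
        response_high=hi,
        prior_mean_response=center,
        effect_slowdown=slow,
        effect_speedup=speed,
    )


# ---------------------------------------------------------------------------
# Box-Cox transform selection


def select_boxcox_lambda(
    y: Sequence[float], grid: np.ndarray | None = None
) -> tuple[float, pd.DataFrame]:
    """Profile-likelihood Box-Cox selection over a lambda grid.

    The transform is (y^lambda - 1)/lambda, log y at lambda = 0.  Default grid
    is [-2, 2] in steps of 0.1.  All responses must be positive; non-positive
    values should be removed by the exclusion step first.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 3:
        raise ModelError("need at least 3 observations")
    if np.any(y <= 0):
        raise ModelError(
            "Box-Cox requires positive responses; apply the exclusion step "
            "(e.g. rt >= 100 ms) before transform selection"
        )
    if grid is None:
        grid = np.round(np.arange(-2.0, 2.0 + 1e-9, 0.1), 10)
    llf = np.array([stats.boxcox_llf(lam, y) for lam in grid])
    profile = pd.DataFrame({"lambda": grid, "loglik": llf})
    return float(grid[np.argmax(llf)]), profile


# ---------------------------------------------------------------------------
# Posterior container


@dataclass
class PosteriorSummary:
    """MCMC output: per-parameter summaries, draws, and diagnostics.

    ``draws`` is (n_samples, n_params) on the unconstrained scale used by the
    sampler; ``params`` reports means and 95% credible intervals on the
    natural scale (SDs exponentiated).  ``log_prob`` is the unnormalized
    log-posterior (batched over rows) needed for bridge sampling, and
    ``fingerprint`` identifies the data/response so Bayes factors can refuse
    mismatched comparisons.
    """

    params: pd.DataFrame
    draws: np.ndarray
    param_names: list[str]
    converged: bool
    max_rhat: float
    min_ess: float
    log_prob: Callable[[np.ndarray], np.ndarray]
    fingerprint: str
    n_obs: int
    transform: Callable[[np.ndarray], np.ndarray]  # unconstrained -> natural

    def natural_draws(self) -> np.ndarray:
        return self.transform(self.draws)


def _summarize_chains(
    chain: np.ndarray,  # (n_chains, n_draws, d) unconstrained
    param_names: list[str],
    transform: Callable[[np.ndarray], np.ndarray],
    rhat_threshold: float = 1.01,
) -> tuple[pd.DataFrame, bool, float, float]:
    natural = transform(chain.reshape(-1, chain.shape[-1])).reshape(chain.shape)
    data = {name: natural[:, :, j] for j, name in enumerate(param_names)}
    idata = az.from_dict(posterior=data)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(idata)
        ess = az.ess(idata)
    rows = []
    for j, name in enumerate(param_names):
        vals = natural[:, :, j].ravel()
        rows.append(
            {
                "parameter": name,
                "mean": float(np.mean(vals)),
                "ci_low": float(np.percentile(vals, 2.5)),
                "ci_high": float(np.percentile(vals, 97.5)),
                "rhat": float(rhat[name].values),
                "ess": float(ess[name].values),
            }
        )
    params = pd.DataFrame(rows)
    max_rhat = float(params["rhat"].max())
    min_ess = float(params["ess"].min())
    converged = bool(max_rhat < rhat_threshold)
    if not converged:
        warnings.warn(
            f"chains not converged: max split-Rhat = {max_rhat:.3f} "
            f">= {rhat_threshold}",
            stacklevel=3,
        )
    return params, converged, max_rhat, min_ess


def _run_emcee(
    log_prob_batch: Callable[[np.ndarray], np.ndarray],
    start: np.ndarray,
    param_names: list[str],
    transform: Callable[[np.ndarray], np.ndarray],
    *,
    n_walkers: int = 48,
    n_warmup: int = 600,
    n_steps: int = 600,
    thin: int = 2,
    seed: int = 0,
    n_chains: int = 4,
    fingerprint: str = "",
    n_obs: int = 0,
    init_scale: float = 0.05,
) -> PosteriorSummary:
    """Shared emcee driver; walkers are split into chains for split-Rhat."""
    d = start.size
    n_walkers = max(n_walkers, 2 * d + 2)
    n_walkers += (-n_walkers) % n_chains
    rng = np.random.default_rng(seed)
    p0 = start + init_scale * rng.standard_normal((n_walkers, d))
    lp0 = log_prob_batch(p0)
    bad = ~np.isfinite(lp0)
    tries = 0
    while bad.any() and tries < 50:
        p0[bad] = start + init_scale * rng.standard_normal((int(bad.sum()), d))
        lp0 = log_prob_batch(p0)
        bad = ~np.isfinite(lp0)
        tries += 1
    if bad.any():
        raise ModelError("could not initialize walkers at finite log-posterior")

    # differential-evolution moves mix far better than the default stretch
    # move on these correlated targets; the snooker variant is avoided because
    # it yields measurably underdispersed posteriors in this emcee version
    sampler = emcee.EnsembleSampler(
        n_walkers, d, log_prob_batch, vectorize=True,
        moves=[(emcee.moves.DEMove(), 0.9),
               (emcee.moves.DEMove(gamma0=1.0), 0.1)],
    )
    sampler.random_state = np.random.RandomState(seed + 1).get_state()
    state = sampler.run_mcmc(
        p0, n_warmup, skip_initial_state_check=True, progress=False
    )
    sampler.reset()
    sampler.run_mcmc(state, n_steps, skip_initial_state_check=True,
                     progress=False)
    chain = sampler.get_chain(thin=thin)  # (steps, walkers, d)
    # regroup walkers into pseudo-chains: (n_chains, steps * walkers/chain, d)
    steps, walkers, _ = chain.shape
    per = walkers // n_chains
    grouped = np.concatenate(
        [
            chain[:, c * per:(c + 1) * per, :].reshape(1, steps * per, d)
            for c in range(n_chains)
        ],
        axis=0,
    )
    params, converged, max_rhat, min_ess = _summarize_chains(
        grouped, param_names, transform
    )
    return PosteriorSummary(
        params=params,
        draws=grouped.reshape(-1, d),
        param_names=param_names,
        converged=converged,
        max_rhat=max_rhat,
        min_ess=min_ess,
        log_prob=log_prob_batch,
        fingerprint=fingerprint,
        n_obs=n_obs,
        transform=transform,
    )


def _halfnormal_logpdf(x: np.ndarray, scale: float) -> np.ndarray:
    return (0.5 * _LOG_2PI * -1 + np.log(2.0) - np.log(scale)
            - 0.5 * (x / scale) ** 2)


def _normal_logpdf(x: np.ndarray, loc: float, scale: float) -> np.ndarray:
    return -0.5 * _LOG_2PI - np.log(scale) - 0.5 * ((x - loc) / scale) ** 2


def _fingerprint(y: np.ndarray, tag: str) -> str:
    h = hashlib.sha1(np.ascontiguousarray(y).tobytes())
    h.update(tag.encode())
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# Marginalized hierarchical Gaussian model


class MarginalHierarchicalModel:
    """Gaussian mixed model with analytically marginalized random effects.

    y = X beta + Z_p u + Z_i w + eps, with u, w independent Gaussians.  The
    marginal covariance V = sigma^2 I + U U^T (U = Z diag(sd)) is handled with
    the Woodbury identity, and because X, Z are fixed per dataset, every
    likelihood evaluation reduces to dense algebra on precomputed
    cross-products — no O(N) work inside the sampler.

    ``random_structure``: "intercepts" (by-participant and by-item intercepts),
    "slopes" (intercepts plus independent random slopes for every fixed
    effect), or "none" (plain regression; used by conjugate oracles).
    """

    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray,
        participant_idx: np.ndarray,
        item_idx: np.ndarray,
        prior: PriorSpec,
        random_structure: str = "intercepts",
        slope_names: Sequence[str] = (),
    ) -> None:
        self.y = np.asarray(y, float)
        self.X = np.asarray(X, float)
        self.n, self.p = self.X.shape
        self.prior = prior
        self.random_structure = random_structure
        self.slope_names = list(slope_names)

        n_part = int(participant_idx.max()) + 1 if self.n else 0
        n_item = int(item_idx.max()) + 1 if self.n else 0
        if random_structure == "none":
            re_cols: list[tuple[int, int]] = []  # (grouping sd index, X col)
            Z = np.zeros((self.n, 0))
            self.sd_names: list[str] = []
        else:
            n_coef = self.p if random_structure == "slopes" else 1
            blocks = []
            col_sd = []
            sd_names = []
            for g, (idx, ng, label) in enumerate(
                ((participant_idx, n_part, "participant"),
                 (item_idx, n_item, "item"))
            ):
                for q in range(n_coef):
                    B = np.zeros((self.n, ng))
                    B[np.arange(self.n), idx] = self.X[:, q]
                    blocks.append(B)
                    col_sd.extend([(len(sd_names))] * ng)
                    coef = "intercept" if q == 0 else self.slope_names[q - 1]
                    sd_names.append(f"sd_{label}_{coef}")
            Z = np.hstack(blocks)
            re_cols = col_sd
            self.sd_names = sd_names
        self.Z = Z
        self.k = Z.shape[1]
        self.col_sd_index = np.asarray(re_cols, dtype=int)
        self.n_sd = len(self.sd_names)

        # precomputed cross-products: all per-evaluation work is O(k^3)
        self.XtX = self.X.T @ self.X
        self.Xty = self.X.T @ self.y
        self.yty = float(self.y @ self.y)
        self.ZtZ = Z.T @ Z
        self.ZtX = Z.T @ self.X
        self.Zty = Z.T @ self.y

    # parameter vector: [beta (p), log re_sds (n_sd), log sigma]
    @property
    def n_params(self) -> int:
        return self.p + self.n_sd + 1

    def param_names(self, fixed_names: Sequence[str]) -> list[str]:
        return list(fixed_names) + self.sd_names + ["sigma"]

    def transform(self, draws: np.ndarray) -> np.ndarray:
        out = draws.copy()
        out[..., self.p:] = np.exp(out[..., self.p:])
        return out

    def start_point(self) -> np.ndarray:
        beta, *_ = np.linalg.lstsq(self.X, self.y, rcond=None)
        resid = self.y - self.X @ beta
        s = max(float(np.std(resid)), 1e-3)
        start = np.concatenate(
            [beta, np.log(np.full(self.n_sd, 0.5 * s) + 1e-6), [np.log(s)]]
        )
        return start

    def log_likelihood_batch(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        m = theta.shape[0]
        beta = theta[:, : self.p]
        log_sds = theta[:, self.p: self.p + self.n_sd]
        sigma = np.exp(theta[:, -1])
        sigma2 = sigma**2

        rtr = (
            self.yty
            - 2.0 * beta @ self.Xty
            + np.einsum("mi,ij,mj->m", beta, self.XtX, beta)
        )
        if self.k == 0:
            quad = rtr / sigma2
            logdet = self.n * np.log(sigma2)
            return -0.5 * (self.n * _LOG_2PI + logdet + quad)

        sds = np.exp(log_sds)[:, self.col_sd_index]  # (m, k)
        a = sds * (self.Zty[None, :] - beta @ self.ZtX.T)  # (m, k) = U^T r
        C = np.eye(self.k)[None, :, :] + (
            sds[:, :, None] * sds[:, None, :] * self.ZtZ[None, :, :]
        ) / sigma2[:, None, None]
        try:
            chol = np.linalg.cholesky(C)
        except np.linalg.LinAlgError:
            return np.full(m, -np.inf)
        logdet = self.n * np.log(sigma2) + 2.0 * np.sum(
            np.log(np.diagonal(chol, axis1=1, axis2=2)), axis=1
        )
        sol = np.linalg.solve(C, a[:, :, None])[:, :, 0]
        quad = (rtr - np.einsum("mk,mk->m", a, sol) / sigma2) / sigma2
        return -0.5 * (self.n * _LOG_2PI + logdet + quad)

    def log_prior_batch(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        beta = theta[:, : self.p]
        lp = _normal_logpdf(beta[:, 0], self.prior.intercept_loc,
                            self.prior.intercept_scale)
        if self.p > 1:
            lp = lp + np.sum(
                _normal_logpdf(beta[:, 1:], 0.0, self.prior.slope_scale),
                axis=1,
            )
        # half-normal on each SD, sampled on the log scale (Jacobian = +log sd)
        for j in range(self.n_sd):
            ell = theta[:, self.p + j]
            lp = lp + _halfnormal_logpdf(np.exp(ell), self.prior.re_sd_scale) + ell
        ell = theta[:, -1]
        lp = lp + _halfnormal_logpdf(np.exp(ell), self.prior.resid_sd_scale) + ell
        return lp

    def log_prob_batch(self, theta: np.ndarray) -> np.ndarray:
        lp = self.log_prior_batch(theta)
        out = np.full(lp.shape, -np.inf)
        ok = np.isfinite(lp)
        if ok.any():
            out[ok] = lp[ok] + self.log_likelihood_batch(np.atleast_2d(theta)[ok])
        return out


def prepare_reading_data(
    trials: pd.DataFrame,
    coding: ContrastCoding,
    scale: Scale,
    *,
    predictors: str = "categorical",
    response_column: str | None = None,
    rt_min_ms: float = 100.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[str], dict]:
    """Transform, exclude, and code trials into (y, X, part_idx, item_idx).

    For the reciprocal scale the response is 1000/rt after excluding presses
    below ``rt_min_ms``; for the log scale it is log rt with non-positive and
    missing values dropped.  ``predictors`` is "categorical" (set size x
    distance) or "entropy" (continuous entropy x distance).
    """
    col = response_column
    if col is None:
        col = "rt_ms" if scale == "reciprocal_speed" else "ffd_ms"
    df = trials.copy()
    n_in = len(df)
    df = df[df[col].notna()]
    n_missing = n_in - len(df)
    if scale == "reciprocal_speed":
        excluded = df[col] < rt_min_ms
        df = df[~excluded]
        y = 1000.0 / df[col].to_numpy(float)
        n_fast = int(excluded.sum())
    else:
        bad = df[col] <= 0
        df = df[~bad]
        y = np.log(df[col].to_numpy(float))
        n_fast = int(bad.sum())
    if len(df) < 8:
        raise ModelError(f"only {len(df)} usable trials after exclusion")

    c_d = df["distance"].map(coding.distance).to_numpy(float)
    if predictors == "categorical":
        x1 = df["set_size"].map(coding.set_size).to_numpy(float)
        names = ["set_size", "distance", "set_size:distance"]
    elif predictors == "entropy":
        h = df["entropy_bits"].to_numpy(float)
        x1 = h - h.mean() if coding.center_entropy else h
        names = ["entropy", "distance", "entropy:distance"]
    else:
        raise ModelError(f"unknown predictors {predictors!r}")
    X = np.column_stack([np.ones(len(df)), x1, c_d, x1 * c_d])

    participants = pd.Categorical(df["participant"])
    items = pd.Categorical(df["item"])
    log = {
        "trials_in": n_in,
        "trials_retained": len(df),
        "excluded_missing": n_missing,
        "excluded_fast_or_nonpositive": n_fast,
    }
    return (y, X, np.asarray(participants.codes), np.asarray(items.codes),
            names, log)


def fit_reading_model(
    trials: pd.DataFrame,
    coding: ContrastCoding,
    prior: PriorSpec,
    scale: Scale,
    *,
    predictors: str = "categorical",
    response_column: str | None = None,
    random_structure: str = "intercepts",
    rt_min_ms: float = 100.0,
    n_walkers: int = 48,
    n_warmup: int = 600,
    n_steps: int = 600,
    seed: int = 0,
    drop_predictor: str | None = None,
) -> PosteriorSummary:
    """Fit the hierarchical reading-time model by MCMC.

    ``drop_predictor`` refits a reduced model without the named fixed effect
    (for Bayes-factor comparisons); when ``random_structure="slopes"`` the
    corresponding random slopes are retained so that the comparison targets
    the population-level effect only.
    """
    y, X, part_idx, item_idx, slope_names, exclusion_log = prepare_reading_data(
        trials, coding, scale, predictors=predictors,
        response_column=response_column, rt_min_ms=rt_min_ms,
    )
    if random_structure != "none":
        if len(np.unique(part_idx)) < 2 or len(np.unique(item_idx)) < 2:
            raise ModelError(
                "need at least 2 participants and 2 items for crossed "
                "random effects"
            )
    fixed_names = ["intercept"] + slope_names
    keep = list(range(X.shape[1]))
    if drop_predictor is not None:
        if drop_predictor not in slope_names:
            raise ModelError(f"unknown predictor {drop_predictor!r}")
        keep.remove(1 + slope_names.index(drop_predictor))
        fixed_names = [n for n in fixed_names if n != drop_predictor]

    if drop_predictor is None:
        model = MarginalHierarchicalModel(
            y, X, part_idx, item_idx, prior,
            random_structure=random_structure, slope_names=slope_names,
        )
    elif random_structure == "slopes":
        # reduced model: the fixed effect is dropped but its random slopes
        # are retained, so the comparison targets the population-level effect
        full = MarginalHierarchicalModel(
            y, X, part_idx, item_idx, prior,
            random_structure="slopes", slope_names=slope_names,
        )
        model = MarginalHierarchicalModel(
            y, X[:, keep], part_idx, item_idx, prior,
            random_structure="none",
        )
        model.Z = full.Z
        model.k = full.k
        model.col_sd_index = full.col_sd_index
        model.n_sd = full.n_sd
        model.sd_names = full.sd_names
        model.ZtZ = full.ZtZ
        model.ZtX = full.Z.T @ X[:, keep]
        model.Zty = full.Zty
    else:
        model = MarginalHierarchicalModel(
            y, X[:, keep], part_idx, item_idx, prior,
            random_structure=random_structure, slope_names=slope_names,
        )

    fp = _fingerprint(y, f"{scale}:{predictors}:{response_column}")
    summary = _run_emcee(
        model.log_prob_batch,
        model.start_point(),
        model.param_names(fixed_names),
        model.transform,
        n_walkers=n_walkers,
        n_warmup=n_warmup,
        n_steps=n_steps,
        seed=seed,
        fingerprint=fp,
        n_obs=model.n,
    )
    summary.exclusion_log = exclusion_log  # type: ignore[attr-defined]
    return summary


# ---------------------------------------------------------------------------
# Zero/one-inflated Beta regression (cloze probabilities)


def zoib_log_density(
    y: np.ndarray, alpha: float | np.ndarray, gamma1: float | np.ndarray,
    mu: np.ndarray, phi: float | np.ndarray,
) -> np.ndarray:
    """Pointwise ZOIB log density.

    p(0) = alpha * (1 - gamma1); p(1) = alpha * gamma1;
    p(y in (0,1)) = (1 - alpha) * Beta(y; mu*phi, (1-mu)*phi).
    """
    y = np.asarray(y, float)
    a = mu * phi
    b = (1.0 - mu) * phi
    with np.errstate(divide="ignore", invalid="ignore"):
        cont = (
            np.log1p(-alpha)
            + (a - 1) * np.log(y)
            + (b - 1) * np.log1p(-y)
            - special.betaln(a, b)
        )
    with np.errstate(divide="ignore"):
        out = np.where(
            y == 0.0,
            np.log(alpha) + np.log1p(-gamma1) * np.ones_like(y),
            np.where(y == 1.0, np.log(alpha) + np.log(gamma1), cont),
        )
    return out


def fit_zoib_cloze(
    values: np.ndarray,
    X: np.ndarray,
    *,
    slope_names: Sequence[str] = ("set_size", "distance", "set_size:distance"),
    slope_scale: float = 0.25,
    intercept_scale: float = 1.5,
    n_walkers: int = 48,
    n_warmup: int = 800,
    n_steps: int = 800,
    seed: int = 0,
) -> PosteriorSummary:
    """ZOIB regression of cloze probabilities on coded predictors.

    ``X`` includes the intercept column.  The Beta mean is logit-linear in X;
    the boundary probability alpha and the conditional-one probability gamma1
    are intercept-only.  Slope priors Normal(0, ``slope_scale``); the 0.25
    default is the regularizing prior of the cloze analysis.
    """
    y = np.asarray(values, float)
    if np.any((y < 0) | (y > 1)):
        raise ModelError("cloze values must lie in [0, 1]")
    X = np.asarray(X, float)
    p = X.shape[1]
    names = (["intercept"] + list(slope_names))[:p] + [
        "alpha", "gamma1", "phi"
    ]
    has_zero = bool(np.any(y == 0)) or bool(np.any(y == 1))

    def log_prob(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        beta = theta[:, :p]
        la, lg, lphi = theta[:, p], theta[:, p + 1], theta[:, p + 2]
        alpha = special.expit(la)
        gamma1 = special.expit(lg)
        phi = np.exp(lphi)
        lp = _normal_logpdf(beta[:, 0], 0.0, intercept_scale)
        if p > 1:
            lp = lp + np.sum(_normal_logpdf(beta[:, 1:], 0.0, slope_scale),
                             axis=1)
        # logistic priors on logit(alpha), logit(gamma1) ~ uniform-ish on (0,1)
        lp = lp + _normal_logpdf(la, 0.0, 1.5) + _normal_logpdf(lg, 0.0, 1.5)
        lp = lp + _halfnormal_logpdf(phi, 20.0) + lphi
        mu = special.expit(X @ beta.T)  # (n, m)
        dens = zoib_log_density(
            y[:, None], alpha[None, :], gamma1[None, :], mu, phi[None, :]
        )
        return lp + np.sum(dens, axis=0)

    def transform(draws: np.ndarray) -> np.ndarray:
        out = draws.copy()
        out[..., p] = special.expit(out[..., p])
        out[..., p + 1] = special.expit(out[..., p + 1])
        out[..., p + 2] = np.exp(out[..., p + 2])
        return out

    frac = float(np.mean((y == 0) | (y == 1))) if has_zero else 0.02
    start = np.concatenate([
        [special.logit(np.clip(np.mean(y[(y > 0) & (y < 1)]) if
                               np.any((y > 0) & (y < 1)) else 0.5,
                               0.05, 0.95))],
        np.zeros(p - 1),
        [special.logit(np.clip(frac, 0.02, 0.98))],
        [0.0],
        [np.log(5.0)],
    ])
    return _run_emcee(
        log_prob, start, names, transform,
        n_walkers=n_walkers, n_warmup=n_warmup, n_steps=n_steps, seed=seed,
        fingerprint=_fingerprint(y, "zoib"), n_obs=len(y),
    )


# ---------------------------------------------------------------------------
# Hurdle-lognormal regression (entropies)


def hurdle_lognormal_log_density(
    y: np.ndarray, theta0: float | np.ndarray, mu: np.ndarray,
    sigma: float | np.ndarray,
) -> np.ndarray:
    """p(0) = theta0; p(y > 0) = (1 - theta0) * LogNormal(y; mu, sigma)."""
    y = np.asarray(y, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        logy = np.where(y > 0, np.log(y), 0.0)
        cont = (
            np.log1p(-theta0)
            - logy - np.log(sigma) - 0.5 * _LOG_2PI
            - 0.5 * ((logy - mu) / sigma) ** 2
        )
    with np.errstate(divide="ignore"):
        return np.where(y == 0.0, np.log(theta0) * np.ones_like(cont), cont)


def fit_hurdle_entropy(
    values: np.ndarray,
    X: np.ndarray,
    *,
    slope_names: Sequence[str] = ("set_size", "distance", "set_size:distance"),
    slope_scale: float = 0.01,
    intercept_scale: float = 1.0,
    n_walkers: int = 48,
    n_warmup: int = 800,
    n_steps: int = 800,
    seed: int = 0,
) -> PosteriorSummary:
    """Hurdle-lognormal regression of entropies on coded predictors.

    The 0.01 default slope prior is the regularizing prior of the entropy
    analysis; it shrinks slopes very hard, which is intentional, documented
    behaviour — pass a larger ``slope_scale`` for sensitivity checks.
    """
    y = np.asarray(values, float)
    if np.any(y < 0):
        raise ModelError("entropies must be non-negative")
    X = np.asarray(X, float)
    p = X.shape[1]
    names = (["intercept"] + list(slope_names))[:p] + ["theta0", "sigma_ln"]

    def log_prob(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        beta = theta[:, :p]
        lt, ls = theta[:, p], theta[:, p + 1]
        theta0 = special.expit(lt)
        sigma = np.exp(ls)
        lp = _normal_logpdf(beta[:, 0], 0.0, intercept_scale)
        if p > 1:
            lp = lp + np.sum(_normal_logpdf(beta[:, 1:], 0.0, slope_scale),
                             axis=1)
        lp = lp + _normal_logpdf(lt, 0.0, 1.5)
        lp = lp + _halfnormal_logpdf(sigma, 1.0) + ls
        mu = X @ beta.T  # (n, m)
        dens = hurdle_lognormal_log_density(
            y[:, None], theta0[None, :], mu, sigma[None, :]
        )
        return lp + np.sum(dens, axis=0)

    def transform(draws: np.ndarray) -> np.ndarray:
        out = draws.copy()
        out[..., p] = special.expit(out[..., p])
        out[..., p + 1] = np.exp(out[..., p + 1])
        return out

    pos = y[y > 0]
    frac0 = float(np.mean(y == 0))
    start = np.concatenate([
        [np.log(pos).mean() if pos.size else 0.0],
        np.zeros(p - 1),
        [special.logit(np.clip(frac0, 0.02, 0.98))],
        [np.log(max(np.log(pos).std(), 0.05)) if pos.size > 1 else 0.0],
    ])
    return _run_emcee(
        log_prob, start, names, transform,
        n_walkers=n_walkers, n_warmup=n_warmup, n_steps=n_steps, seed=seed,
        fingerprint=_fingerprint(y, "hurdle"), n_obs=len(y),
    )


def design_matrix_2x2(
    frame: pd.DataFrame, coding: ContrastCoding | None = None
) -> np.ndarray:
    """Intercept + coded set-size, distance, interaction columns."""
    coding = coding or ContrastCoding()
    c1 = frame["set_size"].map(coding.set_size).to_numpy(float)
    c2 = frame["distance"].map(coding.distance).to_numpy(float)
    return np.column_stack([np.ones(len(frame)), c1, c2, c1 * c2])


def write_posterior_table(summary: PosteriorSummary, path) -> None:
    """Parameter, mean, CrI bounds, diagnostics as CSV."""
    summary.params.to_csv(path, index=False)
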