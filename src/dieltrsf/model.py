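"""Hierarchical Bayesian multinomial temporal resource-selection model.

Each detection event i falls in one of K = 5 diel categories (day is the
reference, k = 1). The category is categorical with probabilities given by
a softmax over log-linear scores

    lambda_i1 = log(alpha_i1)
    lambda_ik = x_i' beta_k + b_{c[i],k} + log(alpha_ik),   k > 1,

where alpha_ik is the hours category k offers in event i's diel cycle (an
availability offset), x_i are city-centered, globally scaled covariates,
and b_{c,k} is a random intercept for the city of the event. Because of
the offset, the null model (all effects zero) puts probability
alpha_k / sum(alpha) on each category, i.e. use proportional to
availability; exponentiated coefficients > 1 mean selection for a category
relative to day per unit covariate increase.

Priors: beta_jk ~ Laplace(0, rate pi) — a Bayesian LASSO; pi ~
Uniform(0.001, 10); b_{c,k} ~ Normal(mu_k, precision tau_k); mu_k ~
Normal(0, variance 10); tau_k ~ Gamma(1, 1). The Laplace rate and the
Normal-precision conventions follow the JAGS parameterization
(density (pi/2) exp(-pi |x|); Normal(mean, precision)).

The sampler is adaptive Metropolis-within-Gibbs (see ``_sampler``);
convergence is checked with the classic Gelman-Rubin potential scale
reduction factor (threshold 1.1), with split-R-hat also available.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import log_softmax, softmax
from sklearn.base import BaseEstimator

from ._sampler import run_chain
from .diel import CATEGORIES

__all__ = [
    "ModelData",
    "ModelParams",
    "SamplerConfig",
    "PosteriorSamples",
    "ConvergenceWarning",
    "log_linear_predictor",
    "category_probabilities",
    "log_likelihood",
    "log_prior",
    "sample_posterior",
    "gelman_rubin",
    "TemporalRSF",
]

N_CATEGORIES = len(CATEGORIES)
PI_BOUNDS = (0.001, 10.0)


class ConvergenceWarning(UserWarning):
    pass


@dataclass
class ModelData:
    """Design matrix, outcomes, availability offsets, and city indices.

    X : (I, J) scaled covariates; y : (I,) category codes 0..4 with 0 = day
    (the reference); log_alpha : (I, K) log availability hours; city : (I,)
    city codes 0..C-1.
    """

    X: np.ndarray
    y: np.ndarray
    log_alpha: np.ndarray
    city: np.ndarray
    n_cities: int | None = None

    def __post_init__(self):
        self.X = np.ascontiguousarray(self.X, dtype=float)
        self.y = np.ascontiguousarray(self.y, dtype=np.int64)
        self.log_alpha = np.ascontiguousarray(self.log_alpha, dtype=float)
        self.city = np.ascontiguousarray(self.city, dtype=np.int64)
        I = len(self.y)
        if self.X.shape[0] != I or self.log_alpha.shape[0] != I or len(self.city) != I:
            raise ValueError("X, y, log_alpha, city must share their first dimension")
        if self.log_alpha.shape[1] != N_CATEGORIES:
            raise ValueError(f"log_alpha must have {N_CATEGORIES} columns")
        if not np.all(np.isfinite(self.log_alpha)):
            raise ValueError("log_alpha must be finite (all availabilities positive)")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains non-finite values")
        if self.y.min() < 0 or self.y.max() >= N_CATEGORIES:
            raise ValueError("y codes must lie in 0..4")
        if self.n_cities is None:
            self.n_cities = int(self.city.max()) + 1 if I else 0
        if I and (self.city.min() < 0 or self.city.max() >= self.n_cities):
            raise ValueError("city codes must lie in 0..n_cities-1")

    @property
    def n_events(self) -> int:
        return len(self.y)

    @property
    def n_covariates(self) -> int:
        return self.X.shape[1]

    def observed_categories(self) -> np.ndarray:
        return np.unique(self.y)


@dataclass
class ModelParams:
    """One point in parameter space (used by density functions and tests)."""

    beta: np.ndarray  # (J, K-1)
    city_int: np.ndarray  # (C, K-1)
    mu: np.ndarray  # (K-1,)
    tau: np.ndarray  # (K-1,)
    pi: float

    def __post_init__(self):
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        self.city_int = np.atleast_2d(np.asarray(self.city_int, dtype=float))
        self.mu = np.asarray(self.mu, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        if np.any(self.tau <= 0):
            raise ValueError("tau (precision) must be positive")

    @classmethod
    def null(cls, n_covariates: int, n_cities: int) -> "ModelParams":
        Km = N_CATEGORIES - 1
        return cls(
            beta=np.zeros((n_covariates, Km)),
            city_int=np.zeros((n_cities, Km)),
            mu=np.zeros(Km),
            tau=np.ones(Km),
            pi=1.0,
        )


@dataclass
class SamplerConfig:
    """MCMC protocol. Defaults reproduce the study protocol: 14 parallel
    chains, 20,000 burn-in iterations discarded, every 7th kept, for a
    total of 75,000 retained draws."""

    n_chains: int = 14
    burn_in: int = 20_000
    thin: int = 7
    kept_total: int = 75_000
    seed: int | None = None
    pi_bounds: tuple[float, float] = PI_BOUNDS

    def __post_init__(self):
        for name in ("n_chains", "burn_in", "thin", "kept_total"):
            if getattr(self, name) < 1 and name != "burn_in":
                raise ValueError(f"{name} must be a positive integer")
        if self.burn_in < 0:
            raise ValueError("burn_in must be non-negative")

    @property
    def kept_per_chain(self) -> int:
        # ceil division; kept_total need not divide evenly by n_chains
        return -(-self.kept_total // self.n_chains)

    @property
    def iterations_per_chain(self) -> int:
        return self.burn_in + self.kept_per_chain * self.thin


def log_linear_predictor(data: ModelData, params: ModelParams) -> np.ndarray:
    """The (I, K) matrix of log-linear scores lambda."""
    lam = np.empty((data.n_events, N_CATEGORIES))
    lam[:, 0] = data.log_alpha[:, 0]
    lam[:, 1:] = (
        data.X @ params.beta + params.city_int[data.city] + data.log_alpha[:, 1:]
    )
    if not np.all(np.isfinite(lam)):
        bad = int(np.argwhere(~np.isfinite(lam).all(axis=1))[0, 0])
        raise FloatingPointError(f"non-finite linear predictor at event row {bad}")
    return lam


def category_probabilities(lam: np.ndarray) -> np.ndarray:
    """Row-wise softmax of the log-linear scores (numerically stabilized)."""
    lam = np.asarray(lam, dtype=float)
    if not np.all(np.isfinite(lam)):
        raise ValueError("non-finite lambda")
    return softmax(lam, axis=-1)


def log_likelihood(data: ModelData, params: ModelParams) -> float:
    """Categorical log likelihood sum_i log phi_{i, y_i}."""
    lam = log_linear_predictor(data, params)
    logphi = log_softmax(lam, axis=1)
    ll = float(logphi[np.arange(data.n_events), data.y].sum())
    if not np.isfinite(ll):
        warnings.warn("zero category probability at an observed outcome", RuntimeWarning)
        return -np.inf
    return ll


def log_prior(params: ModelParams, pi_bounds: tuple[float, float] = PI_BOUNDS) -> float:
    """Joint log prior density at ``params`` (JAGS parameter conventions)."""
    lo, hi = pi_bounds
    if not (lo <= params.pi <= hi) or np.any(params.tau <= 0):
        return -np.inf
    pi = params.pi
    lp = np.sum(np.log(pi / 2.0) - pi * np.abs(params.beta))
    # city intercepts: Normal(mu_k, precision tau_k)
    resid = params.city_int - params.mu
    lp += np.sum(0.5 * np.log(params.tau / (2 * np.pi)) - 0.5 * params.tau * resid**2)
    # mu_k ~ Normal(0, variance 10)
    lp += np.sum(-0.5 * np.log(2 * np.pi * 10.0) - params.mu**2 / 20.0)
    # tau_k ~ Gamma(1, 1): log density = -tau
    lp += float(np.sum(-params.tau))
    lp += -np.log(hi - lo)
    return float(lp)


def gelman_rubin(draws: np.ndarray) -> np.ndarray | float:
    """Classic Gelman-Rubin potential scale reduction factor.

    ``draws`` has shape (chains, iterations) or (chains, iterations, P).
    Uses W = mean within-chain variance, B/n = variance of chain means, and
    Vhat = (n-1)/n W + B/n; R-hat = sqrt(Vhat / W). Returns NaN where all
    chains are constant (diagnostic undefined).
    """
    draws = np.asarray(draws, dtype=float)
    scalar = draws.ndim == 2
    if scalar:
        draws = draws[..., None]
    m, n = draws.shape[0], draws.shape[1]
    if m < 2 or n < 10:
        raise ValueError("need >=2 chains and >=10 iterations per chain")
    chain_means = draws.mean(axis=1)
    W = draws.var(axis=1, ddof=1).mean(axis=0)
    B_over_n = chain_means.var(axis=0, ddof=1)
    vhat = (n - 1) / n * W + B_over_n
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(vhat / W)
    rhat = np.where(W == 0, np.nan, rhat)
    return float(rhat[0]) if scalar else rhat


@dataclass
class PosteriorSamples:
    """MCMC draws with chain/draw dimensions, metadata, and diagnostics."""

    beta: np.ndarray  # (chains, draws, J, K-1)
    city_int: np.ndarray  # (chains, draws, C, K-1)
    mu: np.ndarray  # (chains, draws, K-1)
    tau: np.ndarray  # (chains, draws, K-1)
    pi: np.ndarray  # (chains, draws)
    seed: int | None
    config: dict
    rhat: dict = field(default_factory=dict)
    converged: bool = True

    PARAM_NAMES = ("beta", "city_int", "mu", "tau", "pi")

    @property
    def n_chains(self) -> int:
        return self.beta.shape[0]

    @property
    def n_draws_per_chain(self) -> int:
        return self.beta.shape[1]

    def flat(self, name: str) -> np.ndarray:
        """Draws with the chain dimension collapsed."""
        arr = getattr(self, name)
        return arr.reshape((-1,) + arr.shape[2:])

    def max_rhat(self) -> float:
        vals = [np.nanmax(v) for v in self.rhat.values() if np.size(v)]
        return float(np.nanmax(vals)) if vals else float("nan")

    def split_rhat(self) -> dict:
        """Rank-normalized split-R-hat per parameter block (via ArviZ)."""
        import arviz as az

        out = {}
        for name in self.PARAM_NAMES:
            ds = az.convert_to_dataset({name: getattr(self, name)})
            out[name] = az.rhat(ds)[name].to_numpy()
        return out

    def save(self, path) -> None:
        meta = json.dumps({"seed": self.seed, "config": self.config, "converged": bool(self.converged)})
        np.savez(
            path,
            beta=self.beta,
            city_int=self.city_int,
            mu=self.mu,
            tau=self.tau,
            pi=self.pi,
            meta=np.array(meta),
            **{f"rhat_{k}": np.asarray(v) for k, v in self.rhat.items()},
        )

    @classmethod
    def load(cls, path) -> "PosteriorSamples":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            rhat = {k[5:]: z[k] for k in z.files if k.startswith("rhat_")}
            return cls(
                beta=z["beta"],
                city_int=z["city_int"],
                mu=z["mu"],
                tau=z["tau"],
                pi=z["pi"],
                seed=meta["seed"],
                config=meta["config"],
                rhat=rhat,
                converged=meta["converged"],
            )


def _chain_seeds(seed: int | None, n_chains: int) -> np.ndarray:
    ss = np.random.SeedSequence(seed)
    return (ss.generate_state(n_chains, dtype=np.uint64) % np.uint64(2**31 - 1)).astype(
        np.int64
    )


def sample_posterior(data: ModelData, config: SamplerConfig | None = None) -> PosteriorSamples:
    """Draw from the posterior of the selection model by MCMC.

    Runs ``config.n_chains`` independent adaptive chains (deterministic
    per-chain seeds derived from ``config.seed``), discards the burn-in,
    thins, and reports the classic Gelman-Rubin R-hat per parameter. A
    value >= 1.1 anywhere flags the result as non-converged (with a
    warning) but the draws are still returned.
    """
    if config is None:
        config = SamplerConfig()
    observed = data.observed_categories()
    if len(observed) < 2:
        raise ValueError("degenerate data: fewer than 2 diel categories observed")
    empty = sorted(set(range(N_CATEGORIES)) - set(observed.tolist()))
    if empty:
        warnings.warn(
            f"no events observed in categories {[CATEGORIES[k] for k in empty]}; "
            "their parameters are prior-dominated",
            UserWarning,
        )

    J, C, Km = data.n_covariates, data.n_cities, N_CATEGORIES - 1
    n_keep = config.kept_per_chain
    seeds = _chain_seeds(config.seed, config.n_chains)
    chains = np.empty((config.n_chains, n_keep, J * Km + C * Km + 2 * Km + 1))
    for ci in range(config.n_chains):
        chains[ci] = run_chain(
            data.X,
            data.y,
            data.log_alpha,
            data.city,
            C,
            config.iterations_per_chain,
            config.burn_in,
            config.thin,
            n_keep,
            int(seeds[ci]),
            config.pi_bounds[0],
            config.pi_bounds[1],
        )

    p = 0
    beta = chains[:, :, p : p + J * Km].reshape(config.n_chains, n_keep, J, Km)
    p += J * Km
    city_int = chains[:, :, p : p + C * Km].reshape(config.n_chains, n_keep, C, Km)
    p += C * Km
    mu = chains[:, :, p : p + Km]
    p += Km
    tau = chains[:, :, p : p + Km]
    p += Km
    pi = chains[:, :, p]

    rhat = {
        "beta": gelman_rubin(beta.reshape(config.n_chains, n_keep, -1)).reshape(J, Km),
        "city_int": gelman_rubin(city_int.reshape(config.n_chains, n_keep, -1)).reshape(C, Km),
        "mu": gelman_rubin(mu),
        "tau": gelman_rubin(tau),
        "pi": gelman_rubin(pi[:, :, None])[0],
    }
    max_rhat = float(np.nanmax([np.nanmax(v) for v in rhat.values()]))
    converged = bool(max_rhat < 1.1)
    if not converged:
        warnings.warn(
            f"Gelman-Rubin diagnostic >= 1.1 for some parameters (max {max_rhat:.3f}); "
            "treat estimates with caution",
            ConvergenceWarning,
        )
    return PosteriorSamples(
        beta=beta,
        city_int=city_int,
        mu=mu,
        tau=tau,
        pi=pi,
        seed=config.seed,
        config={
            "n_chains": config.n_chains,
            "burn_in": config.burn_in,
            "thin": config.thin,
            "kept_total": config.kept_total,
        },
        rhat=rhat,
        converged=converged,
    )


class TemporalRSF(BaseEstimator):
    """sklearn-style front end to the temporal resource-selection model.

    Parameters mirror :class:`SamplerConfig`; defaults are the full study
    protocol, so pass reduced settings for interactive use. ``fit`` expects
    the design matrix ``X`` (events x scaled covariates), the category code
    vector ``y`` (0 = day reference), and keyword arrays ``log_alpha``
    (events x 5 log availability hours) and ``city`` (city codes).

    Fitted attributes: ``samples_`` (:class:`PosteriorSamples`), ``rhat_``,
    ``converged_``, ``n_features_in_``, ``n_cities_``.
    """

    def __init__(
        self,
        n_chains: int = 14,
        burn_in: int = 20_000,
        thin: int = 7,
        kept_total: int = 75_000,
        seed: int | None = None,
        pi_bounds: tuple[float, float] = PI_BOUNDS,
    ):
        self.n_chains = n_chains
        self.burn_in = burn_in
        self.thin = thin
        self.kept_total = kept_total
        self.seed = seed
        self.pi_bounds = pi_bounds

    def _config(self) -> SamplerConfig:
        return SamplerConfig(
            n_chains=self.n_chains,
            burn_in=self.burn_in,
            thin=self.thin,
            kept_total=self.kept_total,
            seed=self.seed,
            pi_bounds=self.pi_bounds,
        )

    def fit(self, X, y, *, log_alpha, city, n_cities=None):
        data = ModelData(X=X, y=y, log_alpha=log_alpha, city=city, n_cities=n_cities)
        self.data_ = data
        self.samples_ = sample_posterior(data, self._config())
        self.rhat_ = self.samples_.rhat
        self.converged_ = self.samples_.converged
        self.n_features_in_ = data.n_covariates
        self.n_cities_ = data.n_cities
        return self

    def _check_fitted(self):
        if not hasattr(self, "samples_"):
            raise RuntimeError("TemporalRSF is not fitted; call fit first")

    def predict_proba(self, X, *, log_alpha, city=None) -> np.ndarray:
        """Posterior-mean category probabilities for new events.

        With ``city=None`` the population-level intercept draws (mu_k) are
        used; otherwise the given city's random-intercept draws.
        """
        self._check_fitted()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        log_alpha = np.atleast_2d(np.asarray(log_alpha, dtype=float))
        beta = self.samples_.flat("beta")  # (n, J, Km)
        if city is None:
            inter = self.samples_.flat("mu")  # (n, Km)
        else:
            inter = self.samples_.flat("city_int")[:, int(city), :]
        lam = np.empty((beta.shape[0], X.shape[0], N_CATEGORIES))
        lam[:, :, 0] = log_alpha[:, 0]
        lam[:, :, 1:] = (
            np.einsum("ij,njk->nik", X, beta) + inter[:, None, :] + log_alpha[None, :, 1:]
        )
        return softmax(lam, axis=-1).mean(axis=0)

    def predict(self, X, *, log_alpha, city=None) -> np.ndarray:
        """Most probable diel category per event (names from CATEGORIES)."""
        phi = self.predict_proba(X, log_alpha=log_alpha, city=city)
        return np.asarray(CATEGORIES)[np.argmax(phi, axis=1)]
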