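"""Model densities against independent oracles; sampler and diagnostics."""

import math
import warnings

import numpy as np
import pytest
from scipy import stats

from dieltrsf import (
    ModelData,
    ModelParams,
    SamplerConfig,
    TemporalRSF,
    category_probabilities,
    gelman_rubin,
    log_likelihood,
    log_linear_predictor,
    log_prior,
    sample_posterior,
)
from dieltrsf.model import PosteriorSamples

from conftest import random_model_data


# ---------------------------------------------------------------- densities
def brute_force_loglik(data: ModelData, params: ModelParams) -> float:
    """Independent elementwise evaluation with pure-python loops."""
    total = 0.0
    for i in range(data.n_events):
        lam = []
        for k in range(5):
            if k == 0:
                lam.append(data.log_alpha[i, 0])
            else:
                s = sum(data.X[i, j] * params.beta[j, k - 1] for j in range(data.n_covariates))
                lam.append(s + params.city_int[data.city[i], k - 1] + data.log_alpha[i, k])
        denom = sum(math.exp(l) for l in lam)
        total += math.log(math.exp(lam[data.y[i]]) / denom)
    return total


def test_predictor_null_effects_equals_log_alpha(small_data):
    params = ModelParams.null(small_data.n_covariates, small_data.n_cities)
    lam = log_linear_predictor(small_data, params)
    assert np.allclose(lam, small_data.log_alpha)


def test_predictor_single_event_substitution():
    data = ModelData(
        X=[[1.0]], y=[0], log_alpha=np.zeros((1, 5)), city=[0], n_cities=1
    )
    beta = np.zeros((1, 4))
    beta[0, 0] = 0.5  # effect on the first non-reference category
    params = ModelParams(beta=beta, city_int=np.zeros((1, 4)), mu=np.zeros(4), tau=np.ones(4), pi=1.0)
    lam = log_linear_predictor(data, params)
    assert lam[0, 0] == 0.0
    assert lam[0, 1] == pytest.approx(0.5)
    assert np.allclose(lam[0, 2:], 0.0)


def test_predictor_matches_naive_loop(rng):
    data = random_model_data(rng, n_events=12, n_covariates=3, n_cities=3)
    params = ModelParams(
        beta=rng.normal(0, 1, (3, 4)),
        city_int=rng.normal(0, 1, (3, 4)),
        mu=np.zeros(4),
        tau=np.ones(4),
        pi=1.0,
    )
    lam = log_linear_predictor(data, params)
    for i in range(data.n_events):
        for k in range(5):
            if k == 0:
                expected = data.log_alpha[i, 0]
            else:
                expected = (
                    data.X[i] @ params.beta[:, k - 1]
                    + params.city_int[data.city[i], k - 1]
                    + data.log_alpha[i, k]
                )
            assert lam[i, k] == pytest.approx(expected, rel=1e-12)


def test_softmax_properties(rng):
    lam = rng.normal(0, 3, (40, 5))
    phi = category_probabilities(lam)
    assert np.all(np.abs(phi.sum(axis=1) - 1.0) < 1e-12)
    assert np.allclose(category_probabilities(lam + 7.3), phi)  # shift invariance
    assert np.allclose(category_probabilities(np.zeros((1, 5))), 0.2)


def test_null_model_probabilities_proportional_to_availability(rng):
    data = random_model_data(rng, n_events=15)
    params = ModelParams.null(data.n_covariates, data.n_cities)
    phi = category_probabilities(log_linear_predictor(data, params))
    alpha = np.exp(data.log_alpha)
    assert np.allclose(phi, alpha / alpha.sum(axis=1, keepdims=True), atol=1e-12)


def test_loglik_uniform_and_additive():
    one = ModelData(X=np.zeros((1, 1)), y=[2], log_alpha=np.zeros((1, 5)), city=[0], n_cities=1)
    params = ModelParams.null(1, 1)
    assert log_likelihood(one, params) == pytest.approx(math.log(0.2), abs=1e-12)
    two = ModelData(
        X=np.zeros((2, 1)), y=[2, 2], log_alpha=np.zeros((2, 5)), city=[0, 0], n_cities=1
    )
    assert log_likelihood(two, params) == pytest.approx(2 * math.log(0.2), abs=1e-12)


def test_loglik_matches_brute_force_on_random_instances(rng):
    for _ in range(20):
        n = int(rng.integers(1, 11))
        data = random_model_data(rng, n_events=n, n_covariates=2, n_cities=2)
        params = ModelParams(
            beta=rng.normal(0, 1, (2, 4)),
            city_int=rng.normal(0, 0.5, (2, 4)),
            mu=np.zeros(4),
            tau=np.ones(4),
            pi=1.0,
        )
        assert log_likelihood(data, params) == pytest.approx(
            brute_force_loglik(data, params), abs=1e-10
        )


def test_likelihood_invariant_to_constant_row_shift(rng):
    """Adding any constant to every category score of an event leaves the
    category probabilities unchanged (reference-category identification)."""
    lam = rng.normal(0, 1, (6, 5))
    shift = rng.normal(0, 10, (6, 1))
    assert np.allclose(category_probabilities(lam), category_probabilities(lam + shift))


def test_log_prior_examples_and_oracle(rng):
    params = ModelParams(
        beta=np.zeros((2, 4)),
        city_int=np.zeros((1, 4)),
        mu=np.zeros(4),
        tau=np.ones(4),
        pi=2.0,
    )
    base = log_prior(params)
    # each beta at the Laplace mode contributes log(pi/2)
    p2 = ModelParams(
        beta=np.full((2, 4), 0.0), city_int=np.zeros((1, 4)), mu=np.zeros(4), tau=np.ones(4), pi=2.0
    )
    p2.beta[0, 0] = 1.0
    assert log_prior(p2) == pytest.approx(base - 2.0 * 1.0)  # rate * |beta|
    p2.beta[0, 0] = 2.0
    assert log_prior(p2) == pytest.approx(base - 2.0 * 2.0)

    # term-by-term against scipy.stats
    params = ModelParams(
        beta=rng.normal(0, 1, (2, 4)),
        city_int=rng.normal(0, 1, (3, 4)),
        mu=rng.normal(0, 1, 4),
        tau=rng.uniform(0.5, 2.0, 4),
        pi=1.7,
    )
    expected = (
        stats.laplace.logpdf(params.beta, scale=1 / params.pi).sum()
        + stats.norm.logpdf(params.city_int, loc=params.mu, scale=1 / np.sqrt(params.tau)).sum()
        + stats.norm.logpdf(params.mu, scale=math.sqrt(10.0)).sum()
        + stats.gamma.logpdf(params.tau, a=1.0, scale=1.0).sum()
        + stats.uniform.logpdf(params.pi, loc=0.001, scale=9.999)
    )
    assert log_prior(params) == pytest.approx(expected, rel=1e-10)


def test_log_prior_out_of_support():
    params = ModelParams(
        beta=np.zeros((1, 4)), city_int=np.zeros((1, 4)), mu=np.zeros(4), tau=np.ones(4), pi=50.0
    )
    assert log_prior(params) == -np.inf
    with pytest.raises(ValueError, match="tau"):
        ModelParams(
            beta=np.zeros((1, 4)), city_int=np.zeros((1, 4)), mu=np.zeros(4), tau=np.zeros(4), pi=1.0
        )


def test_shrinkage_mode_moves_toward_zero_with_pi(rng):
    """On a 1-covariate toy problem the penalized posterior mode of beta
    shrinks toward zero as the Laplace rate grows (grid-search oracle)."""
    data = random_model_data(rng, n_events=60, n_covariates=1, n_cities=1)
    # induce a real effect so the unpenalized mode is away from zero
    strong = ModelParams(
        beta=np.array([[1.2, 0.0, 0.0, 0.0]]),
        city_int=np.zeros((1, 4)),
        mu=np.zeros(4),
        tau=np.ones(4),
        pi=1.0,
    )
    phi = category_probabilities(log_linear_predictor(data, strong))
    y = np.array([rng.choice(5, p=p) for p in phi])
    data = ModelData(X=data.X, y=y, log_alpha=data.log_alpha, city=data.city, n_cities=1)

    grid = np.linspace(-2.0, 2.0, 401)
    modes = []
    for pi in (0.5, 3.0, 9.0):
        objective = []
        for b in grid:
            p = ModelParams(
                beta=np.array([[b, 0.0, 0.0, 0.0]]),
                city_int=np.zeros((1, 4)),
                mu=np.zeros(4),
                tau=np.ones(4),
                pi=pi,
            )
            objective.append(log_likelihood(data, p) - pi * abs(b))
        modes.append(abs(grid[int(np.argmax(objective))]))
    assert modes[0] >= modes[1] >= modes[2]


# ---------------------------------------------------------------- diagnostics
def test_gelman_rubin_hand_example():
    """2 chains x 12 draws (pattern 1,2,3,4 vs 3,4,5,6 repeated), computed by
    hand: chain means 2.5 and 4.5, W = 15/11, B/n = 2, Vhat = 11/12*W + 2 =
    3.25, R-hat = sqrt(3.25 * 11/15) = sqrt(143/60)."""
    short = np.array([[1.0, 2.0, 3.0, 4.0], [3.0, 4.0, 5.0, 6.0]])
    with pytest.raises(ValueError):
        gelman_rubin(short)  # too short by contract (>=10 iterations)
    draws = np.tile(short, (1, 3))
    assert gelman_rubin(draws) == pytest.approx(math.sqrt(143.0 / 60.0), rel=1e-12)


def test_gelman_rubin_same_vs_separated_chains(rng):
    same = rng.normal(0, 1, (4, 2000))
    assert gelman_rubin(same) < 1.1
    apart = np.stack([rng.normal(0, 1, 500), rng.normal(10, 1, 500)])
    assert gelman_rubin(apart) > 3.0
    flat = np.ones((2, 50))
    assert math.isnan(gelman_rubin(flat))


# ---------------------------------------------------------------- sampler
@pytest.fixture(scope="module")
def tiny_fit():
    rng = np.random.default_rng(11)
    n = 400
    alpha = np.tile([11.0, 1.2, 1.2, 8.6, 2.0], (n, 1))
    X = rng.normal(0, 1, (n, 2))
    truth = np.array([[0.8, 0.0, -0.5, 0.0], [0.0, 0.6, 0.0, 0.0]])
    lam = np.log(alpha)
    lam[:, 1:] += X @ truth
    phi = np.exp(lam - lam.max(axis=1, keepdims=True))
    phi /= phi.sum(axis=1, keepdims=True)
    y = np.array([rng.choice(5, p=p) for p in phi])
    data = ModelData(X=X, y=y, log_alpha=np.log(alpha), city=np.zeros(n, dtype=int), n_cities=1)
    config = SamplerConfig(n_chains=3, burn_in=800, thin=1, kept_total=1800, seed=5)
    return data, truth, sample_posterior(data, config), config


def test_sampler_shapes_and_metadata(tiny_fit):
    data, truth, samples, config = tiny_fit
    assert samples.beta.shape == (3, 600, 2, 4)
    assert samples.city_int.shape == (3, 600, 1, 4)
    assert samples.pi.shape == (3, 600)
    assert samples.flat("beta").shape == (1800, 2, 4)
    assert samples.config["burn_in"] == 800
    assert np.isfinite(samples.max_rhat())
    assert set(samples.rhat) == {"beta", "city_int", "mu", "tau", "pi"}
    assert np.all(samples.flat("tau") > 0)
    lo, hi = config.pi_bounds
    assert np.all((samples.flat("pi") >= lo) & (samples.flat("pi") <= hi))


def test_sampler_recovers_strong_effects(tiny_fit):
    data, truth, samples, _ = tiny_fit
    flat = samples.flat("beta")
    med = np.median(flat, axis=0)
    # strong true effects keep their sign and rough size
    assert med[0, 0] > 0.3 and med[0, 2] < -0.1 and med[1, 1] > 0.2
    lo = np.quantile(flat, 0.025, axis=0)
    hi = np.quantile(flat, 0.975, axis=0)
    assert ((lo <= truth) & (truth <= hi)).mean() >= 0.75


def test_sampler_deterministic_under_seed(tiny_fit):
    data, _, samples, config = tiny_fit
    again = sample_posterior(data, config)
    assert np.array_equal(again.beta, samples.beta)
    assert np.array_equal(again.pi, samples.pi)


def test_sampler_save_load_roundtrip(tmp_path, tiny_fit):
    _, _, samples, _ = tiny_fit
    path = tmp_path / "posterior.npz"
    samples.save(path)
    loaded = PosteriorSamples.load(path)
    assert np.array_equal(loaded.beta, samples.beta)
    assert loaded.config == samples.config
    assert loaded.converged == samples.converged


def test_sampler_default_config_is_study_protocol():
    config = SamplerConfig()
    assert config.n_chains == 14
    assert config.burn_in == 20_000
    assert config.thin == 7
    assert config.kept_total == 75_000


def test_sampler_degenerate_and_empty_category_warnings(rng):
    alpha = np.ones((30, 5))
    one_cat = ModelData(
        X=rng.normal(0, 1, (30, 1)), y=np.zeros(30, dtype=int), log_alpha=np.log(alpha),
        city=np.zeros(30, dtype=int), n_cities=1,
    )
    with pytest.raises(ValueError, match="degenerate"):
        sample_posterior(one_cat, SamplerConfig(n_chains=2, burn_in=20, thin=1, kept_total=40, seed=0))
    # a missing category warns but still runs, prior-dominated
    y = rng.integers(0, 4, 30)  # never deep_night
    some = ModelData(
        X=rng.normal(0, 1, (30, 1)), y=y, log_alpha=np.log(alpha),
        city=np.zeros(30, dtype=int), n_cities=1,
    )
    with pytest.warns(UserWarning, match="deep_night"):
        samples = sample_posterior(
            some, SamplerConfig(n_chains=2, burn_in=50, thin=1, kept_total=40, seed=0)
        )
    assert samples.beta.shape[2:] == (1, 4)


def test_estimator_interface(tiny_fit):
    from sklearn.base import clone

    data, _, _, _ = tiny_fit
    est = TemporalRSF(n_chains=2, burn_in=300, thin=1, kept_total=600, seed=9)
    cloned = clone(est)
    assert cloned.get_params() == est.get_params()
    with pytest.raises(RuntimeError, match="not fitted"):
        est.predict_proba(data.X[:2], log_alpha=data.log_alpha[:2])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(data.X, data.y, log_alpha=data.log_alpha, city=data.city)
    assert est.n_features_in_ == 2
    assert est.n_cities_ == 1
    phi = est.predict_proba(data.X[:5], log_alpha=data.log_alpha[:5], city=0)
    assert phi.shape == (5, 5)
    assert np.allclose(phi.sum(axis=1), 1.0)
    labels = est.predict(data.X[:5], log_alpha=data.log_alpha[:5])
    assert set(labels) <= {"day", "dawn", "dusk", "night", "deep_night"}
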