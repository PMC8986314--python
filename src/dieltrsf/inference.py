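"""Posterior summaries: activity profiles, nocturnality, odds ratios.

All quantities are computed per posterior draw through the same softmax
code path as the model, then summarized by the median and the central
(equal-tailed) 95% credible interval. "Nocturnality" is the combined
probability of activity in the night and deep-night categories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import softmax

from .diel import CATEGORIES
from .model import N_CATEGORIES, PosteriorSamples

__all__ = [
    "ActivityProfile",
    "OddsRatioEstimate",
    "predict_activity",
    "nocturnal_probability",
    "odds_ratio",
    "odds_ratio_table",
    "city_activity_summary",
    "site_activity_table",
    "plot_activity_profiles",
]

_NIGHT_IDX = CATEGORIES.index("night")
_DEEP_IDX = CATEGORIES.index("deep_night")


@dataclass
class ActivityProfile:
    """Median and 95% CrI of the per-category activity probabilities."""

    median: np.ndarray  # (K,)
    lower: np.ndarray
    upper: np.ndarray
    level: str = "population"

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"category": CATEGORIES, "median": self.median, "lower": self.lower, "upper": self.upper}
        )


@dataclass
class OddsRatioEstimate:
    """Odds ratio of nocturnality for a +shift_sd change in one covariate."""

    covariate: int | str
    shift_sd: float
    median: float
    lower: float
    upper: float
    excludes_one: bool
    n_excluded_draws: int = 0


def _phi_draws(samples: PosteriorSamples, x: np.ndarray, alpha: np.ndarray, city, rng=None) -> np.ndarray:
    """Per-draw category probabilities at one covariate/availability setting.

    ``city=None`` -> population-level intercepts (mu_k draws);
    ``city="new"`` -> a new city drawn per posterior draw from
    Normal(mu_k, precision tau_k), needs ``rng``; an integer selects that
    city's random intercept.
    """
    x = np.asarray(x, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if alpha.shape != (N_CATEGORIES,):
        raise ValueError(f"alpha must have length {N_CATEGORIES}")
    if np.any(alpha <= 0):
        raise ValueError("availabilities must be strictly positive")
    beta = samples.flat("beta")  # (n, J, Km)
    if x.shape != (beta.shape[1],):
        raise ValueError(f"x must have length {beta.shape[1]}")
    if city is None:
        inter = samples.flat("mu")
    elif city == "new":
        if rng is None:
            rng = np.random.default_rng()
        mu = samples.flat("mu")
        tau = samples.flat("tau")
        inter = mu + rng.standard_normal(mu.shape) / np.sqrt(tau)
    else:
        city_int = samples.flat("city_int")
        c = int(city)
        if not 0 <= c < city_int.shape[1]:
            raise ValueError(f"unknown city index {city}")
        inter = city_int[:, c, :]
    lam = np.empty((beta.shape[0], N_CATEGORIES))
    lam[:, 0] = np.log(alpha[0])
    lam[:, 1:] = x @ beta + inter + np.log(alpha[1:])
    return softmax(lam, axis=1)


def predict_activity(
    samples: PosteriorSamples,
    x: np.ndarray,
    alpha: np.ndarray,
    city=None,
    rng=None,
) -> tuple[np.ndarray, ActivityProfile]:
    """Per-draw probabilities and their summary at a covariate setting."""
    phi = _phi_draws(samples, x, alpha, city, rng)
    lo, med, hi = np.quantile(phi, [0.025, 0.5, 0.975], axis=0)
    level = "population" if city is None else str(city)
    return phi, ActivityProfile(median=med, lower=lo, upper=hi, level=level)


def nocturnal_probability(phi: np.ndarray) -> np.ndarray:
    """Night + deep-night probability, per draw (or per row)."""
    phi = np.asarray(phi, dtype=float)
    return phi[..., _NIGHT_IDX] + phi[..., _DEEP_IDX]


def odds_ratio(
    samples: PosteriorSamples,
    covariate: int,
    shift_sd: float,
    alpha: np.ndarray,
    reference_x: np.ndarray | None = None,
    city=None,
    name: str | None = None,
) -> OddsRatioEstimate:
    """Odds ratio of nocturnal use for a +shift_sd covariate change.

    Per draw: p0 = nocturnality at the reference covariates (all zero on
    the centered scale unless given), p1 = the same with covariate j raised
    by ``shift_sd`` global SDs; OR = [p1/(1-p1)] / [p0/(1-p0)]. Draws where
    either probability is numerically 0 or 1 are excluded and counted.
    """
    J = samples.beta.shape[2]
    if not 0 <= covariate < J:
        raise ValueError(f"covariate index {covariate} outside 0..{J - 1}")
    x0 = np.zeros(J) if reference_x is None else np.asarray(reference_x, dtype=float).copy()
    x1 = x0.copy()
    x1[covariate] += shift_sd
    p0 = nocturnal_probability(_phi_draws(samples, x0, alpha, city))
    p1 = nocturnal_probability(_phi_draws(samples, x1, alpha, city))
    eps = np.finfo(float).tiny
    good = (p0 > eps) & (p0 < 1 - 1e-15) & (p1 > eps) & (p1 < 1 - 1e-15)
    n_bad = int((~good).sum())
    orr = (p1[good] / (1 - p1[good])) / (p0[good] / (1 - p0[good]))
    lo, med, hi = np.quantile(orr, [0.025, 0.5, 0.975])
    return OddsRatioEstimate(
        covariate=name if name is not None else covariate,
        shift_sd=shift_sd,
        median=float(med),
        lower=float(lo),
        upper=float(hi),
        excludes_one=bool(lo > 1.0 or hi < 1.0),
        n_excluded_draws=n_bad,
    )


def odds_ratio_table(
    samples: PosteriorSamples,
    alpha: np.ndarray,
    covariate_names: list[str] | None = None,
    shifts=(1.0, 2.0),
    city=None,
) -> pd.DataFrame:
    """Odds ratios for every covariate and each SD shift (Table-2 layout)."""
    J = samples.beta.shape[2]
    names = covariate_names or [f"x{j}" for j in range(J)]
    rows = []
    for j, nm in enumerate(names):
        for s in shifts:
            est = odds_ratio(samples, j, s, alpha, city=city, name=nm)
            rows.append(
                {
                    "covariate": nm,
                    "shift_sd": s,
                    "or_median": est.median,
                    "or_lower": est.lower,
                    "or_upper": est.upper,
                    "excludes_one": est.excludes_one,
                }
            )
    return pd.DataFrame(rows)


def city_activity_summary(
    samples: PosteriorSamples,
    alpha: np.ndarray,
    x: np.ndarray | None = None,
    rng=None,
) -> dict:
    """Per-city activity profiles plus the among-city summary.

    The among-city entry integrates over the city distribution by drawing a
    fresh intercept from Normal(mu_k, precision tau_k) per posterior draw,
    so its interval widens as the among-city precision tau_k falls.
    """
    J = samples.beta.shape[2]
    x = np.zeros(J) if x is None else np.asarray(x, dtype=float)
    C = samples.city_int.shape[2]
    out = {}
    for c in range(C):
        _, out[c] = predict_activity(samples, x, alpha, city=c)
    if rng is None:
        rng = np.random.default_rng(0)
    _, out["among_cities"] = predict_activity(samples, x, alpha, city="new", rng=rng)
    return out


def site_activity_table(
    samples: PosteriorSamples,
    site_covariates: pd.DataFrame,
    alpha: np.ndarray,
    covariate_columns: list[str],
    city_column: str | None = "city",
    site_column: str = "site_id",
) -> pd.DataFrame:
    """Per-site activity medians sorted from least to most nocturnal.

    ``site_covariates`` holds one row per site with scaled covariates (and
    optionally an integer city code column for the city intercept). Sites
    with missing covariates are excluded and listed in the ``excluded``
    attribute of the returned frame (``df.attrs['excluded']``).
    """
    cov = site_covariates.copy()
    bad = cov[covariate_columns].isna().any(axis=1)
    excluded = cov.loc[bad, site_column].tolist()
    cov = cov.loc[~bad]
    rows = []
    for row in cov.itertuples(index=False):
        x = np.array([getattr(row, c) for c in covariate_columns], dtype=float)
        city = getattr(row, city_column) if city_column and hasattr(row, city_column) else None
        phi, prof = predict_activity(samples, x, alpha, city=city)
        rec = {site_column: getattr(row, site_column)}
        rec.update({f"phi_{cat}": m for cat, m in zip(CATEGORIES, prof.median)})
        rec["nocturnality"] = float(np.median(nocturnal_probability(phi)))
        rows.append(rec)
    table = pd.DataFrame(rows).sort_values("nocturnality", kind="mergesort").reset_index(drop=True)
    table.attrs["excluded"] = excluded
    table.attrs["nocturnality_range"] = (
        (float(table["nocturnality"].min()), float(table["nocturnality"].max()))
        if len(table)
        else (np.nan, np.nan)
    )
    return table


def plot_activity_profiles(profiles: dict, ax=None):
    """Stacked-bar plot of per-group median activity probabilities."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    labels = list(profiles)
    bottoms = np.zeros(len(labels))
    for k, cat in enumerate(CATEGORIES):
        vals = np.array([profiles[g].median[k] for g in labels])
        ax.bar(range(len(labels)), vals, bottom=bottoms, label=cat)
        bottoms += vals
    ax.set_xticks(range(len(labels)))
    ax.set_xticklabels([str(l) for l in labels], rotation=45, ha="right")
    ax.set_ylabel("probability of activity")
    ax.legend()
    return ax
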