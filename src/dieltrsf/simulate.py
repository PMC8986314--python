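"""Synthetic multi-city camera-trap datasets with known ground truth.

The generator emulates the study design the model targets: 10 cities with
24-113 sites each (mean near 45), continental-US latitudes (30-48 N), a
Jan 2017 - Dec 2018 window, seasonal temperature cycles per city, and
detection events drawn from the selection model itself — a category from
the softmax of true coefficients plus the availability offset of the
event's actual diel schedule, a timestamp uniform within that category's
intervals, then a burst of photos within the 15-min grouping window. The
per-site-day event count is Poisson; the study has no abundance model, so
that rate is generator plumbing, not science.

Every output table carries the master seed in ``DataFrame.attrs``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as _date, timedelta

import numpy as np
import pandas as pd

from .covariates import GroupMeanScaler
from .diel import CATEGORIES, DielSchedule, GeoPoint, compute_schedule
from .events import ALPHA_COLUMNS
from .model import ModelData, SamplerConfig, sample_posterior

__all__ = [
    "SimulationTruth",
    "SimulatedDataset",
    "simulate_sites",
    "simulate_temperatures",
    "simulate_detections",
    "simulate",
    "build_model_data",
    "recovery_experiment",
    "recovery_truth",
    "null_calibration_truth",
]

N_K = len(CATEGORIES)
SITE_COVARIATES = ("greenspace", "impervious", "vegetation", "pop_density")


@dataclass
class SimulationTruth:
    """Ground-truth design and parameters for one simulated study."""

    n_cities: int = 10
    sites_per_city: tuple | None = None  # default: drawn, range 24-113, mean ~45
    start: _date = _date(2017, 1, 1)
    end: _date = _date(2018, 12, 31)
    # the study's city latitudes: Austin (30.3 N) to Madison (43.1 N); above
    # ~47 N the June astronomical night collapses into the deep-night window
    # and night availability hits zero, which the model forbids
    lat_range: tuple = (30.0, 44.0)
    lon_range: tuple = (-118.0, -75.0)
    site_covariates: tuple = SITE_COVARIATES
    use_temperature: bool = True
    beta: np.ndarray | None = None  # (J, K-1); None -> all zero
    city_intercept_mu: np.ndarray | None = None  # (K-1,)
    city_intercept_sd: float = 0.3
    # sites are placed along within-city urbanization gradients, so most
    # covariate variance is within cities, not between their means
    city_mean_sd: float = 0.5
    within_city_sd: float = 1.0
    temp_noise_sd: float = 2.0
    events_per_site_day: float = 0.25
    photos_per_event_mean: float = 1.5  # extra photos beyond the first, Poisson
    species: str = "sim_species"
    seed: int = 20170101

    def __post_init__(self):
        self.site_covariates = tuple(self.site_covariates)
        if self.sites_per_city is not None:
            self.sites_per_city = tuple(int(c) for c in self.sites_per_city)

    @property
    def n_covariates(self) -> int:
        return len(self.site_covariates) + (1 if self.use_temperature else 0)

    @property
    def covariate_names(self) -> tuple:
        return self.site_covariates + (("temperature",) if self.use_temperature else ())

    def true_beta(self) -> np.ndarray:
        if self.beta is None:
            return np.zeros((self.n_covariates, N_K - 1))
        beta = np.asarray(self.beta, dtype=float)
        if beta.shape != (self.n_covariates, N_K - 1):
            raise ValueError(f"beta must have shape ({self.n_covariates}, {N_K - 1})")
        return beta


@dataclass
class SimulatedDataset:
    truth: SimulationTruth
    sites: pd.DataFrame
    covariates: pd.DataFrame
    temperatures: pd.DataFrame
    photos: pd.DataFrame
    ledger: pd.DataFrame
    city_intercepts: np.ndarray


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def simulate_sites(truth: SimulationTruth, rng=None):
    """Draw the site network and raw site covariates.

    Covariates get city-specific means and a shared within-city spread, so
    sites within a city cluster — the urbanization-gradient structure the
    scaling step (city-mean centering, global SD) is designed for.
    """
    rng = _rng(truth.seed if rng is None else rng)
    if truth.sites_per_city is not None:
        counts = list(truth.sites_per_city)
        if len(counts) != truth.n_cities:
            raise ValueError("sites_per_city length must equal n_cities")
    else:
        # 24 + Poisson(21.3), clipped at 113: range 24-113, mean ~45.3
        counts = (24 + rng.poisson(21.3, truth.n_cities)).clip(max=113).tolist()

    lat0, lat1 = truth.lat_range
    lon0, lon1 = truth.lon_range
    city_lat = rng.uniform(lat0 + 0.5, lat1 - 0.5, truth.n_cities)
    city_lon = rng.uniform(lon0 + 0.5, lon1 - 0.5, truth.n_cities)
    cov_city_means = rng.normal(0.0, truth.city_mean_sd, (truth.n_cities, len(truth.site_covariates)))

    site_rows, cov_rows = [], []
    for c in range(truth.n_cities):
        for s in range(counts[c]):
            sid = f"C{c:02d}S{s:03d}"
            site_rows.append(
                {
                    "station_id": sid,
                    "site_id": sid,
                    "city_id": f"city{c:02d}",
                    "lat": float(np.clip(city_lat[c] + rng.normal(0, 0.15), lat0, lat1)),
                    "lon": float(np.clip(city_lon[c] + rng.normal(0, 0.15), lon0, lon1)),
                    "tz": "UTC",
                }
            )
            vals = cov_city_means[c] + rng.normal(0.0, truth.within_city_sd, len(truth.site_covariates))
            cov_rows.append(
                {"site_id": sid, "city_id": f"city{c:02d}", **dict(zip(truth.site_covariates, vals))}
            )
    sites = pd.DataFrame(site_rows)
    covariates = pd.DataFrame(cov_rows)
    sites.attrs["seed"] = covariates.attrs["seed"] = truth.seed
    return sites, covariates


def simulate_temperatures(truth: SimulationTruth, rng=None) -> pd.DataFrame:
    """Daily mean temperature per city: sinusoidal season plus noise."""
    rng = _rng(truth.seed + 1 if rng is None else rng)
    dates = pd.date_range(truth.start, truth.end, freq="D")
    doy = dates.dayofyear.to_numpy()
    rows = []
    for c in range(truth.n_cities):
        mean = rng.uniform(6.0, 20.0)
        amp = rng.uniform(8.0, 14.0)
        tavg = (
            mean
            - amp * np.cos(2 * np.pi * (doy - 15) / 365.25)
            + rng.normal(0.0, truth.temp_noise_sd, len(dates))
        )
        rows.append(
            pd.DataFrame({"city_id": f"city{c:02d}", "date": dates.date, "tavg_c": tavg})
        )
    out = pd.concat(rows, ignore_index=True)
    out.attrs["seed"] = truth.seed
    return out


def _draw_time_in_category(schedule: DielSchedule, category: str, rng) -> pd.Timestamp:
    """Uniform instant within the category's (possibly split) intervals."""
    intervals = [(s, e) for cat, s, e in schedule.boundaries if cat == category and e > s]
    lengths = np.array([(e - s).total_seconds() for s, e in intervals])
    idx = rng.choice(len(intervals), p=lengths / lengths.sum())
    s, e = intervals[idx]
    return pd.Timestamp(s + timedelta(seconds=float(rng.uniform(0, lengths[idx]))))


def simulate_detections(
    truth: SimulationTruth,
    sites: pd.DataFrame,
    covariates: pd.DataFrame,
    temperatures: pd.DataFrame | None = None,
    rng=None,
):
    """Generate photo records and the true-event ledger.

    For each site-day the event count is Poisson; each event draws its
    category from the model's softmax probabilities (true coefficients,
    that cycle's availabilities) and a timestamp uniform within the
    category's intervals, then becomes a photo burst. Events closer than
    the 15-min grouping window to their predecessor at the same station are
    discarded so event deduplication recovers the ledger exactly.

    Returns (photos, ledger, city_intercepts).
    """
    rng = _rng(truth.seed + 2 if rng is None else rng)
    if truth.use_temperature and temperatures is None:
        raise ValueError("temperature table required when use_temperature is set")

    beta = truth.true_beta()
    mu = (
        np.zeros(N_K - 1)
        if truth.city_intercept_mu is None
        else np.asarray(truth.city_intercept_mu, dtype=float)
    )
    city_ids = sorted(sites["city_id"].unique())
    b_city = mu + rng.normal(0.0, truth.city_intercept_sd, (len(city_ids), N_K - 1))
    city_code = {cid: k for k, cid in enumerate(city_ids)}

    scaler = GroupMeanScaler(columns=list(truth.site_covariates))
    scaled_cov = scaler.fit_transform(covariates).set_index("site_id")

    if truth.use_temperature:
        temp = temperatures.copy()
        temp["date"] = pd.to_datetime(temp["date"]).dt.date
        tmean = temp.groupby("city_id")["tavg_c"].transform("mean")
        tsd = temp["tavg_c"].std(ddof=1)
        temp["temp_scaled"] = (temp["tavg_c"] - tmean) / tsd
        temp_lookup = temp.set_index(["city_id", "date"])

    dates = pd.date_range(truth.start, truth.end, freq="D").date
    window = timedelta(minutes=15)

    photo_rows, ledger_rows = [], []
    event_id = 0
    for srow in sites.itertuples(index=False):
        point = GeoPoint(srow.lat, srow.lon, srow.tz)
        ccode = city_code[srow.city_id]
        x_site = scaled_cov.loc[srow.site_id, list(truth.site_covariates)].to_numpy(dtype=float)
        last_photo_time = None
        for day in dates:
            n_events = rng.poisson(truth.events_per_site_day)
            if n_events == 0:
                continue
            schedule = compute_schedule(day, point)
            alpha = np.array(schedule.alpha_vector())
            if truth.use_temperature:
                trow = temp_lookup.loc[(srow.city_id, day)]
                x = np.concatenate([x_site, [float(trow["temp_scaled"])]])
                tavg = float(trow["tavg_c"])
            else:
                x = x_site
                tavg = np.nan
            lam = np.log(alpha)
            lam[1:] += x @ beta + b_city[ccode]
            lam -= lam.max()
            phi = np.exp(lam)
            phi /= phi.sum()
            drawn = sorted(
                (
                    _draw_time_in_category(schedule, CATEGORIES[k], rng),
                    int(k),
                )
                for k in rng.choice(N_K, size=n_events, p=phi)
            )
            for t0, k in drawn:
                n_extra = int(rng.poisson(truth.photos_per_event_mean))
                gaps_s = rng.uniform(12.0, 180.0, n_extra)
                # keep the burst inside the grouping window
                while gaps_s.sum() >= window.total_seconds() - 1:
                    gaps_s = gaps_s[:-1]
                times = [t0] + [
                    t0 + timedelta(seconds=float(s)) for s in np.cumsum(gaps_s)
                ]
                # discard events too close to the previous one at this station:
                # they would merge during deduplication
                if last_photo_time is not None and t0 - last_photo_time <= window:
                    continue
                last_photo_time = times[-1]
                for t in times:
                    photo_rows.append(
                        {
                            "station_id": srow.station_id,
                            "species": truth.species,
                            "timestamp": t.isoformat(),
                        }
                    )
                rec = {
                    "event_id": event_id,
                    "station_id": srow.station_id,
                    "site_id": srow.site_id,
                    "city_id": srow.city_id,
                    "city_code": ccode,
                    "species": truth.species,
                    "timestamp": t0,
                    "category": CATEGORIES[k],
                    "n_photos": len(times),
                    "daily_mean_temperature": tavg,
                }
                rec.update(dict(zip(ALPHA_COLUMNS, alpha)))
                rec.update({f"x_{name}": v for name, v in zip(truth.covariate_names, x)})
                ledger_rows.append(rec)
                event_id += 1

    photos = pd.DataFrame(photo_rows)
    ledger = pd.DataFrame(ledger_rows)
    # events were generated day-by-day, which is already time order per station
    photos.attrs["seed"] = ledger.attrs["seed"] = truth.seed
    return photos, ledger, b_city


def simulate(truth: SimulationTruth, rng=None) -> SimulatedDataset:
    """Full dataset: sites, covariates, temperatures, photos, true ledger."""
    master = _rng(truth.seed if rng is None else rng)
    sites, covariates = simulate_sites(truth, master)
    temperatures = simulate_temperatures(truth, master)
    photos, ledger, b_city = simulate_detections(truth, sites, covariates, temperatures, master)
    return SimulatedDataset(
        truth=truth,
        sites=sites,
        covariates=covariates,
        temperatures=temperatures,
        photos=photos,
        ledger=ledger,
        city_intercepts=b_city,
    )


def build_model_data(ledger: pd.DataFrame, covariate_names) -> ModelData:
    """Assemble a ModelData from an event table with x_/alpha_ columns."""
    y = np.array([CATEGORIES.index(c) for c in ledger["category"]])
    log_alpha = np.log(ledger[ALPHA_COLUMNS].to_numpy(dtype=float))
    X = ledger[[f"x_{n}" for n in covariate_names]].to_numpy(dtype=float)
    if "city_code" in ledger.columns:
        city = ledger["city_code"].to_numpy(dtype=np.int64)
    else:
        city = pd.Categorical(ledger["city_id"]).codes.astype(np.int64)
    return ModelData(X=X, y=y, log_alpha=log_alpha, city=city)


def recovery_truth(beta: np.ndarray | None = None, seed: int = 1) -> SimulationTruth:
    """Reduced-scale parameter-recovery condition.

    5 cities x 24 sites (the study's smallest per-city network), a 90-day
    spring window, two site covariates, and an event rate giving ~2,000
    events — small enough to refit dozens of times on one CPU while keeping
    the study's hierarchical structure. Default true coefficients are
    moderate selection effects of both signs.
    """
    if beta is None:
        beta = np.array([[0.4, -0.3, 0.2, 0.0], [-0.5, 0.25, 0.0, 0.3]])
    return SimulationTruth(
        n_cities=5,
        sites_per_city=(24,) * 5,
        start=_date(2017, 4, 1),
        end=_date(2017, 6, 29),
        site_covariates=("greenspace", "impervious"),
        use_temperature=False,
        beta=np.asarray(beta, dtype=float),
        events_per_site_day=0.185,
        seed=seed,
    )


def null_calibration_truth(seed: int = 1) -> SimulationTruth:
    """Null condition (~10,000 events, all effects zero, 4 site covariates):
    detections should land in categories proportional to availability and a
    fit should find no selection."""
    return SimulationTruth(
        n_cities=5,
        sites_per_city=(24,) * 5,
        start=_date(2017, 4, 1),
        end=_date(2017, 8, 18),
        use_temperature=False,
        beta=None,
        city_intercept_sd=0.0,
        events_per_site_day=0.6,
        seed=seed,
    )


def recovery_experiment(
    truth: SimulationTruth,
    config: SamplerConfig,
    n_replicates: int,
    seed: int = 0,
) -> dict:
    """Repeated simulate -> fit -> compare, for calibration checking.

    Reports 95%-interval coverage of the true selection coefficients, bias
    and RMSE of the posterior medians, the worst Gelman-Rubin statistic,
    and any convergence failures. Fully reproducible from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    child = ss.generate_state(2 * n_replicates, dtype=np.uint64) % (2**31 - 1)
    beta_true = truth.true_beta()
    cover = np.zeros_like(beta_true)
    medians = np.zeros((n_replicates,) + beta_true.shape)
    max_rhats, failures = [], 0
    for r in range(n_replicates):
        t = SimulationTruth(**{**truth.__dict__, "seed": int(child[2 * r])})
        ds = simulate(t)
        data = build_model_data(ds.ledger, t.covariate_names)
        cfg = SamplerConfig(
            n_chains=config.n_chains,
            burn_in=config.burn_in,
            thin=config.thin,
            kept_total=config.kept_total,
            seed=int(child[2 * r + 1]),
            pi_bounds=config.pi_bounds,
        )
        samples = sample_posterior(data, cfg)
        flat = samples.flat("beta")
        lo = np.quantile(flat, 0.025, axis=0)
        hi = np.quantile(flat, 0.975, axis=0)
        cover += (lo <= beta_true) & (beta_true <= hi)
        medians[r] = np.median(flat, axis=0)
        max_rhats.append(samples.max_rhat())
        failures += 0 if samples.converged else 1
    bias = medians.mean(axis=0) - beta_true
    rmse = np.sqrt(((medians - beta_true) ** 2).mean(axis=0))
    return {
        "n_replicates": n_replicates,
        "coverage": (cover / n_replicates).tolist(),
        "overall_coverage": float(cover.sum() / (n_replicates * beta_true.size)),
        "bias": bias.tolist(),
        "rmse": rmse.tolist(),
        "max_rhat": float(np.nanmax(max_rhats)),
        "n_nonconverged": failures,
        "seed": seed,
    }
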