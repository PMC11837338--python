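"""Ground-truthed simulator of opportunistic butterfly observation data.

Emulates the structure of a multi-decade community-science dataset over
a three-county region: per-species flight curves whose onset shifts
linearly with a March-June spring-temperature index, heterogeneous daily
observer effort (a skewed observer pool, a weekend boost and a seasonal
ramp), duplicate reports, and rare high-effort survey events that plant
artificial early bursts of records — the kind of artefact influence
screening is meant to catch.  Every draw is recorded in a
:class:`GroundTruth` object so each pipeline stage can be validated
against known values.

The generative model, per species s and year y:

    T_y     = mu_T + trend * (y - y0) + Normal(0, sigma_T)
    beta_s  = g0 + g_volt*v_s + g_onset*(mu_s - c) + g_vo*v_s*(mu_s - c)
              + taxonomic effects + Normal(0, sigma_beta)
    onset_{s,y} = mu_s + beta_s * (T_y - Tbar)

Sighting days follow a right-skewed (lognormal) flight curve anchored so
that its 10th percentile sits at the true onset — the simulated estimand
matches the 10%-of-records estimator.  A symmetric (normal) curve is
available to study estimator bias.

Randomness uses one root seed split into independent substreams
(climate / species / records / outliers), so e.g. changing the outlier
model does not perturb the climate draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .records import DEFAULT_COUNTIES

_Z10 = stats.norm.ppf(0.10)  # standard-normal 10th percentile


@dataclass
class TraitModel:
    """Coefficients linking traits to sensitivity beta_s (days/degC)."""

    gamma0: float = -4.7
    gamma_volt: float = 0.0
    gamma_onset: float = 0.0
    gamma_interaction: float = -0.045
    onset_center: float = 120.0
    sd_resid: float = 3.0

    def beta(self, voltinism: np.ndarray, mu_onset: np.ndarray) -> np.ndarray:
        d = mu_onset - self.onset_center
        return (
            self.gamma0
            + self.gamma_volt * voltinism
            + self.gamma_onset * d
            + self.gamma_interaction * voltinism * d
        )


@dataclass
class EffortModel:
    """Observer-effort heterogeneity of opportunistic reporting."""

    n_observers: int = 60
    p_report: float = 0.8
    weekend_multiplier: float = 1.25
    seasonal_ramp: float = 0.4  # relative effort gain from day 1 to day 365
    duplicate_rate: float = 0.3


@dataclass
class OutlierModel:
    """Rare high-effort survey events that distort the empirical onset."""

    p_event: float = 0.08
    burst_size: int = 12
    offset_days: float = -35.0
    offset_jitter: float = 5.0


@dataclass
class SimulationConfig:
    seed: int = 0
    n_species: int = 38
    years: tuple[int, int] = (1993, 2020)
    counties: tuple[str, ...] = DEFAULT_COUNTIES
    # spring-temperature index: no secular trend, interannual variation only
    temp_mean: float = 17.9
    temp_sd: float = 0.8
    temp_trend: float = 0.0
    month_offsets: tuple[float, ...] = (-6.9, -1.9, 2.1, 6.7)  # Mar..Jun
    county_offsets: tuple[float, ...] = (-0.2, 0.0, 0.2)
    cell_noise: float = 0.1  # bounded uniform noise per monthly cell
    # species-level truth
    onset_range: tuple[float, float] = (70.0, 200.0)
    voltinism_levels: tuple[float, ...] = (1.0, 2.0, 3.0, 3.5, 4.0)
    voltinism_probs: tuple[float, ...] = (0.30, 0.30, 0.20, 0.05, 0.15)
    records_per_year_range: tuple[float, float] = (25.0, 60.0)
    flight_curve: str = "lognormal"  # or "normal"
    flight_sigma: float = 0.6  # lognormal shape
    flight_median_offset: float = 35.0  # days from curve start to median
    flight_sd_days: float = 25.0  # spread of the symmetric alternative
    trait_model: TraitModel = field(default_factory=TraitModel)
    # taxonomy and its variance shares in beta
    n_families: int = 5
    n_subfamilies: int = 9
    n_genera: int = 33
    sd_family: float = 0.5
    sd_subfamily: float = 0.5
    sd_genus: float = 1.5
    stage_confounding: float = 0.7  # P(stage follows onset tercile)
    effort: EffortModel = field(default_factory=EffortModel)
    outliers: OutlierModel = field(default_factory=OutlierModel)

    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))


@dataclass
class GroundTruth:
    spring_temp: pd.DataFrame  # year, temp_c
    species: pd.DataFrame  # species, mu_onset, beta, voltinism, stage, taxonomy
    onsets: pd.DataFrame  # species, year, true_onset
    outlier_events: pd.DataFrame  # species, year, event_doy, burst_size
    n_true_records: int = 0

    def to_json(self) -> str:
        payload = {
            "spring_temp": self.spring_temp.to_dict(orient="list"),
            "species": self.species.to_dict(orient="list"),
            "onsets": self.onsets.to_dict(orient="list"),
            "outlier_events": self.outlier_events.to_dict(orient="list"),
            "n_true_records": self.n_true_records,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


@dataclass
class SyntheticDataset:
    records: pd.DataFrame
    climate: pd.DataFrame
    traits: pd.DataFrame
    truth: GroundTruth
    config: SimulationConfig

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(out / "records.csv", index=False)
        self.climate.to_csv(out / "climate.csv", index=False)
        self.traits.to_csv(out / "traits.csv", index=False)
        (out / "truth.json").write_text(self.truth.to_json())


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    names = ("climate", "species", "records", "outliers")
    seqs = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, seqs)}


def simulate_climate(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Monthly county temperatures plus the true annual spring index.

    Cells are built so that the March-June, all-county grand mean equals
    the drawn annual index up to the bounded per-cell noise.
    """
    rng = rng or _substreams(config.seed)["climate"]
    years = config.year_list()
    y0 = years[0]
    idx = (
        config.temp_mean
        + config.temp_trend * (np.array(years) - y0)
        + rng.normal(0.0, config.temp_sd, len(years))
    )
    months = (3, 4, 5, 6)
    rows = []
    for year, t in zip(years, idx):
        for ci, county in enumerate(config.counties):
            for mi, month in enumerate(months):
                eps = rng.uniform(-config.cell_noise, config.cell_noise)
                rows.append(
                    {
                        "county": county,
                        "year": year,
                        "month": month,
                        "mean_temp_c": round(
                            t
                            + config.month_offsets[mi]
                            - np.mean(config.month_offsets)
                            + config.county_offsets[ci % len(config.county_offsets)]
                            - np.mean(config.county_offsets)
                            + eps,
                            4,
                        ),
                    }
                )
    climate = pd.DataFrame(rows)
    truth = pd.DataFrame({"year": years, "temp_c": idx})
    return climate, truth


def _taxonomy(config: SimulationConfig) -> pd.DataFrame:
    """Round-robin nested taxonomy: balanced, with consistent nesting."""
    n = config.n_species
    genera = [f"Genus{g:02d}" for g in range(config.n_genera)]
    sub_of_genus = {
        g: f"Subfam{gi % config.n_subfamilies:02d}"
        for gi, g in enumerate(genera)
    }
    fam_of_sub = {
        s: f"Family{si % config.n_families}"
        for si, s in enumerate(sorted(set(sub_of_genus.values())))
    }
    rows = []
    for i in range(n):
        g = genera[i % config.n_genera]
        s = sub_of_genus[g]
        rows.append(
            {
                "species": f"Species{i:02d}",
                "genus": g,
                "subfamily": s,
                "family": fam_of_sub[s],
            }
        )
    return pd.DataFrame(rows)


def simulate_species(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Per-species ground truth: traits, taxonomy, mean onset and beta."""
    rng = rng or _substreams(config.seed)["species"]
    n = config.n_species
    tax = _taxonomy(config)
    mu = rng.uniform(*config.onset_range, n)
    volt = rng.choice(
        config.voltinism_levels, size=n, p=config.voltinism_probs
    )
    lam = rng.uniform(*config.records_per_year_range, n)

    tm = config.trait_model
    beta = tm.beta(volt, mu)
    fam_eff = {f: rng.normal(0.0, config.sd_family) for f in tax["family"].unique()}
    sub_eff = {
        s: rng.normal(0.0, config.sd_subfamily) for s in tax["subfamily"].unique()
    }
    gen_eff = {g: rng.normal(0.0, config.sd_genus) for g in tax["genus"].unique()}
    beta = (
        beta
        + tax["family"].map(fam_eff).to_numpy()
        + tax["subfamily"].map(sub_eff).to_numpy()
        + tax["genus"].map(gen_eff).to_numpy()
        + rng.normal(0.0, tm.sd_resid, n)
    )

    # Overwintering stage confounded with onset timing: adults fly
    # earliest, larval overwinterers latest (a tercile rule), with
    # probability `stage_confounding`; otherwise a uniform draw.
    terciles = np.searchsorted(
        np.quantile(mu, [1 / 3, 2 / 3]), mu, side="right"
    )
    tercile_stage = np.array(["adult", "pupa", "larva"])[terciles]
    follow = rng.uniform(size=n) < config.stage_confounding
    random_stage = rng.choice(["larva", "pupa", "adult"], size=n)
    stage = np.where(follow, tercile_stage, random_stage)

    return tax.assign(
        mu_onset=mu,
        beta=beta,
        voltinism=volt,
        overwinter_stage=stage,
        records_per_year=lam,
    )


def true_onsets(species: pd.DataFrame, spring: pd.DataFrame) -> pd.DataFrame:
    """Exact per-species-year onset: mu_s + beta_s * (T_y - Tbar)."""
    tbar = spring["temp_c"].mean()
    rows = []
    for sp in species.itertuples(index=False):
        for y in spring.itertuples(index=False):
            rows.append(
                {
                    "species": sp.species,
                    "year": int(y.year),
                    "true_onset": sp.mu_onset + sp.beta * (y.temp_c - tbar),
                }
            )
    return pd.DataFrame(rows)


def _flight_days(
    config: SimulationConfig,
    onset: float,
    size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sighting days from a flight curve whose 10th pctile is the onset."""
    if config.flight_curve == "lognormal":
        mu_log = np.log(config.flight_median_offset)
        anchor = np.exp(mu_log + config.flight_sigma * _Z10)
        days = onset - anchor + rng.lognormal(mu_log, config.flight_sigma, size)
    elif config.flight_curve == "normal":
        days = onset + config.flight_sd_days * (rng.normal(size=size) - _Z10)
    else:
        raise ValueError(f"unknown flight curve: {config.flight_curve!r}")
    return np.clip(np.rint(days), 1, 365).astype(int)


def _doy_to_date(year: int, doy: int) -> pd.Timestamp:
    return pd.Timestamp(year, 1, 1) + pd.Timedelta(days=int(doy) - 1)


def simulate_records(
    config: SimulationConfig,
    species: pd.DataFrame,
    onsets: pd.DataFrame,
    rng: np.random.Generator | None = None,
    outlier_rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Raw observation rows, planted outlier events, and the true record count.

    Sightings are thinned by a per-day reporting probability modulated
    by a weekend boost and a mild seasonal ramp, assigned to a skewed
    observer pool, and then inflated with exact duplicate reports; the
    count of unique keys *before* duplicate injection is returned so
    deduplication can be validated exactly.
    """
    streams = _substreams(config.seed)
    rng = rng or streams["records"]
    outlier_rng = outlier_rng or streams["outliers"]
    eff = config.effort
    observers = np.array([f"obs{i:03d}" for i in range(eff.n_observers)])
    obs_w = 1.0 / np.arange(1, eff.n_observers + 1)  # Zipf-like activity
    obs_w /= obs_w.sum()
    county_p = np.full(len(config.counties), 1.0 / len(config.counties))

    rows = []
    events = []
    onset_lookup = onsets.set_index(["species", "year"])["true_onset"]
    for sp in species.itertuples(index=False):
        for year in range(config.years[0], config.years[1] + 1):
            o = float(onset_lookup.loc[(sp.species, year)])
            n_sight = rng.poisson(sp.records_per_year)
            if n_sight:
                days = _flight_days(config, o, n_sight, rng)
                dates = [_doy_to_date(year, d) for d in days]
                weekend = np.array([d.weekday() >= 5 for d in dates])
                ramp = 1.0 + config.effort.seasonal_ramp * (days / 365.0 - 0.5)
                p = np.clip(
                    eff.p_report
                    * np.where(weekend, eff.weekend_multiplier, 1.0)
                    * ramp,
                    0.0,
                    1.0,
                )
                keep = rng.uniform(size=n_sight) < p
                days = days[keep]
                who = rng.choice(observers, size=keep.sum(), p=obs_w)
                where = rng.choice(
                    list(config.counties), size=keep.sum(), p=county_p
                )
                counts = 1 + rng.poisson(1.5, keep.sum())
                for d, ob, co, k in zip(days, who, where, counts):
                    rows.append(
                        {
                            "observer_id": ob,
                            "date": _doy_to_date(year, d).date().isoformat(),
                            "county": co,
                            "species": sp.species,
                            "count": int(k),
                            "source": "sim",
                        }
                    )
            # rare mass-survey event: many distinct observers, one date
            if outlier_rng.uniform() < config.outliers.p_event:
                off = config.outliers.offset_days + outlier_rng.uniform(
                    -config.outliers.offset_jitter, config.outliers.offset_jitter
                )
                d = int(np.clip(round(o + off), 1, 365))
                burst_obs = outlier_rng.choice(
                    observers,
                    size=min(config.outliers.burst_size, eff.n_observers),
                    replace=False,
                )
                co = str(outlier_rng.choice(list(config.counties)))
                for ob in burst_obs:
                    rows.append(
                        {
                            "observer_id": str(ob),
                            "date": _doy_to_date(year, d).date().isoformat(),
                            "county": co,
                            "species": sp.species,
                            "count": 1,
                            "source": "sim_event",
                        }
                    )
                events.append(
                    {
                        "species": sp.species,
                        "year": year,
                        "event_doy": d,
                        "burst_size": len(burst_obs),
                    }
                )

    base = pd.DataFrame(
        rows,
        columns=["observer_id", "date", "county", "species", "count", "source"],
    )
    # collapse key collisions so the pre-duplication key count is exact
    base = base.drop_duplicates(
        subset=["observer_id", "date", "county", "species"]
    ).reset_index(drop=True)
    n_true = len(base)

    if eff.duplicate_rate > 0 and n_true:
        pick = rng.uniform(size=n_true) < eff.duplicate_rate
        dups = base[pick].copy()
        dups["count"] = 1 + rng.poisson(1.5, len(dups))
        base = pd.concat([base, dups], ignore_index=True)

    base = base.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(
        drop=True
    )
    ev = pd.DataFrame(
        events, columns=["species", "year", "event_doy", "burst_size"]
    )
    return base, ev, n_true


def simulate_traits(species: pd.DataFrame) -> pd.DataFrame:
    """Trait table in the analysis input schema."""
    return species[
        ["species", "voltinism", "overwinter_stage", "family", "subfamily", "genus"]
    ].copy()


def simulate(config: SimulationConfig) -> SyntheticDataset:
    """Full synthetic study: records + climate + traits + ground truth."""
    streams = _substreams(config.seed)
    climate, spring = simulate_climate(config, streams["climate"])
    species = simulate_species(config, streams["species"])
    onsets = true_onsets(species, spring)
    records, events, n_true = simulate_records(
        config, species, onsets, streams["records"], streams["outliers"]
    )
    truth = GroundTruth(
        spring_temp=spring,
        species=species,
        onsets=onsets,
        outlier_events=events,
        n_true_records=n_true,
    )
    return SyntheticDataset(
        records=records,
        climate=climate,
        traits=simulate_traits(species),
        truth=truth,
        config=config,
    )
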