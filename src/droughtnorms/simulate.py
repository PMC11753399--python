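"""Synthetic data with the statistical structure the analysis assumes.

Generates the four inputs the pipeline consumes — daily rainfall,
per-sample fecal glucocorticoid (GC) records, per-female demography, and
a year-level mortality table — from a single :class:`SimulationConfig`
with known ground truth, so that parameter-recovery and sign-recovery
experiments can compare estimates against the generating values.

The generative model mirrors the fitted ones:

* daily rain is zero-inflated gamma with a wet season (May–Nov) and a dry
  season; drought years scale the wet-season mean by a per-year factor;
* each female carries a draw ``(b0, bd, br, bdr)`` from a multivariate
  normal — her random intercept and slopes for drought risk, expected
  rainfall and their interaction.  Her true reaction-norm slope at
  expected rainfall 1 is ``bd + bdr``;
* log GC = fixed effects + individual deviations + Gaussian residual;
* survival is Bernoulli with logit linear in the (z-scored) true slope
  and intercept, age, and rank;
* yearly deaths are binomial at a baseline rate multiplied up in severe
  El Niño years.

Everything is deterministic per seed, with distinct per-component
substreams so each piece can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .hormones import FemaleRecord, assign_reproductive_state, merge_state, DROUGHT_START

__all__ = [
    "SimulationConfig",
    "simulate_rainfall",
    "simulate_individuals",
    "simulate_gc_samples",
    "simulate_survival",
    "simulate_mortality_table",
    "write_fixtures",
]

# substream identifiers
_RAIN, _INDIV, _GC, _SURV, _MORT = 0, 1, 2, 3, 4


def _rng(config, component: int, seed=None):
    if seed is not None:
        return np.random.default_rng(seed)
    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(component,))
    return np.random.default_rng(ss)


@dataclass
class SimulationConfig:
    """Ground-truth configuration; defaults are the study conditions.

    Fixed effects and survival coefficients default to the regime of the
    analysed system (e.g. a survival log-odds slope of 0.73 per SD of
    reaction norm); rainfall defaults produce a tropical-dry-forest
    pattern with ~1900 mm/yr falling mostly May–November and drought
    years during both the sampling period and the later El Niño.
    """

    seed: int = 0
    # rainfall
    rain_start_year: int = 1996
    rain_end_year: int = 2015
    wet_season: tuple = ((5, 1), (11, 30))  # month/day bounds, inclusive
    wet_mean_mm: float = 9.0
    dry_mean_mm: float = 0.3
    p_rain_wet: float = 0.55
    p_rain_dry: float = 0.05
    rain_dispersion: float = 0.7  # gamma shape of wet-day amounts
    drought_year_multipliers: dict = field(
        default_factory=lambda: {2009: 0.55, 2012: 0.6, 2014: 0.35, 2015: 0.4}
    )
    # individuals
    n_females: int = 28
    n_groups: int = 8
    age_range_years: tuple = (8.0, 24.0)  # at the drought start
    group_size_range: tuple = (8, 20)
    samples_per_female_mean: float = 27.0
    min_samples_per_female: int = 5
    study_window: tuple = ("2008-01-01", "2013-12-31")
    # GC fixed effects: intercept, drought risk, expected rainfall,
    # their interaction, collection time (per SD), early/late pregnancy
    beta0: float = 5.0
    beta_drought: float = 0.2
    beta_rain: float = -0.2
    beta_interaction: float = 0.15
    beta_time: float = -0.2
    beta_early_pregnancy: float = 0.15
    beta_late_pregnancy: float = 0.35
    # random-effect SDs for (b0, bd, br, bdr) and their correlation matrix
    sd_random: tuple = (0.2, 0.15, 0.1, 0.15)
    corr_random: np.ndarray | None = None  # default: identity
    sigma_resid: float = 0.4
    # survival: intercept, slope BLUP, intercept BLUP, age, rank (logit scale)
    gamma0: float = 0.0
    gamma_slope: float = 0.73
    gamma_intercept: float = 0.09
    gamma_age: float = -0.44
    gamma_rank: float = 0.27
    # mortality table
    mortality_years: tuple = tuple(range(1990, 2024))
    severe_el_nino_years: tuple = (1997, 2014, 2015)
    el_nino_years: tuple = (1992, 1998, 2003, 2010)
    baseline_death_rate: float = 0.04
    severe_multiplier: float = 3.3
    yearly_exposure: int = 45
    # planted data problems (0 = clean data)
    n_gc_outliers: int = 0
    n_cv_failures: int = 0

    def random_effect_cov(self) -> np.ndarray:
        sd = np.asarray(self.sd_random, float)
        corr = (
            np.eye(4) if self.corr_random is None else np.asarray(self.corr_random, float)
        )
        eigs = np.linalg.eigvalsh(corr)
        if eigs.min() < -1e-10:
            raise ValueError("random-effect correlation matrix is not PSD")
        return corr * np.outer(sd, sd)

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["corr_random"] is not None:
            d["corr_random"] = np.asarray(d["corr_random"]).tolist()
        d["drought_year_multipliers"] = {
            int(k): float(v) for k, v in d["drought_year_multipliers"].items()
        }
        return d


def _in_wet_season(index: pd.DatetimeIndex, wet_season) -> np.ndarray:
    (m0, d0), (m1, d1) = wet_season
    key = index.month * 100 + index.day
    return (key >= m0 * 100 + d0) & (key <= m1 * 100 + d1)


def simulate_rainfall(config: SimulationConfig, seed=None) -> pd.Series:
    """Daily rainfall series (mm) over the configured span."""
    rng = _rng(config, _RAIN, seed)
    index = pd.date_range(
        f"{config.rain_start_year}-01-01", f"{config.rain_end_year}-12-31", freq="D"
    )
    wet = _in_wet_season(index, config.wet_season)
    mean = np.where(wet, config.wet_mean_mm, config.dry_mean_mm).astype(float)
    mult = np.ones(len(index))
    for year, factor in config.drought_year_multipliers.items():
        mult[wet & (index.year == year)] = factor
    mean *= mult
    p_rain = np.where(wet, config.p_rain_wet, config.p_rain_dry)
    rains = rng.uniform(size=len(index)) < p_rain
    k = config.rain_dispersion
    # conditional wet-day mean = daily mean / p(rain)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(p_rain > 0, mean / np.maximum(p_rain, 1e-12) / k, 0.0)
    amounts = rng.gamma(k, 1.0, size=len(index)) * scale
    values = np.where(rains & (mean > 0), amounts, 0.0)
    return pd.Series(values, index=index)


def simulate_individuals(config: SimulationConfig, seed=None):
    """Draw females (demography + offspring) and their true random effects.

    Returns ``(females, truth)``: a dict of :class:`FemaleRecord` and a
    truth DataFrame with one row per female carrying ``b0, bd, br, bdr``,
    the reaction-norm slope/intercept at expected rainfall 1, age and
    rank.
    """
    rng = _rng(config, _INDIV, seed)
    cov = config.random_effect_cov()
    # svd handles singular covariances (zero SDs) gracefully
    effects = rng.multivariate_normal(np.zeros(4), cov, size=config.n_females,
                                      method="svd")
    ages = rng.uniform(*config.age_range_years, size=config.n_females)
    ranks = rng.uniform(0.02, 1.0, size=config.n_females)
    lo, hi = config.group_size_range
    group_sizes = rng.integers(lo, hi + 1, size=config.n_groups)

    window_start = pd.Timestamp(config.study_window[0])
    window_end = pd.Timestamp(config.study_window[1])
    females = {}
    rows = []
    for i in range(config.n_females):
        fid = f"F{i:03d}"
        gid = f"G{i % config.n_groups}"
        birth = DROUGHT_START - pd.Timedelta(days=round(ages[i] * 365.25))
        # births spaced >= 400 days so pregnancies never overlap
        offspring = []
        t = window_start + pd.Timedelta(days=int(rng.integers(0, 700)))
        while t <= window_end:
            if (t - birth).days / 365.25 >= 6.0:
                death = (
                    t + pd.Timedelta(days=int(rng.integers(20, 330)))
                    if rng.uniform() < 0.2
                    else None
                )
                offspring.append((t, death))
            t = t + pd.Timedelta(days=int(rng.integers(500, 1100)))
        females[fid] = FemaleRecord(
            female_id=fid,
            group_id=gid,
            birth_date=birth,
            rank=float(ranks[i]),
            survived_el_nino=None,
            offspring=offspring,
            group_size=float(group_sizes[i % config.n_groups]),
        )
        rows.append(
            {
                "female_id": fid,
                "group_id": gid,
                "b0": effects[i, 0],
                "bd": effects[i, 1],
                "br": effects[i, 2],
                "bdr": effects[i, 3],
                "true_slope_at_rain1": effects[i, 1] + effects[i, 3],
                "true_intercept_at_rain1": effects[i, 0] + effects[i, 2],
                "age": ages[i],
                "rank": ranks[i],
            }
        )
    return females, pd.DataFrame(rows)


def _time_standardizer():
    """Mean/SD of collection time (minutes) under uniform 05:00–18:00 sampling."""
    lo, hi = 300.0, 1080.0
    return (lo + hi) / 2.0, (hi - lo) / np.sqrt(12.0)


def simulate_gc_samples(
    config: SimulationConfig,
    females: dict,
    truth: pd.DataFrame,
    index_table: pd.DataFrame,
    seed=None,
) -> pd.DataFrame:
    """Per-sample GC records generated from the reaction-norm model.

    ``log GC = β0 + b0 + (βd+bd)·D + (βr+br)·R + (βdr+bdr)·D·R + βt·t +
    state offsets + ε``, with D/R read off the supplied drought-index
    table on the sampled dates and t the approximately standardized
    collection time.  Outliers/CV failures are planted on request.
    """
    rng = _rng(config, _GC, seed)
    idx = index_table.set_index(pd.to_datetime(index_table["date"]))
    lo, hi = pd.Timestamp(config.study_window[0]), pd.Timestamp(config.study_window[1])
    eligible = idx.loc[
        (idx.index >= lo)
        & (idx.index <= hi)
        & idx["drought_risk"].notna()
        & idx["expected_rainfall"].notna()
    ]
    if len(eligible) == 0:
        raise ValueError("index table covers no study-window dates")
    dates_pool = eligible.index.to_numpy()
    t_mean, t_sd = _time_standardizer()
    truth_idx = truth.set_index("female_id")

    rows = []
    for fid, rec in females.items():
        n_i = max(config.min_samples_per_female, rng.poisson(config.samples_per_female_mean))
        n_i = min(n_i, len(dates_pool))
        chosen = rng.choice(len(dates_pool), size=n_i, replace=False)
        chosen.sort()
        b0, bd, br, bdr = truth_idx.loc[fid, ["b0", "bd", "br", "bdr"]]
        for j in chosen:
            date = pd.Timestamp(dates_pool[j])
            D = float(eligible["drought_risk"].iloc[j])
            R = float(eligible["expected_rainfall"].iloc[j])
            minutes = float(rng.uniform(300, 1080))
            t = (minutes - t_mean) / t_sd
            state = merge_state(assign_reproductive_state(rec, date))
            offset = {
                "not_pregnant": 0.0,
                "early_pregnancy": config.beta_early_pregnancy,
                "late_pregnancy": config.beta_late_pregnancy,
            }[state]
            log_gc = (
                config.beta0
                + b0
                + (config.beta_drought + bd) * D
                + (config.beta_rain + br) * R
                + (config.beta_interaction + bdr) * D * R
                + config.beta_time * t
                + offset
                + rng.normal(0.0, config.sigma_resid)
            )
            rows.append(
                {
                    "female_id": fid,
                    "group_id": rec.group_id,
                    "date": date,
                    "collection_time_min": round(minutes),
                    "gc_ng_per_g": float(np.exp(log_gc)),
                    "dry_mass_g": float(rng.gamma(8.0, 0.065)),
                    "assay_cv": float(rng.uniform(0.02, 0.15)),
                }
            )
    samples = pd.DataFrame(rows)
    # planted problems go on distinct samples that survive the (deterministic)
    # selection rules, so downstream removal logs count them exactly
    n_bad = config.n_gc_outliers + config.n_cv_failures
    if n_bad:
        from .hormones import select_samples

        kept = pd.concat(
            [
                select_samples(g, study_window=config.study_window)
                for _, g in samples.groupby("female_id", sort=True)
            ],
            ignore_index=True,
        )
        key = samples["female_id"] + "@" + samples["date"].dt.strftime("%Y-%m-%d")
        kept_key = set(kept["female_id"] + "@" + kept["date"].dt.strftime("%Y-%m-%d"))
        eligible_idx = samples.index[key.isin(kept_key)].to_numpy()
        bad = rng.choice(eligible_idx, size=n_bad, replace=False)
        gc_out, cv_out = bad[: config.n_gc_outliers], bad[config.n_gc_outliers :]
        samples.loc[gc_out, "gc_ng_per_g"] *= 50.0
        samples.loc[cv_out, "assay_cv"] = 0.25
    return samples


def simulate_survival(config: SimulationConfig, truth: pd.DataFrame, seed=None):
    """Bernoulli survival outcomes from the true reaction norms.

    The logit-scale linear predictor uses z-scored *true* slope and
    intercept at expected rainfall 1 plus z-scored age and rank, so the
    attenuation introduced later by using BLUPs instead of truth is
    measurable.  Returns ``truth`` with ``p_survive`` and ``survived``
    columns added.
    """
    rng = _rng(config, _SURV, seed)

    def z(x):
        x = np.asarray(x, float)
        sd = x.std(ddof=1)
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    eta = (
        config.gamma0
        + config.gamma_slope * z(truth["true_slope_at_rain1"])
        + config.gamma_intercept * z(truth["true_intercept_at_rain1"])
        + config.gamma_age * z(truth["age"])
        + config.gamma_rank * z(truth["rank"])
    )
    p = 1.0 / (1.0 + np.exp(-eta))
    survived = rng.uniform(size=len(truth)) < p
    out = truth.copy()
    out["p_survive"] = p
    out["survived"] = survived.astype(int)
    return out


def simulate_mortality_table(config: SimulationConfig, seed=None) -> pd.DataFrame:
    """Year-level deaths/exposure table (study years run 15 May – 14 May)."""
    rng = _rng(config, _MORT, seed)
    rows = []
    for year in config.mortality_years:
        if year in config.severe_el_nino_years:
            category, mult = "severe_el_nino", config.severe_multiplier
        elif year in config.el_nino_years:
            category, mult = "el_nino", 1.0
        else:
            category, mult = "normal", 1.0
        rate = min(config.baseline_death_rate * mult, 1.0)
        exposure = int(config.yearly_exposure)
        deaths = int(rng.binomial(exposure, rate)) if exposure > 0 else 0
        rows.append(
            {
                "year_start": f"{year}-05-15",
                "deaths": deaths,
                "exposure": exposure,
                "category": category,
            }
        )
    return pd.DataFrame(rows)


def write_fixtures(config: SimulationConfig, outdir) -> dict:
    """Generate and write all four input tables; returns the file paths.

    Also writes the ground-truth table (``truth.csv``) for recovery
    experiments; the pipeline itself never reads it.
    """
    from pathlib import Path

    from . import rainfall as rf

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rain = simulate_rainfall(config)
    clim = rf.build_climatology(
        rain,
        reference_years=range(config.rain_start_year, 2014),
        expected_reference_years=range(config.rain_start_year + 1, 2014),
    )
    index_table = rf.build_index_table(rain, clim)
    females, truth = simulate_individuals(config)
    samples = simulate_gc_samples(config, females, truth, index_table)
    truth = simulate_survival(config, truth)
    surv = truth.set_index("female_id")["survived"]
    for fid, rec in females.items():
        rec.survived_el_nino = bool(surv.loc[fid])
        if not rec.survived_el_nino:
            rec.death_window = (pd.Timestamp("2014-05-15"), pd.Timestamp("2016-05-14"))
    mortality = simulate_mortality_table(config)

    paths = {
        "rainfall": outdir / "rainfall.csv",
        "samples": outdir / "samples.csv",
        "females": outdir / "females.csv",
        "mortality": outdir / "mortality.csv",
        "truth": outdir / "truth.csv",
    }
    rf.write_rainfall(rain, paths["rainfall"])
    out_samples = samples.copy()
    out_samples["date"] = out_samples["date"].dt.strftime("%Y-%m-%d")
    out_samples.to_csv(paths["samples"], index=False)

    fem_rows = []
    for fid, rec in females.items():
        fem_rows.append(
            {
                "female_id": fid,
                "group_id": rec.group_id,
                "birth_date": rec.birth_date.strftime("%Y-%m-%d"),
                "birth_date_error_years": rec.birth_date_error_years,
                "rank": rec.rank,
                "survived_el_nino": int(rec.survived_el_nino),
                "death_earliest": (
                    rec.death_window[0].strftime("%Y-%m-%d") if rec.death_window else ""
                ),
                "death_latest": (
                    rec.death_window[1].strftime("%Y-%m-%d") if rec.death_window else ""
                ),
                "offspring": ";".join(
                    f"{b.strftime('%Y-%m-%d')}:{d.strftime('%Y-%m-%d') if d else ''}"
                    for b, d in rec.offspring
                ),
                "group_size": rec.group_size,
            }
        )
    pd.DataFrame(fem_rows).to_csv(paths["females"], index=False)
    mortality.to_csv(paths["mortality"], index=False)
    truth.to_csv(paths["truth"], index=False)
    return paths
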