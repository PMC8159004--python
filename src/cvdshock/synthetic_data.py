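"""Seeded generators for internally consistent model inputs.

The real inputs behind this kind of analysis (census population counts,
labour-force survey unemployment rates, national disease-model
epidemiology and cost tables) are administrative and not redistributable,
so this module fabricates tables with the same statistical structure:

* a two-ethnicity population (the indigenous group younger and ~15% of
  the total),
* unemployment rates roughly twice as high for the indigenous group and
  graded downward with age,
* Gompertz-style (exponential in age) mortality, CVD incidence and case
  fatality, with the indigenous group carrying a higher burden,
* plausible disability weights and cost schedules.

Everything is deterministic for a fixed seed and validates against the
package's type invariants, so the whole pipeline is testable offline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._common import AGE_BANDS, ETHNICITIES, MAX_AGE, SEXES, InputError, band_of_age
from .risk_link import builtin_effects, validate_effects
from .scenarios import ScenarioDefinition, builtin_scenarios

# ---------------------------------------------------------------------------
# configs


@dataclass(frozen=True)
class PopulationConfig:
    total: int = 100_000
    maori_share: float = 0.15
    female_share: float = 0.5
    #: age-pyramid scale (years); smaller = younger population
    maori_age_scale: float = 45.0
    non_maori_age_scale: float = 60.0
    younger_maori: bool = True


@dataclass(frozen=True)
class UnemploymentConfig:
    overall: float = 0.04
    maori_ratio: float = 2.0
    female_male_ratio: float = 1.05
    #: band rate relative to the 45-54 reference band
    band_weights: dict = field(
        default_factory=lambda: {
            "15-24": 3.0,
            "25-34": 1.5,
            "35-44": 1.1,
            "45-54": 1.0,
            "55-64": 0.85,
        }
    )
    age_gradient: bool = True


@dataclass(frozen=True)
class EpiConfig:
    """Gompertz-style levels (at the age-60 reference) and log-slopes."""

    acm_level: float = 0.008
    acm_slope: float = 0.085
    chd_incidence_level: float = 0.005
    chd_incidence_slope: float = 0.08
    chd_fatality_level: float = 0.04
    chd_fatality_slope: float = 0.04
    chd_prevalence_level: float = 0.05
    chd_prevalence_slope: float = 0.05
    stroke_incidence_level: float = 0.003
    stroke_incidence_slope: float = 0.085
    stroke_fatality_level: float = 0.06
    stroke_fatality_slope: float = 0.04
    stroke_prevalence_level: float = 0.02
    stroke_prevalence_slope: float = 0.05
    maori_acm_ratio: float = 1.5
    maori_incidence_ratio: float = 2.0
    maori_fatality_ratio: float = 1.3
    maori_prevalence_ratio: float = 2.0
    male_factor: float = 1.2
    # disability weights are placeholders: the source burden-of-disease
    # morbidity schedules are unpublished, so only output *differences*
    # are meaningful downstream
    dw_chd: float = 0.15
    dw_stroke: float = 0.25
    bg_cost_level: float = 1000.0
    bg_cost_slope: float = 0.02
    chd_cost: float = 5000.0
    stroke_cost: float = 8000.0
    jitter_cv: float = 0.03
    rate_cap: float = 0.95
    fatality_cap: float = 0.9
    prevalence_cap: float = 0.25


@dataclass(frozen=True)
class TrendConfig:
    """Secular-decline assumptions applied per model cycle."""

    mortality_decline: dict = field(
        default_factory=lambda: {"maori": 0.0225, "non_maori": 0.0175}
    )
    #: mortality decline applies for this many cycles, then freezes
    mortality_trend_years: int = 15
    disease_decline: float = 0.02
    #: sensitivity switch: halt the disease (incidence/fatality) decline
    disease_trend_frozen: bool = False


# ---------------------------------------------------------------------------
# containers

EPI_COLUMNS = [
    "ethnicity", "sex", "age", "acm",
    "chd_incidence", "chd_fatality", "chd_prevalence",
    "stroke_incidence", "stroke_fatality", "stroke_prevalence",
    "dw_chd", "dw_stroke", "bg_cost", "chd_cost", "stroke_cost",
]

_RATE_COLS = [
    "acm", "chd_incidence", "chd_fatality", "chd_prevalence",
    "stroke_incidence", "stroke_fatality", "stroke_prevalence",
    "dw_chd", "dw_stroke",
]


@dataclass
class EpiTable:
    """Per-stratum, single-year-of-age epidemiology and cost schedule."""

    table: pd.DataFrame
    trends: TrendConfig = field(default_factory=TrendConfig)

    def validate(self) -> None:
        missing = set(EPI_COLUMNS) - set(self.table.columns)
        if missing:
            raise InputError(f"epi table missing columns: {sorted(missing)}")
        sub = self.table[_RATE_COLS]
        if ((sub < 0) | (sub > 1)).any().any():
            raise InputError("epi rates must lie in [0, 1]")
        if (self.table[["chd_fatality", "stroke_fatality"]] >= 1).any().any():
            raise InputError("case fatality must be < 1")
        if (self.table[["bg_cost", "chd_cost", "stroke_cost"]] < 0).any().any():
            raise InputError("costs must be non-negative")

    def copy(self) -> "EpiTable":
        return EpiTable(table=self.table.copy(), trends=self.trends)


@dataclass
class UnemploymentBaseline:
    """Pre-pandemic unemployment rates: cross-classified plus marginals."""

    rates: pd.DataFrame  # columns: ethnicity, sex, age_band, rate
    ethnicity_rates: pd.Series
    sex_rates: pd.Series
    band_rates: pd.Series
    overall: float

    def validate(self) -> None:
        if ((self.rates["rate"] < 0) | (self.rates["rate"] > 1)).any():
            raise InputError("unemployment rates must lie in [0, 1]")
        have = set(
            zip(self.rates["ethnicity"], self.rates["sex"], self.rates["age_band"])
        )
        want = {
            (e, s, b) for e in ETHNICITIES for s in SEXES for b in AGE_BANDS
        }
        if have != want:
            raise InputError("unemployment table must cover every stratum exactly once")


@dataclass
class ModelInputs:
    """A complete, mutually consistent model input set."""

    population: pd.DataFrame
    unemployment: UnemploymentBaseline
    epi: EpiTable
    scenarios: dict[str, ScenarioDefinition]
    effects: pd.DataFrame
    #: multiplier on aggregate shock increments (used by uncertainty draws)
    unemployment_scale: float = 1.0

    def validate(self) -> None:
        validate_population(self.population)
        self.unemployment.validate()
        self.epi.validate()
        validate_effects(self.effects)
        if not self.scenarios:
            raise InputError("at least one scenario required")


def validate_population(population: pd.DataFrame) -> None:
    for col in ("ethnicity", "sex", "age", "count"):
        if col not in population.columns:
            raise InputError(f"population table missing column {col!r}")
    if (population["count"] < 0).any():
        raise InputError("population counts must be non-negative")
    if population["count"].sum() <= 0:
        raise InputError("total population must be positive")
    cells = population.groupby("age").size()
    ages = set(range(MAX_AGE + 1))
    if set(cells.index) != ages or (cells != len(ETHNICITIES) * len(SEXES)).any():
        raise InputError(
            "population must contain all 4 ethnicity x sex cells for every age 0-110"
        )


# ---------------------------------------------------------------------------
# generators


def generate_population(
    config: PopulationConfig | None = None, seed: int = 0
) -> pd.DataFrame:
    """Sample a single-year-of-age population table (ages 0-110).

    Counts are drawn once from a multinomial over ethnicity x sex x age
    with half-Gaussian age pyramids, so the table is deterministic for a
    fixed (config, seed) pair.
    """
    config = config or PopulationConfig()
    if config.total <= 0:
        raise InputError("total population size must be positive")
    for share in (config.maori_share, config.female_share):
        if not 0.0 <= share <= 1.0:
            raise InputError("shares must lie in [0, 1]")

    ages = np.arange(MAX_AGE + 1)
    scales = {
        "maori": config.maori_age_scale if config.younger_maori else config.non_maori_age_scale,
        "non_maori": config.non_maori_age_scale,
    }
    eth_shares = {"maori": config.maori_share, "non_maori": 1.0 - config.maori_share}
    sex_shares = {"female": config.female_share, "male": 1.0 - config.female_share}

    probs, keys = [], []
    for eth in ETHNICITIES:
        shape = np.exp(-((ages / scales[eth]) ** 2))
        shape = shape / shape.sum()
        for sex in SEXES:
            p = eth_shares[eth] * sex_shares[sex] * shape
            probs.append(p)
            keys.extend((eth, sex, int(a)) for a in ages)
    p = np.concatenate(probs)
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(config.total, p)
    out = pd.DataFrame(keys, columns=["ethnicity", "sex", "age"])
    out["count"] = counts.astype(float)
    return out


def _marginal_targets(config: UnemploymentConfig, pops: pd.DataFrame):
    """Marginal rates per axis that satisfy the configured ratios exactly
    and reproduce the overall population-weighted rate."""
    n = pops["count"].sum()
    p_eth = pops.groupby("ethnicity")["count"].sum()
    p_sex = pops.groupby("sex")["count"].sum()
    p_band = pops.groupby("age_band")["count"].sum()

    r_e, r_s = config.maori_ratio, config.female_male_ratio
    u_nm = config.overall * n / (p_eth.get("maori", 0.0) * r_e + p_eth.get("non_maori", 0.0))
    eth = pd.Series({"maori": r_e * u_nm, "non_maori": u_nm})

    u_m = config.overall * n / (p_sex.get("female", 0.0) * r_s + p_sex.get("male", 0.0))
    sex = pd.Series({"female": r_s * u_m, "male": u_m})

    if config.age_gradient:
        weights = dict(config.band_weights)
    else:
        weights = {b: 1.0 for b in AGE_BANDS}
    wsum = sum(p_band.get(b, 0.0) * w for b, w in weights.items())
    u_ref = config.overall * n / wsum
    band = pd.Series({b: w * u_ref for b, w in weights.items()})

    for series in (eth, sex, band):
        if (series > 1.0).any() or (series <= 0).any():
            raise InputError("configured ratios produce marginal rates outside (0, 1]")
    return eth, sex, band


def generate_unemployment_baseline(
    config: UnemploymentConfig | None = None,
    population: pd.DataFrame | None = None,
    seed: int = 0,
) -> UnemploymentBaseline:
    """Build the cross-classified pre-pandemic unemployment baseline.

    The cross-classified cell rates are raked (iterative proportional
    fitting on expected unemployed counts) so that the
    population-weighted marginals match the configured ethnic/sex/age
    targets; the configured ratios therefore hold exactly in the output
    marginals and the population-weighted mean of the cell rates equals
    the configured overall rate.  Generation is deterministic; ``seed``
    is accepted for interface uniformity with the other generators.
    """
    from .calibration import band_populations  # deferred: calibration imports us not

    config = config or UnemploymentConfig()
    if population is None:
        population = generate_population(seed=seed)
    if not 0.0 < config.overall < 1.0:
        raise InputError("overall unemployment rate must lie in (0, 1)")
    pops = band_populations(population)
    eth_t, sex_t, band_t = _marginal_targets(config, pops)

    w = (
        pops.set_index(["ethnicity", "sex", "age_band"])["count"]
        .unstack(["sex", "age_band"])
        .reindex(index=list(ETHNICITIES))
        .to_numpy()
        .reshape(len(ETHNICITIES), len(SEXES), len(AGE_BANDS))
    )
    rates = np.full_like(w, config.overall, dtype=float)
    targets = [
        (0, np.array([eth_t[e] for e in ETHNICITIES])),
        (1, np.array([sex_t[s] for s in SEXES])),
        (2, np.array([band_t[b] for b in AGE_BANDS])),
    ]
    for _ in range(500):
        max_adj = 0.0
        for axis, tvals in targets:
            for k, target in enumerate(tvals):
                sl = [slice(None)] * 3
                sl[axis] = k
                sl = tuple(sl)
                wk = w[sl]
                wsum = wk.sum()
                if wsum <= 0:
                    continue
                cur = float((wk * rates[sl]).sum() / wsum)
                factor = target / cur
                rates[sl] *= factor
                max_adj = max(max_adj, abs(factor - 1.0))
        if max_adj < 1e-15:
            break
    # cells with zero population do not constrain the raking; give them
    # the separable rate implied by the marginals
    zero = np.broadcast_to(w == 0, rates.shape)
    if zero.any():
        sep = (
            np.array([eth_t[e] for e in ETHNICITIES])[:, None, None]
            * np.array([sex_t[s] for s in SEXES])[None, :, None]
            * np.array([band_t[b] for b in AGE_BANDS])[None, None, :]
            / config.overall**2
        )
        rates = np.where(zero, np.clip(sep, 0.0, 1.0), rates)
    if (rates < 0).any() or (rates > 1).any():
        raise InputError("configured ratios produce stratum rates outside [0, 1]")

    rows = [
        (e, s, b, rates[i, j, k])
        for i, e in enumerate(ETHNICITIES)
        for j, s in enumerate(SEXES)
        for k, b in enumerate(AGE_BANDS)
    ]
    table = pd.DataFrame(rows, columns=["ethnicity", "sex", "age_band", "rate"])
    out = UnemploymentBaseline(
        rates=table,
        ethnicity_rates=eth_t,
        sex_rates=sex_t,
        band_rates=band_t,
        overall=config.overall,
    )
    out.validate()
    return out


def _gompertz(ages: np.ndarray, level: float, slope: float, cap: float) -> np.ndarray:
    return np.minimum(level * np.exp(slope * (ages - 60.0)), cap)


def generate_epi_params(config: EpiConfig | None = None, seed: int = 0) -> EpiTable:
    """Generate the per-stratum epidemiology and cost schedule.

    Rates are exponential in age (capped), multiplied by ethnic ratios
    and a male factor, with a small seeded log-normal jitter applied per
    sex so different seeds give different (but structurally identical)
    tables.  The jitter is shared across ethnic groups, so configured
    ethnic ratios hold exactly at every age.
    """
    config = config or EpiConfig()
    slopes = [v for k, v in vars(config).items() if k.endswith("_slope")]
    ratios = [
        config.maori_acm_ratio, config.maori_incidence_ratio,
        config.maori_fatality_ratio, config.maori_prevalence_ratio,
        config.male_factor,
    ]
    if any(s < 0 for s in slopes):
        raise InputError("age slopes must be non-negative")
    if any(r <= 0 for r in ratios):
        raise InputError("group ratios must be positive")

    rng = np.random.default_rng(seed)
    jitter_keys = ["acm", "chd_incidence", "chd_fatality",
                   "stroke_incidence", "stroke_fatality", "bg_cost"]
    sigma = np.sqrt(np.log1p(config.jitter_cv**2))
    jitter = {
        (sex, key): float(np.exp(rng.normal(-sigma**2 / 2, sigma)))
        for sex in SEXES
        for key in jitter_keys
    }

    ages = np.arange(MAX_AGE + 1, dtype=float)
    eth_mult = {
        "acm": {"maori": config.maori_acm_ratio, "non_maori": 1.0},
        "incidence": {"maori": config.maori_incidence_ratio, "non_maori": 1.0},
        "fatality": {"maori": config.maori_fatality_ratio, "non_maori": 1.0},
        "prevalence": {"maori": config.maori_prevalence_ratio, "non_maori": 1.0},
    }
    frames = []
    for eth in ETHNICITIES:
        for sex in SEXES:
            sex_f = config.male_factor if sex == "male" else 1.0
            df = pd.DataFrame({"ethnicity": eth, "sex": sex, "age": ages.astype(int)})
            df["acm"] = np.minimum(
                _gompertz(ages, config.acm_level, config.acm_slope, np.inf)
                * eth_mult["acm"][eth] * sex_f * jitter[(sex, "acm")],
                config.rate_cap,
            )
            for disease in ("chd", "stroke"):
                inc = _gompertz(
                    ages,
                    getattr(config, f"{disease}_incidence_level"),
                    getattr(config, f"{disease}_incidence_slope"),
                    np.inf,
                ) * eth_mult["incidence"][eth] * sex_f * jitter[(sex, f"{disease}_incidence")]
                cf = _gompertz(
                    ages,
                    getattr(config, f"{disease}_fatality_level"),
                    getattr(config, f"{disease}_fatality_slope"),
                    np.inf,
                ) * eth_mult["fatality"][eth] * jitter[(sex, f"{disease}_fatality")]
                prev = np.minimum(
                    _gompertz(
                        ages,
                        getattr(config, f"{disease}_prevalence_level"),
                        getattr(config, f"{disease}_prevalence_slope"),
                        np.inf,
                    ) * eth_mult["prevalence"][eth],
                    config.prevalence_cap,
                )
                df[f"{disease}_incidence"] = np.minimum(inc, config.rate_cap)
                df[f"{disease}_fatality"] = np.minimum(cf, config.fatality_cap)
                df[f"{disease}_prevalence"] = prev
            df["dw_chd"] = config.dw_chd
            df["dw_stroke"] = config.dw_stroke
            df["bg_cost"] = (
                config.bg_cost_level
                * np.exp(config.bg_cost_slope * ages)
                * jitter[(sex, "bg_cost")]
            )
            df["chd_cost"] = config.chd_cost
            df["stroke_cost"] = config.stroke_cost
            frames.append(df)
    out = EpiTable(table=pd.concat(frames, ignore_index=True)[EPI_COLUMNS])
    out.validate()
    return out


def fixture_bundle(
    seed: int = 0,
    *,
    population_config: PopulationConfig | None = None,
    unemployment_config: UnemploymentConfig | None = None,
    epi_config: EpiConfig | None = None,
) -> ModelInputs:
    """A complete default input set, validated and mutually consistent."""
    population = generate_population(population_config, seed=seed)
    unemployment = generate_unemployment_baseline(
        unemployment_config, population, seed=seed
    )
    epi = generate_epi_params(epi_config, seed=seed)
    bundle = ModelInputs(
        population=population,
        unemployment=unemployment,
        epi=epi,
        scenarios=builtin_scenarios(),
        effects=builtin_effects(),
    )
    bundle.validate()
    return bundle


def equalize_ethnic_epi(epi: EpiTable, reference: str = "non_maori") -> EpiTable:
    """Sensitivity switch: give every ethnic group the reference group's
    epidemiology (used for the equity-parameters analysis)."""
    ref = epi.table[epi.table["ethnicity"] == reference]
    frames = []
    for eth in ETHNICITIES:
        block = ref.copy()
        block["ethnicity"] = eth
        frames.append(block)
    table = pd.concat(frames, ignore_index=True)[EPI_COLUMNS]
    return EpiTable(table=table, trends=epi.trends)


# ---------------------------------------------------------------------------
# persistence


def save_bundle(bundle: ModelInputs, directory: str | Path) -> None:
    """Write a bundle to CSV tables plus a YAML metadata file."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    bundle.population.to_csv(d / "population.csv", index=False)
    bundle.unemployment.rates.to_csv(d / "unemployment.csv", index=False)
    bundle.epi.table.to_csv(d / "epi.csv", index=False)
    bundle.effects.to_csv(d / "effects.csv", index=False)
    meta = {
        "unemployment": {
            "overall": float(bundle.unemployment.overall),
            "ethnicity_rates": {k: float(v) for k, v in bundle.unemployment.ethnicity_rates.items()},
            "sex_rates": {k: float(v) for k, v in bundle.unemployment.sex_rates.items()},
            "band_rates": {k: float(v) for k, v in bundle.unemployment.band_rates.items()},
        },
        "trends": {
            "mortality_decline": dict(bundle.epi.trends.mortality_decline),
            "mortality_trend_years": bundle.epi.trends.mortality_trend_years,
            "disease_decline": bundle.epi.trends.disease_decline,
            "disease_trend_frozen": bundle.epi.trends.disease_trend_frozen,
        },
        "unemployment_scale": float(bundle.unemployment_scale),
        "scenarios": {
            name: {
                "rates": [float(r) for r in s.rates],
                "years": list(s.years),
                "baseline_rate": float(s.baseline_rate),
                "duration": s.duration,
            }
            for name, s in bundle.scenarios.items()
        },
    }
    (d / "meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))


def load_bundle(directory: str | Path) -> ModelInputs:
    """Read a bundle previously written by :func:`save_bundle`."""
    d = Path(directory)
    meta = yaml.safe_load((d / "meta.yaml").read_text())
    population = pd.read_csv(d / "population.csv")
    rates = pd.read_csv(d / "unemployment.csv")
    um = meta["unemployment"]
    unemployment = UnemploymentBaseline(
        rates=rates,
        ethnicity_rates=pd.Series(um["ethnicity_rates"]),
        sex_rates=pd.Series(um["sex_rates"]),
        band_rates=pd.Series(um["band_rates"]),
        overall=um["overall"],
    )
    tr = meta["trends"]
    epi = EpiTable(
        table=pd.read_csv(d / "epi.csv"),
        trends=TrendConfig(
            mortality_decline=tr["mortality_decline"],
            mortality_trend_years=tr["mortality_trend_years"],
            disease_decline=tr["disease_decline"],
            disease_trend_frozen=tr["disease_trend_frozen"],
        ),
    )
    scenarios = {
        name: ScenarioDefinition(
            name=name,
            rates=tuple(s["rates"]),
            years=tuple(s["years"]),
            baseline_rate=s["baseline_rate"],
            duration=s["duration"],
        )
        for name, s in meta["scenarios"].items()
    }
    bundle = ModelInputs(
        population=population,
        unemployment=unemployment,
        epi=epi,
        scenarios=scenarios,
        effects=pd.read_csv(d / "effects.csv"),
        unemployment_scale=meta.get("unemployment_scale", 1.0),
    )
    bundle.validate()
    return bundle
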