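"""Proportional multi-state life-table engine.

Every ethnicity x sex x single-year-of-age cohort alive at the model
start is advanced annually to age 110.  Alongside the main life table,
CHD and stroke run as parallel disease processes: each cycle, deaths are
drawn from the start-of-cycle state (background cause-deleted mortality
plus case fatality for prevalent cases, additive across the two
diseases), then survivors acquire disease with the (possibly shocked and
trended) annual incidence.  The deterministic recursion is exactly the
expected-count dynamics of the corresponding individual-level Markov
chain, which is what the microsimulation oracle in the test suite
checks.

Health-adjusted life years accrue as person-years (trapezoidal
half-cycle correction) weighted down by prevalence-weighted disability;
costs accrue as background per-capita costs plus per-prevalent-case
disease costs.  Both are discounted at ``(1 + r)^-t`` with cycle 0 the
model start year.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._common import ETHNICITIES, MAX_AGE, MODEL_BANDS, SEXES, InputError
from .calibration import build_shock_series
from .risk_link import shock_to_rr
from .synthetic_data import EpiTable, ModelInputs, TrendConfig, equalize_ethnic_epi

N_CYCLES = MAX_AGE  # annual cycles: model start to terminal age

_SHOCK_AGE_LO, _SHOCK_AGE_HI = 35, 64


@dataclass(frozen=True)
class EconomicConfig:
    """Discounting, reporting horizons and currency conversion factors."""

    discount_rate: float = 0.03
    horizons: tuple[int, ...] = (5, 10, 20)
    #: multiplicative conversions applied at reporting time
    nz2019_factor: float = 303.0 / 276.0
    usd2019_factor: float = 209.0 / 303.0

    def __post_init__(self) -> None:
        if self.discount_rate < 0:
            raise InputError("discount rate must be non-negative")
        if any(h <= 0 for h in self.horizons):
            raise InputError("horizons must be positive")


def discount_factor(cycle: int, rate: float) -> float:
    """Present value at the model start of one unit accrued at ``cycle``."""
    return (1.0 + rate) ** (-cycle)


# ---------------------------------------------------------------------------
# single-disease process (the standalone three-state view)


def disease_step(state: tuple[float, float, float], i: float, f: float):
    """Advance the (healthy, diseased, dead-of-disease) proportions one year.

    Inflow ``healthy * i`` and outflow ``diseased * f`` are taken from
    start-of-cycle values; remission is zero.  Proportions sum to one.
    """
    if not (0.0 <= i < 1.0 and 0.0 <= f < 1.0):
        raise InputError("incidence and case fatality must lie in [0, 1)")
    h, c, d = state
    return (h * (1.0 - i), c + h * i - c * f, d + c * f)


# ---------------------------------------------------------------------------
# secular trends


def mortality_trend_factor(trends: TrendConfig, ethnicity: str, cycle: int) -> float:
    t = min(cycle, trends.mortality_trend_years)
    return (1.0 - trends.mortality_decline[ethnicity]) ** t


def disease_trend_factor(trends: TrendConfig, cycle: int) -> float:
    if trends.disease_trend_frozen:
        return 1.0
    return (1.0 - trends.disease_decline) ** cycle


def apply_trends(epi: EpiTable, cycle: int) -> EpiTable:
    """Return the epi table as it stands at a given model cycle.

    Background mortality declines per-ethnicity until the trend freeze
    year; disease incidence and case fatality decline at the common
    disease trend (unless frozen for the trend sensitivity analysis).
    """
    if cycle < 0:
        raise InputError("cycle must be non-negative")
    df = epi.table.copy()
    for eth in df["ethnicity"].unique():
        factor = mortality_trend_factor(epi.trends, eth, cycle)
        df.loc[df["ethnicity"] == eth, "acm"] *= factor
    dfac = disease_trend_factor(epi.trends, cycle)
    for col in ("chd_incidence", "chd_fatality", "stroke_incidence", "stroke_fatality"):
        df[col] *= dfac
    return EpiTable(table=df, trends=epi.trends)


# ---------------------------------------------------------------------------
# engine


def _epi_arrays(epi: EpiTable) -> dict[str, np.ndarray]:
    """Reshape the epi table into (ethnicity, sex, age) arrays."""
    df = epi.table.set_index(["ethnicity", "sex", "age"]).sort_index()
    idx = pd.MultiIndex.from_product(
        [ETHNICITIES, SEXES, range(MAX_AGE + 1)], names=["ethnicity", "sex", "age"]
    )
    if not df.index.equals(idx):
        df = df.reindex(idx)
        if df.isna().any().any():
            raise InputError("epi table must cover every stratum and age 0-110")
    shape = (len(ETHNICITIES), len(SEXES), MAX_AGE + 1)
    return {col: df[col].to_numpy().reshape(shape) for col in df.columns}


def _rr_array(rr_table: pd.DataFrame | None) -> np.ndarray:
    """Dense (ethnicity, sex, band, cycle) relative-risk lookup."""
    if rr_table is None or len(rr_table) == 0:
        return np.ones((len(ETHNICITIES), len(SEXES), len(MODEL_BANDS), 0))
    n_cycles = int(rr_table["cycle"].max()) + 1
    arr = np.ones((len(ETHNICITIES), len(SEXES), len(MODEL_BANDS), n_cycles))
    e_ix = {e: i for i, e in enumerate(ETHNICITIES)}
    s_ix = {s: i for i, s in enumerate(SEXES)}
    b_ix = {b: i for i, b in enumerate(MODEL_BANDS)}
    for rec in rr_table.itertuples(index=False):
        arr[e_ix[rec.ethnicity], s_ix[rec.sex], b_ix[rec.age_band], rec.cycle] = rec.rr
    return arr


@dataclass
class LifeTableRun:
    """Trajectories and discounted accruals for every cohort.

    Cohorts are indexed by (ethnicity, sex, age at model start); state
    arrays have shape ``(N_CYCLES + 1, n_cohorts)`` (snapshots at cycle
    starts) and accrual arrays ``(N_CYCLES, n_cohorts)``.
    """

    eth_idx: np.ndarray
    sex_idx: np.ndarray
    age0: np.ndarray
    alive: np.ndarray
    chd_prevalent: np.ndarray
    stroke_prevalent: np.ndarray
    deaths: np.ndarray
    deaths_chd: np.ndarray
    deaths_stroke: np.ndarray
    life_years: np.ndarray
    haly: np.ndarray  # discounted
    cost: np.ndarray  # discounted
    econ: EconomicConfig

    @property
    def initial(self) -> np.ndarray:
        return self.alive[0]

    def cumulative(self, field_name: str, horizon: int | str = "lifetime") -> np.ndarray:
        """Per-cohort accrual summed over the first ``horizon`` cycles."""
        arr = getattr(self, field_name)
        if horizon == "lifetime":
            return arr.sum(axis=0)
        if not (isinstance(horizon, (int, np.integer)) and 0 < horizon <= N_CYCLES):
            raise InputError(f"invalid horizon {horizon!r}")
        return arr[:horizon].sum(axis=0)

    def cohort_mask(
        self, ethnicity: str = "all", sex: str = "all", age_band: str = "all"
    ) -> np.ndarray:
        """Boolean mask over cohorts by baseline (model-start) attributes.

        ``age_band='all'`` means the modelled working bands 35-64.
        """
        mask = np.ones(len(self.age0), dtype=bool)
        if ethnicity != "all":
            mask &= self.eth_idx == ETHNICITIES.index(ethnicity)
        if sex != "all":
            mask &= self.sex_idx == SEXES.index(sex)
        if age_band == "all":
            mask &= (self.age0 >= _SHOCK_AGE_LO) & (self.age0 <= _SHOCK_AGE_HI)
        else:
            lo, hi = int(age_band[:2]), int(age_band[-2:])
            mask &= (self.age0 >= lo) & (self.age0 <= hi)
        return mask


def run_cohort(
    bundle: ModelInputs,
    rr_table: pd.DataFrame | None = None,
    econ: EconomicConfig | None = None,
) -> LifeTableRun:
    """Run the full life table for every stratum cohort.

    ``rr_table`` carries per-cycle incidence relative risks from
    :func:`cvdshock.risk_link.shock_to_rr`; ``None`` runs the
    no-shock counterfactual.
    """
    econ = econ or EconomicConfig()
    arr = _epi_arrays(bundle.epi)
    rr_arr = _rr_array(rr_table)
    n_shock_cycles = rr_arr.shape[-1]
    trends = bundle.epi.trends

    # background mortality with the disease contribution removed, so that
    # adding prevalence-weighted case fatality back reproduces all-cause
    # mortality at baseline prevalence
    m_bg = np.clip(
        arr["acm"]
        - arr["chd_prevalence"] * arr["chd_fatality"]
        - arr["stroke_prevalence"] * arr["stroke_fatality"],
        0.0,
        None,
    )

    pop = bundle.population.set_index(["ethnicity", "sex", "age"])["count"]
    cohorts = [
        (ei, si, a)
        for ei, e in enumerate(ETHNICITIES)
        for si, s in enumerate(SEXES)
        for a in range(MAX_AGE + 1)
    ]
    eth_idx = np.array([c[0] for c in cohorts])
    sex_idx = np.array([c[1] for c in cohorts])
    age0 = np.array([c[2] for c in cohorts])
    n0 = np.array(
        [pop.loc[(ETHNICITIES[ei], SEXES[si], a)] for ei, si, a in cohorts],
        dtype=float,
    )
    if (n0 < 0).any():
        raise InputError("negative population counts")

    k = len(cohorts)
    p_chd = arr["chd_prevalence"][eth_idx, sex_idx, age0]
    p_str = arr["stroke_prevalence"][eth_idx, sex_idx, age0]
    n_b = n0 * p_chd * p_str
    n_c = n0 * p_chd * (1.0 - p_str)
    n_s = n0 * p_str * (1.0 - p_chd)
    n_h = n0 - n_b - n_c - n_s
    # cohorts already at the terminal age contribute nothing
    at_term = age0 >= MAX_AGE
    for state in (n_h, n_c, n_s, n_b):
        state[at_term] = 0.0

    alive = np.zeros((N_CYCLES + 1, k))
    chd_prev = np.zeros((N_CYCLES + 1, k))
    str_prev = np.zeros((N_CYCLES + 1, k))
    deaths = np.zeros((N_CYCLES, k))
    deaths_chd = np.zeros((N_CYCLES, k))
    deaths_str = np.zeros((N_CYCLES, k))
    life_years = np.zeros((N_CYCLES, k))
    haly = np.zeros((N_CYCLES, k))
    cost = np.zeros((N_CYCLES, k))

    alive[0] = n_h + n_c + n_s + n_b
    chd_prev[0] = n_c + n_b
    str_prev[0] = n_s + n_b

    mort_decline = np.array(
        [trends.mortality_decline[e] for e in ETHNICITIES]
    )[eth_idx]

    for t in range(N_CYCLES):
        ages = np.minimum(age0 + t, MAX_AGE)
        gather = (eth_idx, sex_idx, ages)

        mt = min(t, trends.mortality_trend_years)
        m = m_bg[gather] * (1.0 - mort_decline) ** mt
        dfac = disease_trend_factor(trends, t)
        i_chd = arr["chd_incidence"][gather] * dfac
        i_str = arr["stroke_incidence"][gather] * dfac
        f_chd = arr["chd_fatality"][gather] * dfac
        f_str = arr["stroke_fatality"][gather] * dfac

        if n_shock_cycles and t < n_shock_cycles:
            in_band = (ages >= _SHOCK_AGE_LO) & (ages <= _SHOCK_AGE_HI)
            band = np.clip((ages - _SHOCK_AGE_LO) // 10, 0, len(MODEL_BANDS) - 1)
            rr = np.where(in_band, rr_arr[eth_idx, sex_idx, band, t], 1.0)
            i_chd = i_chd * rr
            i_str = i_str * rr
        i_chd = np.clip(i_chd, 0.0, 1.0)
        i_str = np.clip(i_str, 0.0, 1.0)

        q_h = np.clip(m, 0.0, 1.0)
        q_c = np.clip(m + f_chd, 0.0, 1.0)
        q_s = np.clip(m + f_str, 0.0, 1.0)
        q_b = np.clip(m + f_chd + f_str, 0.0, 1.0)

        sh = n_h * (1.0 - q_h)
        sc = n_c * (1.0 - q_c)
        ss = n_s * (1.0 - q_s)
        sb = n_b * (1.0 - q_b)

        deaths[t] = n_h * q_h + n_c * q_c + n_s * q_s + n_b * q_b
        deaths_chd[t] = (n_c + n_b) * f_chd
        deaths_str[t] = (n_s + n_b) * f_str

        # acquisition among survivors (independent per disease)
        nh2 = sh * (1.0 - i_chd) * (1.0 - i_str)
        nc2 = sc * (1.0 - i_str) + sh * i_chd * (1.0 - i_str)
        ns2 = ss * (1.0 - i_chd) + sh * i_str * (1.0 - i_chd)
        nb2 = sb + sc * i_str + ss * i_chd + sh * i_chd * i_str

        n_start = n_h + n_c + n_s + n_b
        n_end = nh2 + nc2 + ns2 + nb2
        c_start, c_end = n_c + n_b, nc2 + nb2
        s_start, s_end = n_s + n_b, ns2 + nb2
        n_bar = 0.5 * (n_start + n_end)
        c_bar = 0.5 * (c_start + c_end)
        s_bar = 0.5 * (s_start + s_end)

        df_t = discount_factor(t, econ.discount_rate)
        life_years[t] = n_bar
        haly[t] = df_t * (
            n_bar - arr["dw_chd"][gather] * c_bar - arr["dw_stroke"][gather] * s_bar
        )
        cost[t] = df_t * (
            arr["bg_cost"][gather] * n_bar
            + arr["chd_cost"][gather] * c_bar
            + arr["stroke_cost"][gather] * s_bar
        )

        # cohorts reaching the terminal age exit after this cycle's accrual
        terminal = (age0 + t) == (MAX_AGE - 1)
        if terminal.any():
            deaths[t][terminal] += n_end[terminal]
            nh2[terminal] = nc2[terminal] = ns2[terminal] = nb2[terminal] = 0.0

        n_h, n_c, n_s, n_b = nh2, nc2, ns2, nb2
        alive[t + 1] = n_h + n_c + n_s + n_b
        chd_prev[t + 1] = n_c + n_b
        str_prev[t + 1] = n_s + n_b

    return LifeTableRun(
        eth_idx=eth_idx,
        sex_idx=sex_idx,
        age0=age0,
        alive=alive,
        chd_prevalent=chd_prev,
        stroke_prevalent=str_prev,
        deaths=deaths,
        deaths_chd=deaths_chd,
        deaths_stroke=deaths_str,
        life_years=life_years,
        haly=haly,
        cost=cost,
        econ=econ,
    )


# ---------------------------------------------------------------------------
# differencing and orchestration

_REPORT_GROUPS = (
    [("all", "all", "all")]
    + [(e, "all", "all") for e in ETHNICITIES]
    + [(e, s, "all") for e in ETHNICITIES for s in SEXES]
    + [(e, s, b) for e in ETHNICITIES for s in SEXES for b in MODEL_BANDS]
)


def diff_outputs(
    scenario_run: LifeTableRun, baseline_run: LifeTableRun
) -> pd.DataFrame:
    """Scenario-minus-baseline HALY and cost changes by group and horizon.

    Negative HALY changes are losses; positive cost changes are
    additional costs.  Groups are keyed by baseline (model-start)
    ethnicity, sex and age band; ``'all'`` rows aggregate ages 35-64.
    """
    if scenario_run.econ != baseline_run.econ:
        raise InputError("runs must share an economic configuration")
    if not np.array_equal(scenario_run.age0, baseline_run.age0):
        raise InputError("runs must share cohort strata")
    horizons: list[int | str] = [*scenario_run.econ.horizons, "lifetime"]
    rows = []
    for eth, sex, band in _REPORT_GROUPS:
        mask = scenario_run.cohort_mask(eth, sex, band)
        population = float(scenario_run.initial[mask].sum())
        for horizon in horizons:
            d_haly = float(
                scenario_run.cumulative("haly", horizon)[mask].sum()
                - baseline_run.cumulative("haly", horizon)[mask].sum()
            )
            d_cost = float(
                scenario_run.cumulative("cost", horizon)[mask].sum()
                - baseline_run.cumulative("cost", horizon)[mask].sum()
            )
            rows.append(
                {
                    "ethnicity": eth,
                    "sex": sex,
                    "age_band": band,
                    "horizon": str(horizon),
                    "population": population,
                    "haly_change": d_haly,
                    "cost_change": d_cost,
                    "haly_per_1000": 1000.0 * d_haly / population if population else np.nan,
                    "cost_per_1000": 1000.0 * d_cost / population if population else np.nan,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class AnalysisResult:
    scenario_run: LifeTableRun
    baseline_run: LifeTableRun
    outputs: pd.DataFrame


def run_analysis(
    bundle: ModelInputs,
    scenario_name: str,
    econ: EconomicConfig | None = None,
    *,
    duration: int | None = None,
    extension: str = "hold_last",
    rr_mode: str = "relative",
    equity_params: bool = False,
    freeze_disease_trend: bool = False,
) -> AnalysisResult:
    """End-to-end run of one scenario against the no-shock counterfactual.

    The keyword switches select the sensitivity analyses: equalised
    ethnic epidemiology, 10-year shock duration, frozen disease trend,
    and (through ``econ``) alternative discount rates.
    """
    econ = econ or EconomicConfig()
    if scenario_name not in bundle.scenarios:
        raise InputError(f"unknown scenario {scenario_name!r}")
    epi = bundle.epi
    if equity_params:
        epi = equalize_ethnic_epi(epi)
    if freeze_disease_trend:
        epi = EpiTable(
            table=epi.table, trends=replace(epi.trends, disease_trend_frozen=True)
        )
    work = replace(bundle, epi=epi)

    scenario = bundle.scenarios[scenario_name]
    shock = build_shock_series(
        work.population,
        work.unemployment,
        scenario,
        duration=duration,
        extension=extension,
        scale=work.unemployment_scale,
    )
    rr_table = shock_to_rr(shock, work.unemployment, work.effects, mode=rr_mode)
    scenario_run = run_cohort(work, rr_table, econ)
    baseline_run = run_cohort(work, None, econ)
    return AnalysisResult(
        scenario_run=scenario_run,
        baseline_run=baseline_run,
        outputs=diff_outputs(scenario_run, baseline_run),
    )
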