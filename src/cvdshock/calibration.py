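"""Disaggregation of aggregate unemployment-rate changes into strata.

An aggregate absolute change ``dU`` is split across groups so that

* the pre-shock relative rates are preserved:
  ``dU_g / dU_h = U_g / U_h`` for every pair of groups, and
* the population-weighted mean of the group changes equals the
  aggregate change.

These two constraints have the unique solution

    dU_g = dU * U_g * N_total / sum_h(pop_h * U_h)

which is applied per axis (ethnicity, sex, age band) and combined
multiplicatively for the full ethnicity x sex x age cross-classification,
with sex and age patterns taken from the general population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._common import AGE_BANDS, ETHNICITIES, MODEL_BANDS, REFERENCE_BAND, SEXES, InputError, band_of_age
from .scenarios import (
    DEFAULT_MODEL_START_YEAR,
    ScenarioDefinition,
    map_to_model_years,
    scenario_increments,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RateWeights:
    """Relative unemployment-rate weights by axis.

    ``w_e`` is the Maori/non-Maori rate ratio, ``w_s`` the female/male
    ratio, and ``w_a`` maps each working-age band to its rate relative
    to the 45-54 reference band.
    """

    w_e: float
    w_s: float
    w_a: dict[str, float]

    def __post_init__(self) -> None:
        vals = [self.w_e, self.w_s, *self.w_a.values()]
        if any(not np.isfinite(v) or v <= 0 for v in vals):
            raise InputError("rate weights must be positive and finite")


def derive_weights(baseline) -> RateWeights:
    """Compute the axis weights from marginal pre-pandemic rates."""
    eth = baseline.ethnicity_rates
    sex = baseline.sex_rates
    band = baseline.band_rates
    for name, series in (("ethnicity", eth), ("sex", sex), ("age-band", band)):
        if (series <= 0).any():
            raise InputError(f"all {name} baseline rates must be positive")
    ref = band[REFERENCE_BAND]
    return RateWeights(
        w_e=eth["maori"] / eth["non_maori"],
        w_s=sex["female"] / sex["male"],
        w_a={b: band[b] / ref for b in band.index},
    )


def disaggregate_one_axis(
    du_overall: float, groups: Sequence[tuple[float, float]]
) -> list[float]:
    """Split an aggregate change across one axis of (population, rate) groups.

    Returns the per-group absolute changes ``dU_g`` satisfying ratio
    preservation and population-weighted conservation.
    """
    pops = np.asarray([g[0] for g in groups], dtype=float)
    rates = np.asarray([g[1] for g in groups], dtype=float)
    if len(groups) == 0:
        raise InputError("at least one group required")
    if (pops < 0).any():
        raise InputError("populations must be non-negative")
    total = pops.sum()
    if total <= 0:
        raise InputError("total population must be positive")
    if (rates <= 0).any():
        raise InputError("all group baseline rates must be positive")
    denom = float(pops @ rates)
    return list(du_overall * rates * total / denom)


def disaggregate_full(
    du_overall: float,
    population: pd.DataFrame,
    baseline,
    year: int,
    *,
    clip: bool = True,
) -> pd.DataFrame:
    """Cross-classified absolute changes for every ethnicity x sex x band cell.

    Cell changes are multiplicative-separable in the marginal rates
    (sex and age patterns follow the general population, not each
    ethnicity) and renormalised so the population-weighted mean over all
    working-age cells equals ``du_overall``.

    Returns a frame with columns (ethnicity, sex, age_band, year, du)
    covering all five working-age bands; use
    :func:`restrict_to_model_bands` for the bands fed into the model.
    """
    pops = band_populations(population)
    u_e = baseline.ethnicity_rates
    u_s = baseline.sex_rates
    u_b = baseline.band_rates
    if (u_e <= 0).any() or (u_s <= 0).any() or (u_b <= 0).any():
        raise InputError("all marginal baseline rates must be positive")
    n_total = pops["count"].sum()
    if n_total <= 0:
        raise InputError("total working-age population must be positive")

    score = (
        pops["ethnicity"].map(u_e).to_numpy()
        * pops["sex"].map(u_s).to_numpy()
        * pops["age_band"].map(u_b).to_numpy()
    )
    z = float(pops["count"].to_numpy() @ score) / n_total
    du = du_overall * score / z

    out = pops[["ethnicity", "sex", "age_band"]].copy()
    out["year"] = year
    out["du"] = du

    base = baseline.rates.set_index(["ethnicity", "sex", "age_band"])["rate"]
    keys = list(zip(out["ethnicity"], out["sex"], out["age_band"]))
    rates = np.array([base.loc[k] for k in keys])
    shifted = rates + out["du"].to_numpy()
    bad = (shifted < 0) | (shifted > 1)
    if bad.any():
        if not clip:
            raise InputError("disaggregated change pushes a stratum rate outside [0, 1]")
        logger.warning(
            "clipping %d stratum increments that leave [0, 1]", int(bad.sum())
        )
        out.loc[bad, "du"] = np.clip(shifted[bad], 0.0, 1.0) - rates[bad]
    return out


def restrict_to_model_bands(deltas: pd.DataFrame) -> pd.DataFrame:
    """Keep only the 35-44 / 45-54 / 55-64 bands the model consumes."""
    return deltas[deltas["age_band"].isin(MODEL_BANDS)].reset_index(drop=True)


def band_populations(population: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a single-year population table to working-age bands."""
    df = population.copy()
    df["age_band"] = df["age"].map(lambda a: band_of_age(int(a)))
    df = df.dropna(subset=["age_band"])
    out = (
        df.groupby(["ethnicity", "sex", "age_band"], as_index=False)["count"]
        .sum()
    )
    # guarantee every cell exists
    full = pd.MultiIndex.from_product(
        [ETHNICITIES, SEXES, AGE_BANDS], names=["ethnicity", "sex", "age_band"]
    )
    out = (
        out.set_index(["ethnicity", "sex", "age_band"])
        .reindex(full, fill_value=0.0)
        .reset_index()
    )
    return out


def build_shock_series(
    population: pd.DataFrame,
    baseline,
    scenario: ScenarioDefinition,
    *,
    model_start_year: int = DEFAULT_MODEL_START_YEAR,
    duration: int | None = None,
    extension: str = "hold_last",
    scale: float = 1.0,
) -> pd.DataFrame:
    """Full shock series for a scenario: one stratified delta set per cycle.

    Returns a frame with columns (cycle, year, ethnicity, sex, age_band,
    du), restricted to the model bands.  ``scale`` multiplies every
    aggregate increment (used by the uncertainty engine).
    """
    duration = scenario.duration if duration is None else duration
    increments = scenario_increments(scenario)
    profile = map_to_model_years(
        increments, model_start_year, duration=duration, extension=extension
    )
    frames = []
    for cycle, inc in enumerate(profile):
        inc = inc * scale
        if inc == 0.0:
            continue
        deltas = disaggregate_full(
            inc, population, baseline, year=model_start_year + cycle
        )
        deltas = restrict_to_model_bands(deltas)
        deltas.insert(0, "cycle", cycle)
        frames.append(deltas)
    if not frames:
        return pd.DataFrame(
            columns=["cycle", "ethnicity", "sex", "age_band", "year", "du"]
        )
    return pd.concat(frames, ignore_index=True)
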