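"""Link between unemployment increments and CVD incidence relative risks.

Effect sizes are expressed as the percent change in annual CVD incidence
per 1% *relative* increase in the unemployment rate, by sex and age band,
and scale linearly with the size of the relative increase:

    rr = 1 + (beta / 100) * relative_increase_pct

The same relative risk is applied to CHD and stroke incidence; case
fatality and background mortality are never touched.
"""

from __future__ import annotations

import pandas as pd

from ._common import MODEL_BANDS, InputError, band_of_age

#: Effect-size age bands (these do not coincide with the model bands).
EFFECT_BANDS = ("35-44", "45-59", "60-64")

#: Nearest-band mapping from model age bands to effect-size bands.
MODEL_TO_EFFECT_BAND = {"35-44": "35-44", "45-54": "45-59", "55-64": "60-64"}

_BUILTIN_EFFECTS = [
    # sex, band, beta (%), ci_low, ci_high
    ("female", "35-44", -0.14, -1.95, 1.67),
    ("female", "45-59", 0.10, -1.09, 1.30),
    ("female", "60-64", 0.23, -0.22, 0.68),
    ("male", "35-44", 0.85, 0.06, 1.64),
    ("male", "45-59", 0.48, -0.06, 1.02),
    ("male", "60-64", 0.38, -0.16, 0.91),
]


def builtin_effects() -> pd.DataFrame:
    """The six built-in sex-by-age effect sizes with 95% CIs."""
    df = pd.DataFrame(
        _BUILTIN_EFFECTS, columns=["sex", "age_band", "beta", "ci_low", "ci_high"]
    )
    return df


def validate_effects(effects: pd.DataFrame) -> None:
    required = {"sex", "age_band", "beta", "ci_low", "ci_high"}
    missing = required - set(effects.columns)
    if missing:
        raise InputError(f"effects table missing columns: {sorted(missing)}")
    if ((effects["ci_low"] > effects["beta"]) | (effects["beta"] > effects["ci_high"])).any():
        raise InputError("effects must satisfy ci_low <= beta <= ci_high")


def effect_for(effects: pd.DataFrame, sex: str, model_band: str) -> pd.Series:
    """Look up the effect row for a model stratum (nearest effect band)."""
    band = MODEL_TO_EFFECT_BAND.get(model_band)
    if band is None:
        raise InputError(f"no effect band mapped for model band {model_band!r}")
    rows = effects[(effects["sex"] == sex) & (effects["age_band"] == band)]
    if len(rows) != 1:
        raise InputError(f"expected one effect row for ({sex}, {band}), got {len(rows)}")
    return rows.iloc[0]


def relative_increase(du: float, baseline_rate: float) -> float:
    """Percent relative increase implied by an absolute increment ``du``."""
    if baseline_rate <= 0:
        raise InputError("baseline unemployment rate must be positive")
    return 100.0 * du / baseline_rate


def incidence_rr(beta: float, rel_increase_pct: float) -> float:
    """Relative risk on annual CVD incidence under the linear scaling rule."""
    rr = 1.0 + (beta / 100.0) * rel_increase_pct
    if rr <= 0:
        raise InputError(f"pathological inputs: implied rr = {rr:.4g} <= 0")
    return rr


def shock_to_rr(
    shock: pd.DataFrame,
    baseline,
    effects: pd.DataFrame | None = None,
    *,
    mode: str = "relative",
    rr_floor: float = 1e-3,
) -> pd.DataFrame:
    """Convert a stratified shock series into per-stratum incidence RRs.

    Parameters
    ----------
    shock:
        Frame with columns (cycle, ethnicity, sex, age_band, du) as
        produced by :func:`cvdshock.calibration.build_shock_series`.
    baseline:
        An :class:`~cvdshock.synthetic_data.UnemploymentBaseline`; each
        stratum's increment is divided by its own pre-pandemic rate.
    mode:
        ``'relative'`` (default) interprets the effect size per 1%
        relative increase; ``'percentage_point'`` is the alternative
        reading, per 1 percentage-point absolute increase.
    rr_floor:
        Incidence cannot be negative, but the linear scaling rule
        extrapolated to large relative increases with strongly negative
        (e.g. Monte-Carlo sampled) effect sizes can cross zero; such
        draws are floored at this positive value.
    """
    if effects is None:
        effects = builtin_effects()
    validate_effects(effects)
    if mode not in ("relative", "percentage_point"):
        raise InputError("mode must be 'relative' or 'percentage_point'")

    base = baseline.rates.set_index(["ethnicity", "sex", "age_band"])["rate"]
    rows = []
    for rec in shock.itertuples(index=False):
        if rec.age_band not in MODEL_BANDS:
            continue
        key = (rec.ethnicity, rec.sex, rec.age_band)
        if key not in base.index:
            raise InputError(f"no baseline unemployment rate for stratum {key}")
        if mode == "relative":
            rel = relative_increase(rec.du, base.loc[key])
        else:
            rel = 100.0 * rec.du  # percentage points
        beta = effect_for(effects, rec.sex, rec.age_band)["beta"]
        rr = max(1.0 + (beta / 100.0) * rel, rr_floor)
        rows.append((rec.cycle, rec.ethnicity, rec.sex, rec.age_band, rr))
    return pd.DataFrame(rows, columns=["cycle", "ethnicity", "sex", "age_band", "rr"])


def apply_shock(epi, rr_table: pd.DataFrame, cycle: int):
    """Return a copy of an epi table with incidence scaled by the cycle RRs.

    Only CHD and stroke incidence at ages 35-64 are touched; case
    fatality, prevalence, mortality, disability and costs pass through
    unchanged.  This is the single-cycle view used by tests; the
    life-table engine applies the same multiplication internally.
    """
    from .synthetic_data import EpiTable  # local import avoids a cycle

    sub = rr_table[rr_table["cycle"] == cycle]
    lookup = sub.set_index(["ethnicity", "sex", "age_band"])["rr"]
    df = epi.table.copy()
    bands = df["age"].map(lambda a: band_of_age(int(a)))
    for key, rr in lookup.items():
        eth, sex, band = key
        mask = (df["ethnicity"] == eth) & (df["sex"] == sex) & (bands == band)
        df.loc[mask, ["chd_incidence", "stroke_incidence"]] *= rr
    return EpiTable(table=df, trends=epi.trends)
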