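"""Monte-Carlo propagation of parameter uncertainty.

Uncertain multiplicative quantities (aggregate unemployment increments,
disease incidence and case fatality, costs) are perturbed by log-normal
factors parameterised to have mean one and a coefficient of variation
equal to the stated percentage SD, so central estimates are preserved.
Effect sizes are sampled additively on their natural percent scale from
the normal distribution implied by their printed 95% CI (a log-normal is
impossible for sign-crossing intervals).

Every draw is deterministic given ``(seed, draw_index)`` and draws share
no mutable state, so they are independent and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._common import InputError
from .mslt import EconomicConfig, run_analysis
from .synthetic_data import EpiTable, ModelInputs

_Z95 = 1.959964


@dataclass(frozen=True)
class UncertaintyConfig:
    n_draws: int = 2000
    seed: int = 0
    unemployment_cv: float = 0.20
    disease_cv: float = 0.05
    cost_cv: float = 0.10
    level: float = 0.95

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise InputError("n_draws must be at least 1")
        if min(self.unemployment_cv, self.disease_cv, self.cost_cv) < 0:
            raise InputError("coefficients of variation must be non-negative")
        if not 0.0 < self.level < 1.0:
            raise InputError("interval level must lie in (0, 1)")


def lognormal_factor(rng: np.random.Generator, cv: float, size=None) -> np.ndarray | float:
    """Log-normal multiplicative factor with mean 1 and the given CV."""
    if cv < 0:
        raise InputError("cv must be non-negative")
    sigma2 = np.log1p(cv * cv)
    draw = rng.normal(-sigma2 / 2.0, np.sqrt(sigma2), size)
    return np.exp(draw)


def beta_sd_from_ci(ci_low: float, ci_high: float) -> float:
    """Normal SD implied by a printed 95% confidence interval."""
    return (ci_high - ci_low) / (2.0 * _Z95)


def sample_parameters(
    bundle: ModelInputs, cfg: UncertaintyConfig, draw_index: int
) -> ModelInputs:
    """One perturbed copy of the input bundle (the base bundle is untouched)."""
    rng = np.random.default_rng([cfg.seed, draw_index])
    # fixed draw order keeps results reproducible as config SDs change
    u_factor = float(lognormal_factor(rng, cfg.unemployment_cv))
    inc_factor = float(lognormal_factor(rng, cfg.disease_cv))
    cf_factor = float(lognormal_factor(rng, cfg.disease_cv))
    cost_factor = float(lognormal_factor(rng, cfg.cost_cv))
    z = rng.standard_normal(len(bundle.effects))

    epi_df = bundle.epi.table.copy()
    for col in ("chd_incidence", "stroke_incidence"):
        epi_df[col] = np.clip(epi_df[col] * inc_factor, 0.0, 1.0)
    for col in ("chd_fatality", "stroke_fatality"):
        epi_df[col] = np.clip(epi_df[col] * cf_factor, 0.0, 0.99)
    for col in ("bg_cost", "chd_cost", "stroke_cost"):
        epi_df[col] = epi_df[col] * cost_factor

    effects = bundle.effects.copy()
    sds = np.array(
        [beta_sd_from_ci(lo, hi) for lo, hi in zip(effects["ci_low"], effects["ci_high"])]
    )
    effects["beta"] = effects["beta"].to_numpy() + sds * z
    # keep the stored CI bracketing the sampled central value
    effects["ci_low"] = np.minimum(effects["ci_low"], effects["beta"])
    effects["ci_high"] = np.maximum(effects["ci_high"], effects["beta"])

    return replace(
        bundle,
        epi=EpiTable(table=epi_df, trends=bundle.epi.trends),
        effects=effects,
        unemployment_scale=bundle.unemployment_scale * u_factor,
    )


def run_monte_carlo(
    bundle: ModelInputs,
    scenario_name: str,
    cfg: UncertaintyConfig,
    econ: EconomicConfig | None = None,
    **run_options,
) -> pd.DataFrame:
    """Draw-level output bundles: one full model run per parameter draw.

    Returns the concatenation of per-draw difference tables with a
    ``draw`` column.  Each draw perturbs the epidemiology, costs, effect
    sizes and aggregate shock size, then runs scenario and counterfactual
    with the same perturbed parameters.
    """
    frames = []
    for d in range(cfg.n_draws):
        perturbed = sample_parameters(bundle, cfg, d)
        result = run_analysis(perturbed, scenario_name, econ, **run_options)
        out = result.outputs
        out.insert(0, "draw", d)
        frames.append(out)
    return pd.concat(frames, ignore_index=True)


def summarize_ui(draws, level: float = 0.95):
    """Empirical mean and central percentile interval of a draw vector.

    With a single draw the point estimate is returned and the interval
    is undefined (``(nan, nan)``).
    """
    values = np.asarray(draws, dtype=float)
    if values.size == 0:
        raise InputError("cannot summarize an empty draw set")
    mean = float(values.mean())
    if values.size < 2:
        return mean, (float("nan"), float("nan"))
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(values, [alpha, 1.0 - alpha])
    return mean, (float(lo), float(hi))


def summarize_outputs(draws_df: pd.DataFrame, level: float = 0.95) -> pd.DataFrame:
    """Per-cell mean and uncertainty interval across Monte-Carlo draws."""
    if "draw" not in draws_df.columns:
        raise InputError("expected a draw-level frame with a 'draw' column")
    rows = []
    keys = ["ethnicity", "sex", "age_band", "horizon"]
    for key, grp in draws_df.groupby(keys, sort=False):
        rec = dict(zip(keys, key))
        rec["population"] = float(grp["population"].iloc[0])
        for col in ("haly_change", "cost_change", "haly_per_1000", "cost_per_1000"):
            mean, (lo, hi) = summarize_ui(grp[col].to_numpy(), level)
            rec[f"{col}_mean"] = mean
            rec[f"{col}_lo"] = lo
            rec[f"{col}_hi"] = hi
        rows.append(rec)
    return pd.DataFrame(rows)
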