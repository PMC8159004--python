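"""Treasury-style unemployment projection scenarios.

Each scenario is a short series of projected aggregate unemployment rates
for calendar years 2020-2024, compared against a constant pre-pandemic
baseline rate (4%).  Scenario increments are mapped onto model cycles
(the cohort model starts in 2011, so calendar year 2020+k lands on
cycle k, i.e. model year 2011+k).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._common import InputError

SCENARIO_YEARS = (2020, 2021, 2022, 2023, 2024)
BASELINE_RATE = 0.04
DEFAULT_MODEL_START_YEAR = 2011


@dataclass(frozen=True)
class ScenarioDefinition:
    """An aggregate unemployment projection over the five scenario years.

    Parameters
    ----------
    name:
        Scenario identifier.
    rates:
        Projected aggregate unemployment rates (proportions), one per
        year in ``years``.
    baseline_rate:
        The counterfactual no-pandemic rate, constant across years.
    duration:
        Number of model years the shock persists (5 default, 10 for the
        long-shock sensitivity analysis).
    """

    name: str
    rates: tuple[float, ...]
    years: tuple[int, ...] = SCENARIO_YEARS
    baseline_rate: float = BASELINE_RATE
    duration: int = 5

    def __post_init__(self) -> None:
        if len(self.rates) != len(self.years):
            raise InputError("rates and years must have equal length")
        if any(not 0.0 <= r <= 1.0 for r in self.rates):
            raise InputError("scenario rates must lie in [0, 1]")
        if not 0.0 <= self.baseline_rate <= 1.0:
            raise InputError("baseline rate must lie in [0, 1]")
        if self.duration not in (5, 10):
            raise InputError("shock duration must be 5 or 10 years")

    def rate_for(self, year: int) -> float:
        try:
            return self.rates[self.years.index(year)]
        except ValueError:
            raise InputError(f"year {year} outside scenario grid") from None


def builtin_scenarios() -> dict[str, ScenarioDefinition]:
    """The built-in projection set: a flat baseline plus four shocks."""
    mk = ScenarioDefinition
    flat = (BASELINE_RATE,) * 5
    return {
        "baseline": mk("baseline", flat),
        "base_case": mk("base_case", (0.053, 0.077, 0.076, 0.066, 0.053)),
        "early_recovery": mk("early_recovery", (0.053, 0.077, 0.064, 0.055, 0.048)),
        "extended_border": mk("extended_border", (0.053, 0.077, 0.081, 0.076, 0.066)),
        "resurgence": mk("resurgence", (0.053, 0.090, 0.085, 0.073, 0.058)),
    }


def scenario_increments(
    scenario: ScenarioDefinition, *, floor_at_zero: bool = False
) -> dict[int, float]:
    """Aggregate absolute unemployment-rate increments over the baseline.

    Returns a mapping from calendar year to ``rate - baseline_rate``.
    ``floor_at_zero`` clips negative increments (off by default; all
    built-in scenarios are non-negative anyway).
    """
    out = {}
    for year, rate in zip(scenario.years, scenario.rates):
        inc = rate - scenario.baseline_rate
        if floor_at_zero:
            inc = max(inc, 0.0)
        out[year] = inc
    return out


def map_to_model_years(
    increments: dict[int, float],
    model_start_year: int = DEFAULT_MODEL_START_YEAR,
    *,
    duration: int = 5,
    extension: str = "hold_last",
) -> np.ndarray:
    """Map calendar-year increments onto model cycles.

    Calendar year ``2020 + k`` maps to model cycle ``k`` (model year
    ``model_start_year + k``).  For ``duration`` longer than the
    projected series the profile is extended either by holding the final
    increment (``extension='hold_last'``) or by repeating the whole
    profile (``extension='repeat'``).  Cycles at or beyond ``duration``
    carry zero shock (the returned array has length ``duration``).
    """
    if extension not in ("hold_last", "repeat"):
        raise InputError("extension must be 'hold_last' or 'repeat'")
    years = sorted(increments)
    profile = [increments[y] for y in years]
    out = np.zeros(duration)
    for k in range(duration):
        if k < len(profile):
            out[k] = profile[k]
        elif extension == "hold_last":
            out[k] = profile[-1]
        else:
            out[k] = profile[k % len(profile)]
    return out
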