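"""Independent oracles used by the unit and acceptance tests.

These deliberately re-derive expected results by a different route than
the package (linear-system solves, stochastic individual-level
simulation) and must stay decoupled from the implementation they check.
"""

from __future__ import annotations

import numpy as np


def solve_axis_deltas(du_overall: float, pops, rates) -> np.ndarray:
    """Brute-force linear solve of the disaggregation constraints.

    Unknowns x_g satisfy ratio preservation ``x_g * U_0 = x_0 * U_g``
    for g >= 1 and population-weighted conservation
    ``sum(pop_g x_g) / sum(pop_g) = du_overall``.
    """
    pops = np.asarray(pops, dtype=float)
    rates = np.asarray(rates, dtype=float)
    n = len(pops)
    a = np.zeros((n, n))
    b = np.zeros(n)
    for g in range(1, n):
        a[g - 1, 0] = rates[g]
        a[g - 1, g] = -rates[0]
    a[n - 1] = pops / pops.sum()
    b[n - 1] = du_overall
    return np.linalg.solve(a, b)


def three_state_microsim(
    n: int, cycles: int, incidence: float, fatality: float, seed: int
) -> np.ndarray:
    """Simulate the healthy/diseased/dead-of-disease chain for n individuals.

    Returns the diseased *proportion* of the cohort at each cycle start
    (length ``cycles + 1``).
    """
    rng = np.random.default_rng(seed)
    # 0 healthy, 1 diseased, 2 dead-of-disease
    state = np.zeros(n, dtype=np.int8)
    out = np.empty(cycles + 1)
    out[0] = 0.0
    for t in range(cycles):
        diseased = state == 1
        dies = diseased & (rng.random(n) < fatality)
        becomes = (state == 0) & (rng.random(n) < incidence)
        state[dies] = 2
        state[becomes] = 1
        out[t + 1] = (state == 1).mean()
    return out


def constant_rate_bundle(
    *,
    m_bg: float,
    i_chd: float,
    f_chd: float,
    i_str: float,
    f_str: float,
    p0_chd: float,
    p0_str: float,
    ethnicity: str = "non_maori",
    sex: str = "male",
    start_age: int = 60,
    count: float = 1.0,
):
    """A model input set with one populated cohort and age-constant rates.

    All trends are switched off and disability/costs zeroed, so the life
    table reduces to the plain state dynamics that the microsimulation
    oracle reproduces.
    """
    import pandas as pd

    from cvdshock._common import ETHNICITIES, MAX_AGE, SEXES
    from cvdshock.risk_link import builtin_effects
    from cvdshock.scenarios import builtin_scenarios
    from cvdshock.synthetic_data import EpiTable, ModelInputs, TrendConfig

    rows = []
    for e in ETHNICITIES:
        for s in SEXES:
            for a in range(MAX_AGE + 1):
                c = count if (e == ethnicity and s == sex and a == start_age) else 0.0
                rows.append((e, s, a, c))
    population = pd.DataFrame(rows, columns=["ethnicity", "sex", "age", "count"])

    acm = m_bg + p0_chd * f_chd + p0_str * f_str
    epi_rows = []
    for e in ETHNICITIES:
        for s in SEXES:
            for a in range(MAX_AGE + 1):
                epi_rows.append(
                    (e, s, a, acm, i_chd, f_chd, p0_chd,
                     i_str, f_str, p0_str, 0.0, 0.0, 0.0, 0.0, 0.0)
                )
    epi = EpiTable(
        table=pd.DataFrame(
            epi_rows,
            columns=[
                "ethnicity", "sex", "age", "acm",
                "chd_incidence", "chd_fatality", "chd_prevalence",
                "stroke_incidence", "stroke_fatality", "stroke_prevalence",
                "dw_chd", "dw_stroke", "bg_cost", "chd_cost", "stroke_cost",
            ],
        ),
        trends=TrendConfig(
            mortality_decline={"maori": 0.0, "non_maori": 0.0},
            disease_decline=0.0,
        ),
    )
    return ModelInputs(
        population=population,
        unemployment=None,
        epi=epi,
        scenarios=builtin_scenarios(),
        effects=builtin_effects(),
    )


def cohort_microsim(
    n: int,
    cycles: int,
    *,
    m_bg: float,
    i_chd: float,
    f_chd: float,
    i_str: float,
    f_str: float,
    p0_chd: float,
    p0_str: float,
    seed: int,
):
    """Individual-level stochastic simulation of one cohort stratum.

    Each cycle, every alive individual first dies with probability
    ``m_bg`` plus the case fatality of each disease they carry, then
    survivors independently acquire each disease.  Returns per-cycle
    (alive, chd-prevalent, stroke-prevalent) counts, shape
    ``(cycles + 1, 3)``, sampled at cycle starts.
    """
    rng = np.random.default_rng(seed)
    alive = np.ones(n, dtype=bool)
    chd = rng.random(n) < p0_chd
    stk = rng.random(n) < p0_str
    out = np.empty((cycles + 1, 3))
    out[0] = (n, chd.sum(), stk.sum())
    for t in range(cycles):
        q = m_bg + f_chd * (alive & chd) + f_str * (alive & stk)
        dies = alive & (rng.random(n) < q)
        alive = alive & ~dies
        chd = chd | (alive & ~chd & (rng.random(n) < i_chd))
        stk = stk | (alive & ~stk & (rng.random(n) < i_str))
        out[t + 1] = (alive.sum(), (alive & chd).sum(), (alive & stk).sum())
    return out
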