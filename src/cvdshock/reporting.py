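"""Equity metrics, per-capita normalisation, horizon shares and currency
conversion, plus table export.

Sign conventions: HALY losses print as negatives, additional costs as
positives; equity ratios are computed on magnitudes.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ._common import InputError


def per_capita(change: float, population: float) -> float:
    """Per-1000-capita rate of an absolute change."""
    if population <= 0:
        raise InputError("population must be positive")
    return 1000.0 * change / population


def equity_ratio(maori_pc: float, nonmaori_pc: float) -> float:
    """Ratio of per-capita changes on magnitudes (indigenous / reference)."""
    if nonmaori_pc == 0:
        raise InputError("reference per-capita change is zero")
    return abs(maori_pc) / abs(nonmaori_pc)


def horizon_share(cumulative: float, lifetime: float) -> float:
    """Percent of the lifetime change accrued by a horizon."""
    if lifetime == 0:
        raise InputError("lifetime change is zero")
    return 100.0 * cumulative / lifetime


def currency_convert(
    values_2011, nz2019_factor: float, usd2019_factor: float
) -> dict[str, np.ndarray | float]:
    """Report 2011-dollar values alongside 2019 NZ$ and US$ conversions.

    Pure multiplications: the US$ factor applies to the 2019 NZ$ value.
    """
    if nz2019_factor <= 0 or usd2019_factor <= 0:
        raise InputError("conversion factors must be positive")
    v = np.asarray(values_2011, dtype=float)
    nz2019 = v * nz2019_factor
    usd2019 = nz2019 * usd2019_factor
    if np.ndim(values_2011) == 0:
        return {"nz_2011": float(v), "nz_2019": float(nz2019), "usd_2019": float(usd2019)}
    return {"nz_2011": v, "nz_2019": nz2019, "usd_2019": usd2019}


# ---------------------------------------------------------------------------
# table construction on OutputBundle frames


def _cell(outputs: pd.DataFrame, ethnicity: str, sex: str, band: str, horizon: str) -> pd.Series:
    sub = outputs[
        (outputs["ethnicity"] == ethnicity)
        & (outputs["sex"] == sex)
        & (outputs["age_band"] == band)
        & (outputs["horizon"] == horizon)
    ]
    if len(sub) != 1:
        raise InputError(
            f"expected one output row for ({ethnicity}, {sex}, {band}, {horizon})"
        )
    return sub.iloc[0]


def equity_table(outputs: pd.DataFrame, horizon: str = "lifetime") -> pd.DataFrame:
    """Equity ratios (indigenous vs reference per-1000 HALY change) by group."""
    rows = []
    groups = outputs[outputs["ethnicity"] == "maori"][["sex", "age_band"]].drop_duplicates()
    for _, g in groups.iterrows():
        m = _cell(outputs, "maori", g["sex"], g["age_band"], horizon)
        nm = _cell(outputs, "non_maori", g["sex"], g["age_band"], horizon)
        if nm["haly_per_1000"] == 0:
            continue
        rows.append(
            {
                "sex": g["sex"],
                "age_band": g["age_band"],
                "horizon": horizon,
                "maori_per_1000": m["haly_per_1000"],
                "non_maori_per_1000": nm["haly_per_1000"],
                "equity_ratio": equity_ratio(m["haly_per_1000"], nm["haly_per_1000"]),
            }
        )
    return pd.DataFrame(rows)


def horizon_share_table(outputs: pd.DataFrame) -> pd.DataFrame:
    """Percent of each group's lifetime HALY change accrued by horizon."""
    rows = []
    keys = outputs[["ethnicity", "sex", "age_band"]].drop_duplicates()
    for _, g in keys.iterrows():
        sub = outputs[
            (outputs["ethnicity"] == g["ethnicity"])
            & (outputs["sex"] == g["sex"])
            & (outputs["age_band"] == g["age_band"])
        ]
        lifetime = _cell(
            outputs, g["ethnicity"], g["sex"], g["age_band"], "lifetime"
        )["haly_change"]
        if lifetime == 0:
            continue
        for _, row in sub.iterrows():
            rows.append(
                {
                    "ethnicity": g["ethnicity"],
                    "sex": g["sex"],
                    "age_band": g["age_band"],
                    "horizon": row["horizon"],
                    "haly_share_pct": horizon_share(row["haly_change"], lifetime),
                }
            )
    return pd.DataFrame(rows)


def cost_table(
    outputs: pd.DataFrame, nz2019_factor: float, usd2019_factor: float
) -> pd.DataFrame:
    """Cost changes with 2019 NZ$ and US$ conversions appended."""
    out = outputs.copy()
    conv = currency_convert(out["cost_change"].to_numpy(), nz2019_factor, usd2019_factor)
    out["cost_change_nz2019"] = conv["nz_2019"]
    out["cost_change_usd2019"] = conv["usd_2019"]
    return out


def presentation_round(outputs: pd.DataFrame) -> pd.DataFrame:
    """A display variant: HALYs to the nearest 10, per-1000 and ratios to
    one decimal.  Exports always keep the unrounded frame alongside."""
    out = outputs.copy()
    for col in ("haly_change", "cost_change"):
        out[col] = (out[col] / 10.0).round() * 10.0
    for col in ("haly_per_1000", "cost_per_1000"):
        out[col] = out[col].round(1)
    return out


def export_outputs(
    outputs: pd.DataFrame,
    directory: str | Path,
    *,
    nz2019_factor: float,
    usd2019_factor: float,
    prefix: str = "outputs",
) -> None:
    """Write the CSV/JSON report set for one scenario run."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    full = cost_table(outputs, nz2019_factor, usd2019_factor)
    full.to_csv(d / f"{prefix}.csv", index=False)
    presentation_round(outputs).to_csv(d / f"{prefix}_rounded.csv", index=False)
    equity = equity_table(outputs)
    equity.to_csv(d / f"{prefix}_equity.csv", index=False)
    shares = horizon_share_table(outputs)
    shares.to_csv(d / f"{prefix}_horizon_shares.csv", index=False)

    total = _cell(outputs, "all", "all", "all", "lifetime")
    summary = {
        "haly_change_lifetime": float(total["haly_change"]),
        "haly_per_1000_lifetime": float(total["haly_per_1000"]),
        "cost_change_lifetime": currency_convert(
            float(total["cost_change"]), nz2019_factor, usd2019_factor
        ),
        "equity_ratio_lifetime": (
            float(
                equity_ratio(
                    _cell(outputs, "maori", "all", "all", "lifetime")["haly_per_1000"],
                    _cell(outputs, "non_maori", "all", "all", "lifetime")["haly_per_1000"],
                )
            )
            if _cell(outputs, "non_maori", "all", "all", "lifetime")["haly_per_1000"]
            else None
        ),
    }
    (d / f"{prefix}_summary.json").write_text(json.dumps(summary, indent=2))
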