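"""Shared constants, keys and validation errors."""

from __future__ import annotations

ETHNICITIES = ("maori", "non_maori")
SEXES = ("female", "male")

#: Working-age 10-year bands used for unemployment rates.
AGE_BANDS = ("15-24", "25-34", "35-44", "45-54", "55-64")

#: Bands in which the incidence shock is applied (and outputs are reported).
MODEL_BANDS = ("35-44", "45-54", "55-64")

#: Reference band for the age weights.
REFERENCE_BAND = "45-54"

MAX_AGE = 110

_BAND_EDGES = {b: (int(b[:2]), int(b[-2:])) for b in AGE_BANDS}


class InputError(ValueError):
    """Raised when an input table or parameter violates a contract."""


def band_of_age(age: int) -> str | None:
    """Return the 10-year working-age band containing ``age``, or None."""
    for band, (lo, hi) in _BAND_EDGES.items():
        if lo <= age <= hi:
            return band
    return None


def band_ages(band: str) -> range:
    """Single-year ages covered by a band, inclusive."""
    lo, hi = _BAND_EDGES[band]
    return range(lo, hi + 1)
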