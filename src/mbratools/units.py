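"""Small unit conversions for reactor operation and medium composition."""

from __future__ import annotations

# Molecular weights (g/mol) of the fermentable carbohydrates in the
# low-carbohydrate bioreactor medium.
MOLECULAR_WEIGHTS = {
    "glucose": 180.16,
    "maltose": 342.30,
    "cellobiose": 342.30,
}


def percent_wv_to_micromolar(percent_wv: float, molecular_weight: float) -> float:
    """Convert a percent weight/volume concentration to micromolar.

    ``percent_wv`` of X % w/v means X g per 100 ml, i.e. 10*X g/L;
    micromolarity is then 1e6 * (g/L) / (g/mol).
    """
    if percent_wv < 0:
        raise ValueError("concentration cannot be negative")
    if molecular_weight <= 0:
        raise ValueError("molecular weight must be positive")
    grams_per_liter = percent_wv * 10.0
    return grams_per_liter / molecular_weight * 1e6


def turnovers(days: float, retention_time_h: float) -> float:
    """Number of reactor volume turnovers in ``days`` of continuous flow."""
    if retention_time_h <= 0:
        raise ValueError("retention time must be positive")
    return days * 24.0 / retention_time_h
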