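"""Bench-protocol arithmetic for the immobilized-trypsin digestion setup.

Immobilized trypsin is specified by BAEE activity (U/ml); comparing against
soluble trypsin of known specific activity (U/mg) converts the suspension
activity into a mass concentration, and the dilution into the digest gives
the final protease concentration.
"""

from __future__ import annotations


def stock_concentration_ug_per_ml(
    activity_u_per_ml: float, specific_activity_u_per_mg: float
) -> float:
    """Trypsin mass concentration of the stock suspension (ug/ml).

    activity [U/ml] / specific activity [U/mg] gives mg/ml; x1000 -> ug/ml.
    """
    if specific_activity_u_per_mg <= 0:
        raise ValueError("specific activity must be positive")
    if activity_u_per_ml < 0:
        raise ValueError("activity cannot be negative")
    return activity_u_per_ml / specific_activity_u_per_mg * 1000.0


def final_concentration_ug_per_ml(
    stock_ug_per_ml: float,
    added_volume_ul: float = 30.0,
    digest_volume_ul: float = 1000.0,
) -> float:
    """Protease concentration after adding ``added_volume_ul`` of stock
    to a digest of ``digest_volume_ul`` (dilution on the digest volume)."""
    if added_volume_ul < 0 or digest_volume_ul <= 0:
        raise ValueError("volumes must be positive")
    return stock_ug_per_ml * added_volume_ul / digest_volume_ul
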