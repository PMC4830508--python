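"""Small physical utilities."""

from __future__ import annotations

__all__ = ["estimate_applied_stress", "ATM_PA"]

ATM_PA = 101_325.0


def estimate_applied_stress(
    force_N: float = 10.0, width_m: float = 1e-2, thickness_m: float = 1e-3
) -> dict:
    """Order-of-magnitude stress in a stretched leaf region.

    The stress is force over the cross-section perpendicular to it,
    sigma = F / (width x leaf thickness).  With the default values for
    a spring-loaded bay leaf (affected region ~1 cm wide, lamina ~1 mm
    thick) this gives 1e6 Pa, about 10 atm — the same order as turgor
    pressure, which is why the model sweeps external stress in units of
    P_tur.

    Returns a dict with the stress in Pa and in atmospheres.
    """
    if width_m <= 0 or thickness_m <= 0:
        raise ValueError("cross-section dimensions must be positive")
    pa = force_N / (width_m * thickness_m)
    return {"Pa": pa, "atm": pa / ATM_PA}
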