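"""Fick-principle oxygen delivery, consumption and extraction.

With [Hb] in g/L, saturations Y as fractions and flows Q in mL/min, the
oxygen content of blood is 1.36 * [Hb] * Y  (mL O2 per L of blood; 1.36 mL
O2 binds per gram of haemoglobin at 1 atm), so transport rates need a /1000
to land in mL O2/min:

    fetal DO2    = 1.36 * Hb * Y_UV * Q_UV / 1000
    cerebral DO2 = 1.36 * Hb * Y_AAo * Q_CCa / 1000
    fetal VO2    = 1.36 * Hb * (Y_UV - Y_DAo) * Q_UV / 1000
    cerebral VO2 = 1.36 * Hb * (Y_AAo - Y_SVC) * Q_CCa / 1000

The fetus receives oxygen through the umbilical vein (UV) and returns blood
to the placenta at descending-aortic (DAo) saturation; the brain is supplied
at ascending-aortic (AAo) saturation through the combined carotids (CCa) and
drains through the superior vena cava (SVC).  Oxygen extraction fraction is
(arterial - venous) / arterial over the same vessel pairs, so
VO2 = OEF * DO2 holds identically.
"""

from __future__ import annotations

from typing import Optional

from .types import (CirculationState, DerivedHaemodynamics, OxygenTransport,
                    ValidationError)

__all__ = [
    "O2_PER_G_HB", "o2_content", "fetal_do2", "cerebral_do2",
    "fetal_vo2", "cerebral_vo2", "extraction_fraction", "normalise_per_kg",
    "compute_oxygen_transport",
]

#: mL of oxygen bound per gram of haemoglobin at 1 atmosphere.
O2_PER_G_HB = 1.36


def _check_y(*ys: float) -> None:
    for y in ys:
        if not 0.0 <= y <= 1.0:
            raise ValidationError("saturation must be in [0, 1]")


def o2_content(hb_g_per_l: float, y: float) -> float:
    """Oxygen content of blood, mL O2 per L: 1.36 * [Hb] * Y."""
    if hb_g_per_l <= 0:
        raise ValidationError("haemoglobin must be positive")
    _check_y(y)
    return O2_PER_G_HB * hb_g_per_l * y


def fetal_do2(hb_g_per_l: float, y_uv: float, q_uv: float) -> float:
    """Fetal oxygen delivery, mL O2/min."""
    if q_uv < 0:
        raise ValidationError("flow must be non-negative")
    return o2_content(hb_g_per_l, y_uv) * q_uv / 1000.0


def cerebral_do2(hb_g_per_l: float, y_aao: float, q_cca: float) -> float:
    """Cerebral oxygen delivery, mL O2/min (Q_CCa = left + right carotid)."""
    if q_cca < 0:
        raise ValidationError("flow must be non-negative")
    return o2_content(hb_g_per_l, y_aao) * q_cca / 1000.0


def fetal_vo2(hb_g_per_l: float, y_uv: float, y_dao: float,
              q_uv: float) -> float:
    """Fetal oxygen consumption, mL O2/min; negative if Y_DAo > Y_UV."""
    if q_uv < 0:
        raise ValidationError("flow must be non-negative")
    if hb_g_per_l <= 0:
        raise ValidationError("haemoglobin must be positive")
    _check_y(y_uv, y_dao)
    return O2_PER_G_HB * hb_g_per_l * (y_uv - y_dao) * q_uv / 1000.0


def cerebral_vo2(hb_g_per_l: float, y_aao: float, y_svc: float,
                 q_cca: float) -> float:
    """Cerebral oxygen consumption, mL O2/min; negative if Y_SVC > Y_AAo."""
    if q_cca < 0:
        raise ValidationError("flow must be non-negative")
    if hb_g_per_l <= 0:
        raise ValidationError("haemoglobin must be positive")
    _check_y(y_aao, y_svc)
    return O2_PER_G_HB * hb_g_per_l * (y_aao - y_svc) * q_cca / 1000.0


def extraction_fraction(y_in: float, y_out: float) -> float:
    """Oxygen extraction fraction (y_in - y_out) / y_in."""
    _check_y(y_in, y_out)
    if y_in == 0:
        raise ValidationError("arterial saturation is zero: OEF undefined")
    return (y_in - y_out) / y_in


def normalise_per_kg(value_ml_min: float, weight_g: float) -> float:
    """Weight-normalise a transport rate: mL/min -> mL/min/kg."""
    if weight_g <= 0:
        raise ValidationError("weight must be positive")
    return value_ml_min / (weight_g / 1000.0)


def compute_oxygen_transport(state: CirculationState,
                             derived: DerivedHaemodynamics,
                             weight_g: Optional[float] = None,
                             ) -> OxygenTransport:
    """Full oxygen-transport panel for one subject x state."""
    hb = state.hb_g_per_l
    y = state.saturations
    for v in ("UV", "DAo", "AAo", "SVC"):
        if v not in y:
            raise ValidationError(f"missing saturation for {v}")
    q_uv = state.flows["UV"]
    q_cca = derived.cca_combined

    f_do2 = fetal_do2(hb, y["UV"], q_uv)
    c_do2 = cerebral_do2(hb, y["AAo"], q_cca)
    f_vo2 = fetal_vo2(hb, y["UV"], y["DAo"], q_uv)
    c_vo2 = cerebral_vo2(hb, y["AAo"], y["SVC"], q_cca)
    f_oef = extraction_fraction(y["UV"], y["DAo"])
    c_oef = extraction_fraction(y["AAo"], y["SVC"])

    flags = []
    if f_vo2 < 0:
        flags.append("fetal VO2 negative: Y_DAo exceeds Y_UV")
    if c_vo2 < 0:
        flags.append("cerebral VO2 negative: Y_SVC exceeds Y_AAo")

    out = OxygenTransport(fetal_do2=f_do2, cerebral_do2=c_do2,
                          fetal_vo2=f_vo2, cerebral_vo2=c_vo2,
                          fetal_oef=f_oef, cerebral_oef=c_oef, flags=flags)
    if weight_g is not None:
        out.fetal_do2_per_kg = normalise_per_kg(f_do2, weight_g)
        out.cerebral_do2_per_kg = normalise_per_kg(c_do2, weight_g)
        out.fetal_vo2_per_kg = normalise_per_kg(f_vo2, weight_g)
        out.cerebral_vo2_per_kg = normalise_per_kg(c_vo2, weight_g)
    return out
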