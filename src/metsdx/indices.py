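"""The five adiposity/cardiometabolic indexes and their unit conversions.

All scalar operations take and return plain floats in the units stated in
their signatures. ``index_panel`` orchestrates the conversions a
:class:`~metsdx.records.SubjectRecord` needs: waist circumference cm -> m for
BMFI, triglycerides and HDL-C mg/dL -> mmol/L for VAI and CMI.

Index definitions
-----------------
* WHR  = WC (cm) / HC (cm)
* WtHR = WC (cm) / stature (cm)
* BMFI = BMI (kg/m^2) x fat-mass fraction x WC (m)   [kg/m]
* VAI (women) = (WC / (36.58 + 1.89 BMI)) x (TG / 0.81) x (1.52 / HDL),
  lipids in mmol/L
* CMI  = WtHR x TG / HDL, lipids in mmol/L
"""

from __future__ import annotations

from dataclasses import dataclass

from .records import SubjectRecord

INDEX_NAMES = ("whr", "wthr", "bmfi", "vai", "cmi")

#: mg/dL per mmol/L, from the molar masses of the analytes.
CONVERSION_FACTORS = {
    "glucose": 18.016,
    "triglycerides": 88.57,
    "cholesterol": 38.67,
}


@dataclass(frozen=True)
class IndexPanel:
    """The five index values for one subject."""

    whr: float
    wthr: float
    bmfi: float
    vai: float
    cmi: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in INDEX_NAMES}


def _factor(analyte: str) -> float:
    try:
        return CONVERSION_FACTORS[analyte]
    except KeyError:
        known = ", ".join(sorted(CONVERSION_FACTORS))
        raise ValueError(f"unknown analyte {analyte!r}; expected one of: {known}") from None


def mgdl_to_mmol(analyte: str, value_mgdl: float) -> float:
    """Convert an analyte concentration from mg/dL to mmol/L."""
    if value_mgdl < 0:
        raise ValueError(f"concentration must be >= 0, got {value_mgdl}")
    return value_mgdl / _factor(analyte)


def mmol_to_mgdl(analyte: str, value_mmol: float) -> float:
    """Inverse of :func:`mgdl_to_mmol`."""
    if value_mmol < 0:
        raise ValueError(f"concentration must be >= 0, got {value_mmol}")
    return value_mmol * _factor(analyte)


def bmi(body_mass_kg: float, stature_m: float) -> float:
    """Body mass index: mass (kg) divided by stature (m) squared."""
    if body_mass_kg <= 0 or stature_m <= 0:
        raise ValueError("body mass and stature must both be > 0")
    return body_mass_kg / stature_m**2


def whr(wc_cm: float, hc_cm: float) -> float:
    """Waist-to-hip circumference ratio."""
    if wc_cm <= 0 or hc_cm <= 0:
        raise ValueError("waist and hip circumference must both be > 0")
    return wc_cm / hc_cm


def wthr(wc_cm: float, stature_cm: float) -> float:
    """Waist-to-height ratio; both arguments in centimetres.

    A stature below 3 is rejected as an almost certain metre-valued input.
    """
    if wc_cm <= 0 or stature_cm <= 0:
        raise ValueError("waist circumference and stature must both be > 0")
    if stature_cm < 3:
        raise ValueError(f"stature {stature_cm} looks like metres; wthr expects centimetres")
    return wc_cm / stature_cm


def bmfi(bmi_value: float, fm_fraction: float, wc_m: float) -> float:
    """Body mass fat index: BMI x fat-mass fraction x waist circumference (m).

    The fat-mass term is a fraction in [0, 1]; callers holding a percentage
    must divide by 100 first.
    """
    if bmi_value <= 0:
        raise ValueError("BMI must be > 0")
    if not 0.0 <= fm_fraction <= 1.0:
        raise ValueError(f"fm_fraction must lie in [0, 1], got {fm_fraction}; divide a percent by 100")
    if wc_m <= 0:
        raise ValueError("waist circumference must be > 0")
    return bmi_value * fm_fraction * wc_m


def vai_female(wc_cm: float, bmi_value: float, tg_mmol: float, hdl_mmol: float) -> float:
    """Visceral adiposity index for women.

    (WC / (36.58 + 1.89 BMI)) x (TG / 0.81) x (1.52 / HDL) with WC in cm,
    BMI in kg/m^2, lipids in mmol/L. The first factor normalizes waist
    circumference by its BMI-predicted value; the lipid factors normalize TG
    and HDL-C by healthy female reference levels.
    """
    if min(wc_cm, bmi_value, tg_mmol, hdl_mmol) <= 0:
        raise ValueError("all VAI arguments must be > 0")
    return (wc_cm / (36.58 + 1.89 * bmi_value)) * (tg_mmol / 0.81) * (1.52 / hdl_mmol)


def cmi(wthr_value: float, tg_mmol: float, hdl_mmol: float) -> float:
    """Cardiometabolic index: WtHR x TG/HDL-C, lipids in mmol/L."""
    if min(wthr_value, tg_mmol, hdl_mmol) <= 0:
        raise ValueError("all CMI arguments must be > 0")
    return wthr_value * tg_mmol / hdl_mmol


def index_panel(record: SubjectRecord) -> IndexPanel:
    """Compute all five indexes for one subject, handling unit conversions."""
    stature_m, body_mass_kg, wc_cm, hc_cm = record.require(
        "stature_m", "body_mass_kg", "wc_cm", "hc_cm"
    )
    tg_mgdl, hdl_mgdl = record.require("tg_mgdl", "hdl_mgdl")
    fm_fraction = record.fat_fraction()

    bmi_value = bmi(body_mass_kg, stature_m)
    tg_mmol = mgdl_to_mmol("triglycerides", tg_mgdl)
    hdl_mmol = mgdl_to_mmol("cholesterol", hdl_mgdl)
    wthr_value = wthr(wc_cm, stature_m * 100.0)

    return IndexPanel(
        whr=whr(wc_cm, hc_cm),
        wthr=wthr_value,
        bmfi=bmfi(bmi_value, fm_fraction, wc_cm / 100.0),
        vai=vai_female(wc_cm, bmi_value, tg_mmol, hdl_mmol),
        cmi=cmi(wthr_value, tg_mmol, hdl_mmol),
    )
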