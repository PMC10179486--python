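"""Subject-level measurement records and their validation.

A :class:`SubjectRecord` carries one woman's anthropometry (SI units),
biochemistry (mg/dL, the units of the source laboratory), blood pressures
(mmHg) and drug-treatment flags. Fields other than ``subject_id`` are
optional at construction so that partially observed rows can be loaded;
operations that need a field request it through :meth:`SubjectRecord.require`,
which raises a :class:`MissingFieldError` naming both the field and the
subject.
"""

from __future__ import annotations

from typing import Optional

from pydantic import BaseModel, ConfigDict, field_validator, model_validator

#: Canonical cohort CSV column order (booleans serialized as 0/1).
CSV_COLUMNS = [
    "subject_id",
    "age",
    "stature_m",
    "body_mass_kg",
    "wc_cm",
    "hc_cm",
    "fm_kg",
    "sbp",
    "dbp",
    "glucose_mgdl",
    "tg_mgdl",
    "hdl_mgdl",
    "on_glucose_drug",
    "on_bp_drug",
    "on_tg_drug",
    "on_hdl_drug",
]

DRUG_FLAGS = ["on_glucose_drug", "on_bp_drug", "on_tg_drug", "on_hdl_drug"]

_STRICTLY_POSITIVE = ("stature_m", "body_mass_kg", "wc_cm", "hc_cm", "hdl_mgdl")
_NONNEGATIVE = ("age", "fm_kg", "sbp", "dbp", "glucose_mgdl", "tg_mgdl")


class MissingFieldError(ValueError):
    """A required measurement is absent from a subject record."""

    def __init__(self, subject_id: str, field: str):
        self.subject_id = subject_id
        self.field = field
        super().__init__(f"subject {subject_id!r}: required field {field!r} is missing")


class SubjectRecord(BaseModel):
    model_config = ConfigDict(frozen=True)

    subject_id: str
    age: Optional[float] = None
    stature_m: Optional[float] = None
    body_mass_kg: Optional[float] = None
    wc_cm: Optional[float] = None
    hc_cm: Optional[float] = None
    fm_kg: Optional[float] = None
    fm_fraction: Optional[float] = None
    sbp: Optional[float] = None
    dbp: Optional[float] = None
    glucose_mgdl: Optional[float] = None
    tg_mgdl: Optional[float] = None
    hdl_mgdl: Optional[float] = None
    on_glucose_drug: bool = False
    on_bp_drug: bool = False
    on_tg_drug: bool = False
    on_hdl_drug: bool = False

    @field_validator(*_STRICTLY_POSITIVE)
    @classmethod
    def _strictly_positive(cls, v, info):
        if v is not None and v <= 0:
            raise ValueError(f"{info.field_name} must be > 0, got {v}")
        return v

    @field_validator(*_NONNEGATIVE)
    @classmethod
    def _nonnegative(cls, v, info):
        if v is not None and v < 0:
            raise ValueError(f"{info.field_name} must be >= 0, got {v}")
        return v

    @field_validator("fm_fraction")
    @classmethod
    def _fraction_in_unit_interval(cls, v):
        if v is not None and not 0.0 <= v <= 1.0:
            raise ValueError(f"fm_fraction must lie in [0, 1], got {v}")
        return v

    @model_validator(mode="after")
    def _fat_mass_consistent(self):
        if self.fm_kg is not None and self.fm_fraction is not None and self.body_mass_kg is not None:
            implied = self.fm_kg / self.body_mass_kg
            if abs(implied - self.fm_fraction) > 0.005:
                raise ValueError(
                    f"subject {self.subject_id!r}: fm_kg/body_mass_kg = {implied:.4f} "
                    f"disagrees with fm_fraction = {self.fm_fraction:.4f} by more than 0.005"
                )
        return self

    def require(self, *fields: str) -> tuple:
        """Return the named field values, raising :class:`MissingFieldError` on any None."""
        values = []
        for name in fields:
            value = getattr(self, name)
            if value is None:
                raise MissingFieldError(self.subject_id, name)
            values.append(value)
        return tuple(values)

    def fat_fraction(self) -> float:
        """Fat mass as a fraction of body mass, derived from fm_kg if needed."""
        if self.fm_fraction is not None:
            return self.fm_fraction
        if self.fm_kg is not None and self.body_mass_kg is not None:
            return self.fm_kg / self.body_mass_kg
        raise MissingFieldError(self.subject_id, "fm_fraction")
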