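"""Rule-based IDF metabolic-syndrome classification.

The study's operationalization counts five risk factors — central obesity
(WC >= 80 cm, the female IDF threshold), hyperglycemia (FPG >= 100 mg/dL),
elevated blood pressure (SBP >= 130 or DBP >= 85 mmHg), elevated
triglycerides (TG >= 150 mg/dL) and reduced HDL-C (< 50 mg/dL) — with each
criterion also satisfiable by the corresponding drug treatment, and labels a
subject MetS-positive when three or more are present. The canonical IDF rule
(mandatory central obesity plus >= 2 of the other four) is available through
``variant="canonical"``; the default reproduces the study's rule.

Glucose is compared in mg/dL, its source unit, so the threshold is exact
rather than subject to conversion rounding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .records import SubjectRecord

CRITERIA = ("central_obesity", "hyperglycemia", "elevated_bp", "elevated_tg", "reduced_hdl")

WC_THRESHOLD_CM = 80.0
GLUCOSE_THRESHOLD_MGDL = 100.0
SBP_THRESHOLD = 130.0
DBP_THRESHOLD = 85.0
TG_THRESHOLD_MGDL = 150.0
HDL_THRESHOLD_MGDL = 50.0


@dataclass(frozen=True)
class MetSAssessment:
    subject_id: str
    central_obesity: bool
    hyperglycemia: bool
    elevated_bp: bool
    elevated_tg: bool
    reduced_hdl: bool
    n_criteria: int
    mets: bool

    def flags(self) -> dict[str, bool]:
        return {name: getattr(self, name) for name in CRITERIA}


@dataclass(frozen=True)
class CohortPrevalence:
    n: int
    counts: dict[str, int]
    proportions: dict[str, float]
    mets_count: int
    mets_prevalence: float


def _mets_label(flags: Sequence[bool], variant: str) -> tuple[int, bool]:
    n = int(sum(flags))
    if variant == "paper":
        return n, n >= 3
    if variant == "canonical":
        # central obesity is flags[0]
        return n, bool(flags[0]) and (n - int(flags[0])) >= 2
    raise ValueError(f"unknown idf_variant {variant!r}; expected 'paper' or 'canonical'")


def evaluate_idf_criteria(record: SubjectRecord, variant: str = "paper") -> MetSAssessment:
    """Evaluate the five IDF risk-factor criteria for one subject.

    Boundary semantics: >= for WC, FPG, SBP, DBP and TG; strict < for HDL-C.
    A set drug-treatment flag satisfies its criterion regardless of the
    measured value.
    """
    wc, glucose, sbp, dbp, tg, hdl = record.require(
        "wc_cm", "glucose_mgdl", "sbp", "dbp", "tg_mgdl", "hdl_mgdl"
    )
    flags = (
        wc >= WC_THRESHOLD_CM,
        glucose >= GLUCOSE_THRESHOLD_MGDL or record.on_glucose_drug,
        sbp >= SBP_THRESHOLD or dbp >= DBP_THRESHOLD or record.on_bp_drug,
        tg >= TG_THRESHOLD_MGDL or record.on_tg_drug,
        hdl < HDL_THRESHOLD_MGDL or record.on_hdl_drug,
    )
    n, mets = _mets_label(flags, variant)
    return MetSAssessment(record.subject_id, *flags, n_criteria=n, mets=mets)


def cohort_criterion_prevalence(
    records: Iterable[SubjectRecord], variant: str = "paper"
) -> CohortPrevalence:
    """Per-criterion counts/proportions and MetS prevalence over a cohort."""
    assessments = [evaluate_idf_criteria(r, variant=variant) for r in records]
    n = len(assessments)
    if n == 0:
        raise ValueError("cohort is empty")
    counts = {name: sum(getattr(a, name) for a in assessments) for name in CRITERIA}
    mets_count = sum(a.mets for a in assessments)
    return CohortPrevalence(
        n=n,
        counts=counts,
        proportions={name: c / n for name, c in counts.items()},
        mets_count=mets_count,
        mets_prevalence=mets_count / n,
    )
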