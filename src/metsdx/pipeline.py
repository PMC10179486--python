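"""End-to-end orchestration: indexes -> classification -> diagnostic accuracy.

``evaluate_cohort`` reproduces the full analysis for a cohort: compute the
five indexes per subject, label subjects with the IDF classifier, then for
each requested index build the ROC curve with DeLong AUC inference, pick the
Youden-optimal cutoff (or use a caller-fixed one), summarize cutoff-level
performance, and run all pairwise DeLong AUC comparisons. Pairwise p-values
are reported unadjusted for multiple testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .records import SubjectRecord
from .indices import INDEX_NAMES, index_panel
from .mets import evaluate_idf_criteria
from .diagnostics import (
    DiagnosticSummary,
    RocCurve,
    AucComparison,
    compare_auc_delong,
    confusion_at_cutoff,
    diagnostic_summary,
    group_descriptives,
    positivity_rate,
    roc_with_ci,
    youden_optimal_cutoff,
)
from .io import records_to_frame


@dataclass(frozen=True)
class IndexEvaluation:
    index: str
    roc: RocCurve
    summary: DiagnosticSummary
    positivity: float


@dataclass(frozen=True)
class EvaluationReport:
    n: int
    n_pos: int
    n_neg: int
    level: float
    idf_variant: str
    evaluations: dict[str, IndexEvaluation]
    comparisons: dict[tuple[str, str], AucComparison]
    notes: tuple[str, ...] = ("pairwise AUC p-values are unadjusted for multiple testing",)

    def summary_frame(self) -> pd.DataFrame:
        """One row per index: AUC, CI, cutoff, Se/Sp/PPV/NPV/PLR/NLR/Youden, positivity."""
        rows = []
        for name, ev in self.evaluations.items():
            s = ev.summary
            rows.append(
                {
                    "index": name,
                    "auc": ev.roc.auc,
                    "auc_se": ev.roc.auc_se,
                    "auc_ci_low": ev.roc.auc_ci[0],
                    "auc_ci_high": ev.roc.auc_ci[1],
                    "cutoff": s.cutoff,
                    "sensitivity": s.sensitivity,
                    "specificity": s.specificity,
                    "ppv": s.ppv,
                    "npv": s.npv,
                    "plr": s.plr,
                    "nlr": s.nlr,
                    "youden": s.youden,
                    "positivity_rate": ev.positivity,
                }
            )
        return pd.DataFrame(rows).set_index("index")

    def comparison_frame(self) -> pd.DataFrame:
        rows = [
            {
                "index_a": a,
                "index_b": b,
                "auc_a": c.auc_a,
                "auc_b": c.auc_b,
                "difference": c.difference,
                "z": c.z,
                "p": c.p,
            }
            for (a, b), c in self.comparisons.items()
        ]
        cols = ["index_a", "index_b", "auc_a", "auc_b", "difference", "z", "p"]
        return pd.DataFrame(rows, columns=cols)


def compute_index_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Cohort DataFrame extended with the five index columns."""
    frame = records_to_frame(records)
    panels = [index_panel(r) for r in records]
    for name in INDEX_NAMES:
        frame[name] = [getattr(p, name) for p in panels]
    return frame


def mets_labels(records: Sequence[SubjectRecord], variant: str = "paper") -> np.ndarray:
    """Boolean MetS labels from the IDF classifier."""
    return np.array([evaluate_idf_criteria(r, variant=variant).mets for r in records])


def evaluate_cohort(
    records: Sequence[SubjectRecord],
    indices: Sequence[str] = INDEX_NAMES,
    level: float = 0.95,
    idf_variant: str = "paper",
    cutoffs: Optional[dict[str, float]] = None,
) -> EvaluationReport:
    """Full diagnostic-accuracy evaluation of the requested indexes.

    ``cutoffs`` maps index name -> fixed cutoff; indexes absent from the map
    use their Youden-optimal cutoff. PPV/NPV are computed at the cohort's
    empirical prevalence.
    """
    if not indices:
        raise ValueError("at least one index must be evaluated")
    unknown = [i for i in indices if i not in INDEX_NAMES]
    if unknown:
        raise ValueError(f"unknown indexes {unknown}; expected a subset of {list(INDEX_NAMES)}")

    labels = mets_labels(records, variant=idf_variant)
    if labels.all():
        raise ValueError("cohort has no MetS-negative subjects; cannot evaluate")
    if not labels.any():
        raise ValueError("cohort has no MetS-positive subjects; cannot evaluate")

    panels = [index_panel(r) for r in records]
    scores = {name: np.array([getattr(p, name) for p in panels]) for name in indices}

    evaluations: dict[str, IndexEvaluation] = {}
    for name in indices:
        s = scores[name]
        roc = roc_with_ci(s, labels, level=level)
        if cutoffs is not None and name in cutoffs:
            cutoff = float(cutoffs[name])
        else:
            cutoff, _ = youden_optimal_cutoff(roc)
        counts = confusion_at_cutoff(s, labels, cutoff)
        summary = diagnostic_summary(counts, cutoff=cutoff, level=level)
        evaluations[name] = IndexEvaluation(
            index=name,
            roc=roc,
            summary=summary,
            positivity=positivity_rate(s, cutoff),
        )

    comparisons = {
        (a, b): compare_auc_delong(scores[a], scores[b], labels)
        for i, a in enumerate(indices)
        for b in list(indices)[i + 1 :]
    }
    return EvaluationReport(
        n=len(records),
        n_pos=int(labels.sum()),
        n_neg=int((~labels).sum()),
        level=level,
        idf_variant=idf_variant,
        evaluations=evaluations,
        comparisons=comparisons,
    )


def cohort_descriptives(
    records: Sequence[SubjectRecord], group_labels: Sequence[bool]
) -> pd.DataFrame:
    """Two-group mean +/- SD + Welch-p table over measurements and indexes."""
    frame = compute_index_frame(records)
    variables = [
        c
        for c in frame.columns
        if c not in ("subject_id",) and pd.api.types.is_numeric_dtype(frame[c])
    ]
    # drug flags are booleans stored as 0/1; drop them from the descriptive table
    variables = [v for v in variables if not v.startswith("on_")]
    return group_descriptives(frame, group_labels, variables)
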