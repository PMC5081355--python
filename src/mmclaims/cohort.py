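"""Gold-standard cohort construction.

Cases come from oncology-EMR diagnosis records; controls from primary-care
EMR-linked claims, with exclusions guaranteeing absence of disease during
the observation period.  The merged labelled file is split into development
and validation halves with a seeded permutation.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .claims_model import (
    ClaimsBundle,
    MedicalClaim,
    PatientHistory,
    ReferentialIntegrityError,
    build_histories,
    spans_cover,
)
from .codesets import CodeSetLibrary, claim_in_codeset

__all__ = [
    "CohortParams",
    "GoldLabel",
    "SampleAssignment",
    "note_mentions_mm",
    "select_cases",
    "classify_incident",
    "select_controls",
    "split_sample",
    "build_gold_standard",
]

DEFAULT_MM_TERMS = ("multiple myeloma", "myeloma")


@dataclass(frozen=True)
class CohortParams:
    """Knobs for case/control selection.

    ``chemo_association`` controls what "chemotherapy associated with an MM
    diagnosis" means: ``same_claim`` (default) requires the chemotherapy
    code and an MM diagnosis code on the same claim record; ``same_day``
    accepts any chemotherapy claim sharing a service date with an MM
    diagnosis claim.
    """

    pre_days: int = 90
    post_days: int = 30
    overlap_days: int = 365  # ">= 12 months of overlap"
    min_age: int = 18
    chemo_association: str = "same_claim"
    mm_terms: tuple[str, ...] = DEFAULT_MM_TERMS


@dataclass(frozen=True)
class GoldLabel:
    """Ground-truth case/control status for one patient."""

    patient_id: str
    label: str  # "case" | "control"
    anchor_date: _dt.date
    incident: Optional[bool]  # cases only; None for controls
    observation_start: _dt.date
    observation_end: _dt.date

    def __post_init__(self) -> None:
        if self.label not in ("case", "control"):
            raise ValueError(f"label must be case/control, got {self.label!r}")
        if self.label == "control" and self.incident is not None:
            raise ValueError("controls carry no incident flag")
        if self.observation_start >= self.observation_end:
            raise ValueError("observation_start must precede observation_end")


@dataclass(frozen=True)
class SampleAssignment:
    patient_id: str
    sample: str  # "development" | "validation"


def note_mentions_mm(note_text: str, term_list: Sequence[str] = DEFAULT_MM_TERMS) -> bool:
    """Case-insensitive substring scan of a free-text note."""
    if not term_list:
        raise ValueError("term_list must be non-empty")
    lowered = note_text.lower()
    return any(term.lower() in lowered for term in term_list)


def _chemo_mm_dates(
    history: PatientHistory, codesets: CodeSetLibrary, association: str
) -> set[_dt.date]:
    """Service dates of chemotherapy claims associated with an MM diagnosis."""
    chemo = codesets["chemotherapy"]
    mm = codesets.mm_diagnosis
    if association == "same_claim":
        return {
            c.service_date
            for c in history.medical_claims
            if claim_in_codeset(c, chemo) and claim_in_codeset(c, mm)
        }
    if association == "same_day":
        chemo_days = {
            c.service_date for c in history.medical_claims if claim_in_codeset(c, chemo)
        }
        mm_days = {
            c.service_date for c in history.medical_claims if claim_in_codeset(c, mm)
        }
        return chemo_days & mm_days
    raise ValueError(f"unknown chemo_association {association!r}")


def select_cases(
    bundle: ClaimsBundle,
    codesets: CodeSetLibrary,
    params: CohortParams = CohortParams(),
    histories: Optional[dict[str, PatientHistory]] = None,
) -> list[GoldLabel]:
    """Select gold-standard cases from the oncology EMR.

    A patient qualifies if an oncology-EMR record labels MM with a clinic
    visit date, age at the EMR diagnosis date is >= 18, and merged claims
    enrollment continuously covers [dx - pre_days, dx + post_days].  The
    anchor is the earliest qualifying EMR diagnosis date; the observation
    period is the merged enrollment span containing it.
    """
    histories = histories if histories is not None else build_histories(bundle)
    known = {p.patient_id for p in bundle.persons}
    for rec in bundle.emr_oncology:
        if rec.patient_id not in known:
            raise ReferentialIntegrityError(
                f"emr_oncology references unknown patient {rec.patient_id!r}"
            )
    labels = []
    for pid in sorted(histories):
        h = histories[pid]
        candidates = sorted(
            r.emr_dx_date
            for r in h.emr_oncology
            if r.visit_date is not None and note_mentions_mm(r.diagnosis_label, params.mm_terms)
        )
        for anchor in candidates:
            if h.person.age_at(anchor) < params.min_age:
                continue
            lo = anchor - _dt.timedelta(days=params.pre_days)
            hi = anchor + _dt.timedelta(days=params.post_days)
            span = next((s for s in h.spans if s.covers(lo, hi)), None)
            if span is None:
                continue
            incident = classify_incident_dates(
                anchor, _chemo_mm_dates(h, codesets, params.chemo_association)
            )
            labels.append(
                GoldLabel(
                    patient_id=pid,
                    label="case",
                    anchor_date=anchor,
                    incident=incident,
                    observation_start=span.start_date,
                    observation_end=span.end_date,
                )
            )
            break
    return labels


def classify_incident_dates(anchor: _dt.date, chemo_mm_dates: set[_dt.date]) -> bool:
    """Incident iff no MM-associated chemotherapy strictly before the anchor."""
    return not any(d < anchor for d in chemo_mm_dates)


def classify_incident(
    case: GoldLabel,
    bundle_or_history: ClaimsBundle | PatientHistory,
    codesets: CodeSetLibrary,
    params: CohortParams = CohortParams(),
) -> bool:
    """True (incident) iff the case has no chemotherapy claim associated
    with an MM diagnosis strictly before the anchor date."""
    if case.label != "case":
        raise ValueError("classify_incident applies to case labels only")
    if isinstance(bundle_or_history, PatientHistory):
        h = bundle_or_history
    else:
        h = build_histories(bundle_or_history)[case.patient_id]
    return classify_incident_dates(
        case.anchor_date, _chemo_mm_dates(h, codesets, params.chemo_association)
    )


def _overlap_windows(history: PatientHistory) -> list[tuple[_dt.date, _dt.date]]:
    """Intersections of merged claims enrollment with primary-care EMR
    coverage (taken as the span of the patient's note dates)."""
    if not history.notes:
        return []
    emr_lo = min(n.note_date for n in history.notes)
    emr_hi = max(n.note_date for n in history.notes)
    windows = []
    for s in history.spans:
        lo, hi = max(s.start_date, emr_lo), min(s.end_date, emr_hi)
        if lo <= hi:
            windows.append((lo, hi))
    return windows


def select_controls(
    bundle: ClaimsBundle,
    codesets: CodeSetLibrary,
    params: CohortParams = CohortParams(),
    histories: Optional[dict[str, PatientHistory]] = None,
    exclude_ids: frozenset[str] = frozenset(),
) -> list[GoldLabel]:
    """Select gold-standard controls.

    Requires age >= 18 at observation start and an overlap window of at
    least ``overlap_days`` between claims enrollment and primary-care EMR
    coverage containing at least one MM-diagnosis claim.  Excludes, within
    the observation period: (1) chemotherapy associated with an MM
    diagnosis, (2) any stem-cell-transplant claim, (3) any note matching
    the MM text scan.  When several qualifying windows exist the earliest
    is used.
    """
    histories = histories if histories is not None else build_histories(bundle)
    mm = codesets.mm_diagnosis
    sct = codesets["stem_cell_transplant"]
    labels = []
    for pid in sorted(histories):
        if pid in exclude_ids:
            continue
        h = histories[pid]
        window = next(
            (
                w
                for w in sorted(_overlap_windows(h))
                if (w[1] - w[0]).days + 1 >= params.overlap_days
            ),
            None,
        )
        if window is None:
            continue
        lo, hi = window
        if h.person.age_at(lo) < params.min_age:
            continue

        def in_window(d: _dt.date) -> bool:
            return lo <= d <= hi

        if not any(
            in_window(c.service_date) and claim_in_codeset(c, mm)
            for c in h.medical_claims
        ):
            continue
        chemo_mm = _chemo_mm_dates(h, codesets, params.chemo_association)
        if any(in_window(d) for d in chemo_mm):
            continue
        if any(
            in_window(c.service_date) and claim_in_codeset(c, sct)
            for c in h.medical_claims
        ):
            continue
        if any(
            in_window(n.note_date) and note_mentions_mm(n.note_text, params.mm_terms)
            for n in h.notes
        ):
            continue
        labels.append(
            GoldLabel(
                patient_id=pid,
                label="control",
                anchor_date=lo,
                incident=None,
                observation_start=lo,
                observation_end=hi,
            )
        )
    return labels


def split_sample(labels: Sequence[GoldLabel], seed: int) -> list[SampleAssignment]:
    """Randomly split labelled patients into development/validation halves.

    Deterministic given ``seed`` and invariant to input ordering (labels
    are sorted by patient_id before the seeded permutation).  With an odd
    count the development half gets the extra patient.
    """
    if not labels:
        raise ValueError("split_sample requires at least one label")
    pids = sorted({l.patient_id for l in labels})
    if len(pids) != len(labels):
        raise ValueError("duplicate patient_id in labels")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pids))
    n_dev = math.ceil(len(pids) / 2)
    dev = {pids[i] for i in order[:n_dev]}
    return [
        SampleAssignment(pid, "development" if pid in dev else "validation")
        for pid in pids
    ]


def build_gold_standard(
    bundle: ClaimsBundle,
    codesets: CodeSetLibrary,
    params: CohortParams = CohortParams(),
    seed: int = 0,
) -> tuple[list[GoldLabel], list[SampleAssignment]]:
    """Cases, then controls from the remaining patients, then the split."""
    histories = build_histories(bundle)
    cases = select_cases(bundle, codesets, params, histories=histories)
    case_ids = frozenset(l.patient_id for l in cases)
    controls = select_controls(
        bundle, codesets, params, histories=histories, exclude_ids=case_ids
    )
    labels = cases + controls
    assignments = split_sample(labels, seed) if labels else []
    return labels, assignments
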