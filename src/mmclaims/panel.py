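"""Per-diagnosis evaluation panel and windowed feature extraction.

An *index diagnosis* is one MM-coded claim around which temporal windows
are anchored.  Every MM-diagnosis claim with continuous enrollment for at
least ``pre_days`` (90) before and ``post_days`` (30) after is eligible.
Feature windows span at most 180 days on each side, truncated by
enrollment; window endpoints are inclusive.

Window conventions (relative day offsets from the index date):

* prior MM-dx window          [-180, -1]
* post MM-dx window           [+1, +180]
* ">30 days following"        [+31, +180]
* test lookback               [-90, 0]   (tests are often billed on the
  diagnosis day, so the index date is included)
* chemo prior-or-on           [-180, 0]
* chemo following             [0, +180]
* symptom / treatment lookback [-180, -1]

MM diagnoses are counted as DISTINCT SERVICE DATES: multiple line items on
one day count once (duplicate billing rows must not inflate counts).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Iterable, Sequence

from .claims_model import (
    EnrollmentSpan,
    PatientHistory,
    ValidationError,
    spans_cover,
)
from .codesets import (
    DIAGNOSTIC_TEST_SETS,
    SYMPTOM_SETS,
    TREATMENT_SETS,
    CodeSetLibrary,
    claim_in_codeset,
)

__all__ = [
    "PanelParams",
    "IndexDiagnosis",
    "DiagnosisFeatures",
    "continuous_enrollment",
    "build_panel",
    "build_membership",
    "extract_features",
]

_DAY = _dt.timedelta(days=1)


@dataclass(frozen=True)
class PanelParams:
    pre_days: int = 90           # enrollment required before the index
    post_days: int = 30          # enrollment required after the index
    window_days: int = 180       # maximum lookback/lookahead
    test_lookback_days: int = 90
    post_gap_days: int = 30      # ">30 days following" boundary


@dataclass(frozen=True)
class IndexDiagnosis:
    patient_id: str
    index_date: _dt.date
    claim_id: str


@dataclass(frozen=True)
class DiagnosisFeatures:
    """Windowed feature vector around one index diagnosis."""

    index: IndexDiagnosis
    n_mm_dx_prior: int
    n_mm_dx_post: int
    has_mm_dx_post_30: bool
    test_counts_90: dict[str, int]   # per test set, [-90, 0]
    test_counts_180: dict[str, int]  # per test set, [-180, 0]
    chemo_prior_or_on: bool
    chemo_post: bool
    flags_prior: dict[str, bool]     # symptoms + treatments, [-180, -1]
    observed_days_prior: int
    observed_days_post: int


def continuous_enrollment(
    spans: Sequence[EnrollmentSpan],
    date: _dt.date,
    days_before: int,
    days_after: int,
) -> bool:
    """True iff one merged span covers [date - days_before, date + days_after]."""
    if days_before < 0 or days_after < 0:
        raise ValidationError("day arguments must be non-negative")
    return spans_cover(
        spans, date - _dt.timedelta(days=days_before), date + _dt.timedelta(days=days_after)
    )


def _mm_claims(history: PatientHistory, codesets: CodeSetLibrary):
    mm = codesets.mm_diagnosis
    return [c for c in history.medical_claims if claim_in_codeset(c, mm)]


def build_panel(
    history: PatientHistory,
    codesets: CodeSetLibrary,
    params: PanelParams = PanelParams(),
) -> list[IndexDiagnosis]:
    """All panel-eligible index diagnoses for one patient, in date order
    (claim_id tie-break)."""
    panel = []
    for c in _mm_claims(history, codesets):
        if continuous_enrollment(
            history.spans, c.service_date, params.pre_days, params.post_days
        ):
            panel.append(IndexDiagnosis(c.patient_id, c.service_date, c.claim_id))
    panel.sort(key=lambda ix: (ix.index_date, ix.claim_id))
    return panel


def _covered_days(
    spans: Sequence[EnrollmentSpan], lo: _dt.date, hi: _dt.date
) -> int:
    """Number of days in [lo, hi] covered by merged enrollment."""
    total = 0
    for s in spans:
        a, b = max(s.start_date, lo), min(s.end_date, hi)
        if a <= b:
            total += (b - a).days + 1
    return total


def build_membership(
    history: PatientHistory, codesets: CodeSetLibrary
) -> dict[str, set[str]]:
    """claim_id -> names of every code set the claim belongs to.

    Computing this once per patient (rather than once per index diagnosis)
    keeps feature extraction linear in the number of claims.
    """
    mem = {c.claim_id: codesets.membership(c) for c in history.medical_claims}
    mem.update({c.claim_id: codesets.membership(c) for c in history.drug_claims})
    return mem


def extract_features(
    index: IndexDiagnosis,
    history: PatientHistory,
    codesets: CodeSetLibrary,
    params: PanelParams = PanelParams(),
    membership: dict[str, set[str]] | None = None,
) -> DiagnosisFeatures:
    d0 = index.index_date
    W = params.window_days
    mem = membership if membership is not None else build_membership(history, codesets)

    def window(off_lo: int, off_hi: int) -> tuple[_dt.date, _dt.date]:
        return d0 + off_lo * _DAY, d0 + off_hi * _DAY

    mm_dates = {
        c.service_date
        for c in history.medical_claims
        if "mm_diagnosis" in mem[c.claim_id]
    }

    lo, hi = window(-W, -1)
    n_prior = sum(1 for d in mm_dates if lo <= d <= hi)
    lo, hi = window(1, W)
    n_post = sum(1 for d in mm_dates if lo <= d <= hi)
    lo, hi = window(params.post_gap_days + 1, W)
    has_post_30 = any(lo <= d <= hi for d in mm_dates)

    test_counts_90: dict[str, int] = {}
    test_counts_180: dict[str, int] = {}
    lo90, hi90 = window(-params.test_lookback_days, 0)
    lo180, hi180 = window(-W, 0)
    for cs in codesets.test_sets():
        dates = [
            c.service_date
            for c in history.medical_claims
            if cs.name in mem[c.claim_id]
        ]
        test_counts_90[cs.name] = sum(1 for d in dates if lo90 <= d <= hi90)
        test_counts_180[cs.name] = sum(1 for d in dates if lo180 <= d <= hi180)

    chemo_dates = [
        c.service_date
        for c in history.medical_claims
        if "chemotherapy" in mem[c.claim_id]
    ] + [
        c.fill_date for c in history.drug_claims if "chemotherapy" in mem[c.claim_id]
    ]
    lo, hi = window(-W, 0)
    chemo_prior_or_on = any(lo <= d <= hi for d in chemo_dates)
    lo, hi = window(0, W)
    chemo_post = any(lo <= d <= hi for d in chemo_dates)

    flags_prior: dict[str, bool] = {}
    lo, hi = window(-W, -1)
    for name in SYMPTOM_SETS + TREATMENT_SETS:
        if name not in codesets:
            continue
        hit = any(
            lo <= c.service_date <= hi and name in mem[c.claim_id]
            for c in history.medical_claims
        ) or any(
            lo <= c.fill_date <= hi and name in mem[c.claim_id]
            for c in history.drug_claims
        )
        flags_prior[name] = hit

    return DiagnosisFeatures(
        index=index,
        n_mm_dx_prior=n_prior,
        n_mm_dx_post=n_post,
        has_mm_dx_post_30=has_post_30,
        test_counts_90=test_counts_90,
        test_counts_180=test_counts_180,
        chemo_prior_or_on=chemo_prior_or_on,
        chemo_post=chemo_post,
        flags_prior=flags_prior,
        observed_days_prior=_covered_days(history.spans, *window(-W, -1)),
        observed_days_post=_covered_days(history.spans, *window(1, W)),
    )
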