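"""Development-phase descriptive summaries.

Two views are produced:

* patient-level annualized event rates by stratum (controls and the four
  incident/prevalent x treated/untreated case strata), and
* diagnosis-level window summaries (percent with >= 1 event and mean/SD of
  counts for each windowed feature).

"Treated" means at least one chemotherapy claim on or after the case's
anchor date within the observation period.  Chemotherapy days are counted
as distinct chemotherapy service dates.  In the diagnosis-level view,
index diagnoses of incident cases dated before the anchor are pooled with
control diagnoses (the patient was not yet a case on those dates).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .claims_model import ClaimsBundle, PatientHistory, build_histories
from .codesets import DIAGNOSTIC_TEST_SETS, CodeSetLibrary, claim_in_codeset
from .cohort import GoldLabel
from .panel import DiagnosisFeatures

__all__ = [
    "PATIENT_STRATA",
    "StratumSummary",
    "WindowSummary",
    "patient_stratum",
    "annualized_rates",
    "window_summaries",
]

PATIENT_STRATA = (
    "control",
    "incident_untreated",
    "prevalent_untreated",
    "incident_treated",
    "prevalent_treated",
)

_RATE_EVENTS = DIAGNOSTIC_TEST_SETS + ("mm_dx", "chemo_days")

_DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class StratumSummary:
    stratum: str
    n_patients: int
    mean_annual: dict[str, float]  # event name -> mean events/patient/year


@dataclass(frozen=True)
class WindowSummary:
    stratum: str  # control | case | case_untreated | case_treated
    n_diagnoses: int
    pct_with_event: dict[str, float]   # feature -> % of diagnoses with >= 1
    mean_count: dict[str, float]
    sd_count: dict[str, float]


def _is_treated(label: GoldLabel, history: PatientHistory, codesets: CodeSetLibrary) -> bool:
    chemo = codesets["chemotherapy"]
    return any(
        label.anchor_date <= c.service_date <= label.observation_end
        and claim_in_codeset(c, chemo)
        for c in history.medical_claims
    ) or any(
        label.anchor_date <= c.fill_date <= label.observation_end
        and claim_in_codeset(c, chemo)
        for c in history.drug_claims
    )


def patient_stratum(
    label: GoldLabel, history: PatientHistory, codesets: CodeSetLibrary
) -> str:
    if label.label == "control":
        return "control"
    incident = "incident" if label.incident else "prevalent"
    treated = "treated" if _is_treated(label, history, codesets) else "untreated"
    return f"{incident}_{treated}"


def annualized_rates(
    labels: Sequence[GoldLabel],
    bundle: ClaimsBundle,
    codesets: CodeSetLibrary,
    histories: Optional[dict[str, PatientHistory]] = None,
) -> list[StratumSummary]:
    """Per-stratum mean annualized event counts over each patient's
    observation period.  Empty strata are omitted.

    Per patient and event type: events inside the observation window
    divided by observation years.  MM diagnoses and chemotherapy days
    count distinct service dates; diagnostic tests count claims.
    """
    histories = histories if histories is not None else build_histories(bundle)
    per_stratum: dict[str, list[dict[str, float]]] = {s: [] for s in PATIENT_STRATA}
    chemo = codesets["chemotherapy"]
    mm = codesets.mm_diagnosis
    for label in labels:
        h = histories[label.patient_id]
        lo, hi = label.observation_start, label.observation_end
        years = ((hi - lo).days + 1) / _DAYS_PER_YEAR
        if years <= 0:
            raise ValueError(
                f"patient {label.patient_id!r}: zero-length observation period"
            )
        in_obs = [c for c in h.medical_claims if lo <= c.service_date <= hi]
        rates: dict[str, float] = {}
        for name in DIAGNOSTIC_TEST_SETS:
            cs = codesets[name]
            rates[name] = sum(1 for c in in_obs if claim_in_codeset(c, cs)) / years
        rates["mm_dx"] = (
            len({c.service_date for c in in_obs if claim_in_codeset(c, mm)}) / years
        )
        chemo_dates = {c.service_date for c in in_obs if claim_in_codeset(c, chemo)}
        chemo_dates |= {
            c.fill_date
            for c in h.drug_claims
            if lo <= c.fill_date <= hi and claim_in_codeset(c, chemo)
        }
        rates["chemo_days"] = len(chemo_dates) / years
        per_stratum[patient_stratum(label, h, codesets)].append(rates)

    out = []
    for stratum in PATIENT_STRATA:
        rows = per_stratum[stratum]
        if not rows:
            continue
        mean_annual = {
            ev: sum(r[ev] for r in rows) / len(rows) for ev in _RATE_EVENTS
        }
        out.append(
            StratumSummary(stratum=stratum, n_patients=len(rows), mean_annual=mean_annual)
        )
    return out


def _numeric_features(f: DiagnosisFeatures) -> dict[str, float]:
    out: dict[str, float] = {
        "n_mm_dx_prior": f.n_mm_dx_prior,
        "n_mm_dx_post": f.n_mm_dx_post,
        "has_mm_dx_post_30": int(f.has_mm_dx_post_30),
        "chemo_prior_or_on": int(f.chemo_prior_or_on),
        "chemo_post": int(f.chemo_post),
    }
    for name, v in f.test_counts_90.items():
        out[f"{name}_90d"] = v
    for name, v in f.test_counts_180.items():
        out[f"{name}_180d"] = v
    for name, v in f.flags_prior.items():
        out[name] = int(v)
    return out


def _diagnosis_stratum(feature: DiagnosisFeatures, label: GoldLabel, treated: bool) -> str:
    if label.label == "control":
        return "control"
    if label.incident and feature.index.index_date < label.anchor_date:
        # Not yet a case on that date: pooled with control diagnoses.
        return "control"
    return "case_treated" if treated else "case_untreated"


def window_summaries(
    panel_features: Sequence[tuple[DiagnosisFeatures, GoldLabel]],
    histories: dict[str, PatientHistory],
    codesets: CodeSetLibrary,
) -> list[WindowSummary]:
    """Diagnosis-level percent-with-event and mean (SD) by stratum.

    The ``case`` stratum aggregates treated and untreated case diagnoses;
    SDs use the n-1 denominator (SD of a singleton is 0).
    """
    groups: dict[str, list[dict[str, float]]] = {
        "control": [], "case": [], "case_untreated": [], "case_treated": []
    }
    treated_cache: dict[str, bool] = {}
    for feature, label in panel_features:
        if label.label == "case" and label.patient_id not in treated_cache:
            treated_cache[label.patient_id] = _is_treated(
                label, histories[label.patient_id], codesets
            )
        stratum = _diagnosis_stratum(
            feature, label, treated_cache.get(label.patient_id, False)
        )
        row = _numeric_features(feature)
        groups[stratum].append(row)
        if stratum in ("case_untreated", "case_treated"):
            groups["case"].append(row)

    out = []
    for stratum in ("control", "case", "case_untreated", "case_treated"):
        rows = groups[stratum]
        if not rows:
            continue
        features = sorted(rows[0])
        pct, mean, sd = {}, {}, {}
        n = len(rows)
        for ft in features:
            vals = [r[ft] for r in rows]
            pct[ft] = 100.0 * sum(1 for v in vals if v >= 1) / n
            m = sum(vals) / n
            mean[ft] = m
            sd[ft] = (
                math.sqrt(sum((v - m) ** 2 for v in vals) / (n - 1)) if n > 1 else 0.0
            )
        out.append(
            WindowSummary(
                stratum=stratum, n_diagnoses=n, pct_with_event=pct,
                mean_count=mean, sd_count=sd,
            )
        )
    return out
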