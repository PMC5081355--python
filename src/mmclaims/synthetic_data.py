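"""Seeded synthetic claims/EMR generator calibrated to published stratum
descriptives, plus deterministic archetype timelines for exact rule tests.

Counts per event type are Poisson with mean ``annual_rate x observation
years``.  MM-diagnosis dates are drawn as DISTINCT days; for cases they
follow a two-rate burst: a thin uniform scatter before the confirmed
diagnosis date and an exponentially decaying (plus uniform floor)
intensity after it.  The temporal shape is an artifact construct — only
the annual means are calibrated.  Chemotherapy days are realized as
administration claims on distinct dates grouped into consecutive-day
blocks, mimicking infusion-cycle billing.

Construction invariants (asserted by the test suite):

* controls carry zero chemotherapy and zero stem-cell-transplant claims
  and their notes never mention MM;
* every generated case passes case selection, every control passes
  control selection, and the incident/prevalent flag round-trips through
  ``classify_incident``;
* identical config + seed => byte-identical bundles.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .claims_model import (
    ClaimsBundle,
    DrugClaim,
    EnrollmentSpan,
    MedicalClaim,
    OncologyEmrRecord,
    Person,
    PrimaryCareNote,
)
from .codesets import (
    DIAGNOSTIC_TEST_SETS,
    SYMPTOM_SETS,
    TREATMENT_SETS,
    CodeSetLibrary,
    default_codesets,
)
from .cohort import GoldLabel

__all__ = [
    "STRATA",
    "TABLE_RATES",
    "TABLE_WINDOW_PROBS",
    "GeneratorConfig",
    "default_config_from_tables",
    "generate_population",
    "ArchetypeExpectation",
    "generate_archetypes",
]

STRATA = (
    "control",
    "incident_untreated",
    "prevalent_untreated",
    "incident_treated",
    "prevalent_treated",
)

_CASE_STRATA = STRATA[1:]
_TREATED_STRATA = ("incident_treated", "prevalent_treated")

#: Published per-stratum mean annual event counts (tests and chemotherapy
#: days per patient per year; MM diagnoses as distinct service dates).
TABLE_RATES: dict[str, dict[str, float]] = {
    "control": {
        "protein_electrophoresis": 1.20, "quantitative_immunoglobulin": 0.68,
        "serum_free_light_chain": 0.34, "serum_albumin": 0.05,
        "beta2_microglobulin": 0.28, "bone_marrow": 0.93,
        "skeletal_survey": 0.27, "ldh": 0.63,
        "mm_dx": 3.0, "chemo_days": 0.0,
    },
    "incident_untreated": {
        "protein_electrophoresis": 2.25, "quantitative_immunoglobulin": 1.36,
        "serum_free_light_chain": 1.12, "serum_albumin": 0.05,
        "beta2_microglobulin": 0.84, "bone_marrow": 0.88,
        "skeletal_survey": 0.60, "ldh": 0.77,
        "mm_dx": 8.0, "chemo_days": 0.0,
    },
    "prevalent_untreated": {
        "protein_electrophoresis": 3.80, "quantitative_immunoglobulin": 1.31,
        "serum_free_light_chain": 1.00, "serum_albumin": 0.04,
        "beta2_microglobulin": 0.65, "bone_marrow": 1.03,
        "skeletal_survey": 0.47, "ldh": 0.62,
        "mm_dx": 18.0, "chemo_days": 0.0,
    },
    "incident_treated": {
        "protein_electrophoresis": 4.80, "quantitative_immunoglobulin": 2.69,
        "serum_free_light_chain": 2.23, "serum_albumin": 0.14,
        "beta2_microglobulin": 1.27, "bone_marrow": 1.67,
        "skeletal_survey": 1.00, "ldh": 2.50,
        "mm_dx": 39.0, "chemo_days": 240.0,
    },
    "prevalent_treated": {
        "protein_electrophoresis": 5.37, "quantitative_immunoglobulin": 3.09,
        "serum_free_light_chain": 3.17, "serum_albumin": 0.09,
        "beta2_microglobulin": 1.93, "bone_marrow": 0.95,
        "skeletal_survey": 0.67, "ldh": 2.85,
        "mm_dx": 34.0, "chemo_days": 202.0,
    },
}

#: Published window-level percentages (as probabilities) for treatments and
#: symptoms, by diagnosis-level column: control / case-untreated / case-treated.
TABLE_WINDOW_PROBS: dict[str, dict[str, float]] = {
    col: {}
    for col in ("control", "case_untreated", "case_treated")
}
_WINDOW_ROWS = {
    "corticosteroid": (26.1, 28.3, 79.7),
    "bisphosphonate": (13.6, 54.2, 61.4),
    "anemia_treatment": (13.8, 18.0, 31.9),
    "monoclonal_gammopathy": (19.3, 4.1, 12.6),
    "other_malignancy": (18.6, 12.4, 19.2),
    "anemia_diagnosis": (29.1, 24.8, 38.2),
    "osteoporosis_diagnosis": (3.4, 0.9, 1.7),
    "skeletal_related_event": (9.3, 7.6, 13.6),
    "bone_pain_lesion": (7.2, 5.0, 10.0),
    "fatigue": (9.7, 5.4, 12.6),
    "shortness_of_breath": (7.6, 9.6, 9.9),
    "chest_pain": (13.8, 14.3, 16.3),
    "peripheral_neuropathy": (4.8, 3.0, 2.9),
    "renal_failure": (15.2, 11.1, 23.9),
    "hypercalcemia": (1.0, 2.7, 5.3),
    "pneumonia": (7.7, 4.6, 7.7),
    "herpes_zoster": (1.3, 2.1, 2.6),
    "urinary_tract_infection": (9.1, 6.6, 4.8),
}
for _name, (_c, _u, _t) in _WINDOW_ROWS.items():
    TABLE_WINDOW_PROBS["control"][_name] = _c / 100.0
    TABLE_WINDOW_PROBS["case_untreated"][_name] = _u / 100.0
    TABLE_WINDOW_PROBS["case_treated"][_name] = _t / 100.0

_DEFAULT_N = {
    "control": 140,
    "incident_untreated": 12,
    "prevalent_untreated": 4,
    "incident_treated": 36,
    "prevalent_treated": 16,
}

_MM_DX_CODES = ("20300", "20301")
_DAY = _dt.timedelta(days=1)


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything the generator needs; defaults are table-calibrated.

    ``pre_anchor_fraction`` is the share of a case's MM-diagnosis dates
    falling before the confirmed diagnosis date; ``burst_half_life_days``
    and ``post_burst_floor`` shape the post-diagnosis intensity decay.
    Enrollment durations are drawn uniformly (in days) from
    ``enrollment_years``; the default minimum of 2 years leaves room for
    the heaviest chemotherapy calendars without truncation bias.
    """

    n: dict[str, int] = field(default_factory=lambda: dict(_DEFAULT_N))
    annual_rates: dict[str, dict[str, float]] = field(
        default_factory=lambda: {s: dict(r) for s, r in TABLE_RATES.items()}
    )
    window_probs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {c: dict(p) for c, p in TABLE_WINDOW_PROBS.items()}
    )
    enrollment_years: tuple[float, float] = (2.0, 4.0)
    pre_anchor_fraction: dict[str, float] = field(
        default_factory=lambda: {
            "incident_untreated": 0.12, "prevalent_untreated": 0.40,
            "incident_treated": 0.12, "prevalent_treated": 0.40,
        }
    )
    burst_half_life_days: float = 120.0
    post_burst_floor: float = 0.25
    test_near_anchor_fraction: float = 0.5
    age_range: tuple[int, int] = (40, 80)
    study_start: _dt.date = _dt.date(2005, 1, 1)
    start_jitter_days: int = 1500
    seed: int = 0

    def validate(self) -> None:
        for s, count in self.n.items():
            if s not in STRATA:
                raise ValueError(f"unknown stratum {s!r}")
            if count < 0:
                raise ValueError(f"n[{s!r}] must be >= 0")
        for s in STRATA:
            for ev, rate in self.annual_rates[s].items():
                if rate < 0:
                    raise ValueError(f"annual_rates[{s!r}][{ev!r}] must be >= 0")
        for col, probs in self.window_probs.items():
            for name, p in probs.items():
                if not 0 <= p <= 1:
                    raise ValueError(f"window_probs[{col!r}][{name!r}] not in [0,1]")
        if self.enrollment_years[0] <= 0 or self.enrollment_years[0] > self.enrollment_years[1]:
            raise ValueError("enrollment_years must be an increasing positive pair")


def default_config_from_tables(
    n: Optional[dict[str, int]] = None, seed: int = 0
) -> GeneratorConfig:
    """Config whose rates and window probabilities equal the published
    table values."""
    cfg = GeneratorConfig(seed=seed)
    if n is not None:
        merged = dict(_DEFAULT_N)
        merged.update(n)
        cfg = replace(cfg, n=merged)
    cfg.validate()
    return cfg


class _IdFactory:
    def __init__(self) -> None:
        self._claim = 0
        self._patient = 0

    def patient(self) -> str:
        self._patient += 1
        return f"P{self._patient:06d}"

    def claim(self) -> str:
        self._claim += 1
        return f"C{self._claim:08d}"


def _sample_distinct_days(
    rng: np.random.Generator,
    lo: _dt.date,
    hi: _dt.date,
    n: int,
    weights: Optional[np.ndarray] = None,
) -> list[_dt.date]:
    """n distinct days in [lo, hi], optionally intensity-weighted; clips n
    to the window size."""
    n_days = (hi - lo).days + 1
    if n_days <= 0 or n <= 0:
        return []
    n = min(n, n_days)
    if weights is not None:
        p = weights / weights.sum()
        offs = rng.choice(n_days, size=n, replace=False, p=p)
    else:
        offs = rng.choice(n_days, size=n, replace=False)
    return [lo + int(o) * _DAY for o in sorted(offs)]


def _burst_weights(cfg: GeneratorConfig, n_days: int) -> np.ndarray:
    scale = cfg.burst_half_life_days / np.log(2.0)
    d = np.arange(n_days, dtype=float)
    return cfg.post_burst_floor + np.exp(-d / scale)


def _chemo_cycle_days(
    rng: np.random.Generator, lo: _dt.date, hi: _dt.date, n: int
) -> list[_dt.date]:
    """n distinct days in [lo, hi] grouped into blocks of consecutive days
    (infusion cycles of 4-5 days)."""
    avail = (hi - lo).days + 1
    if avail <= 0 or n <= 0:
        return []
    n = min(n, avail)
    days: set[int] = set()
    cursor = 0
    while len(days) < n and cursor < avail:
        block = int(rng.integers(4, 6))
        for k in range(block):
            if len(days) >= n or cursor + k >= avail:
                break
            days.add(cursor + k)
        # spread remaining cycles over the remaining room
        remaining_cycles = max(1, (n - len(days)) // 4)
        room = avail - (cursor + block)
        gap = max(2, room // (remaining_cycles + 1)) if room > 0 else 2
        cursor += block + int(rng.integers(2, gap + 2))
    # top up (window nearly saturated): fill arbitrary free days
    free = [d for d in range(avail) if d not in days]
    rng.shuffle(free)
    for d in free[: n - len(days)]:
        days.add(d)
    return [lo + d * _DAY for d in sorted(days)]


def _window_column(stratum: str) -> str:
    if stratum == "control":
        return "control"
    return "case_treated" if stratum in _TREATED_STRATA else "case_untreated"


def generate_population(
    config: GeneratorConfig,
    seed: Optional[int] = None,
    codesets: Optional[CodeSetLibrary] = None,
) -> tuple[ClaimsBundle, list[GoldLabel]]:
    """Generate a bundle plus ground-truth labels, deterministically."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    codesets = codesets if codesets is not None else default_codesets()
    ids = _IdFactory()
    bundle = ClaimsBundle()
    labels: list[GoldLabel] = []

    for stratum in STRATA:
        for _ in range(config.n.get(stratum, 0)):
            _generate_patient(stratum, config, rng, codesets, ids, bundle, labels)

    bundle.validate()
    bundle.sort()
    labels.sort(key=lambda l: l.patient_id)
    return bundle, labels


def _generate_patient(
    stratum: str,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    codesets: CodeSetLibrary,
    ids: _IdFactory,
    bundle: ClaimsBundle,
    labels: list[GoldLabel],
) -> None:
    pid = ids.patient()
    lo_y, hi_y = cfg.enrollment_years
    duration = int(rng.integers(round(lo_y * 365.25), round(hi_y * 365.25) + 1))
    start = cfg.study_start + int(rng.integers(0, cfg.start_jitter_days + 1)) * _DAY
    end = start + (duration - 1) * _DAY
    years = duration / 365.25
    rates = cfg.annual_rates[stratum]
    is_case = stratum != "control"

    if is_case:
        if stratum.startswith("incident"):
            anchor = start + (90 + int(rng.integers(0, 61))) * _DAY
        else:
            anchor = start + (180 + int(rng.integers(0, 186))) * _DAY
    else:
        anchor = start

    age = int(rng.integers(cfg.age_range[0], cfg.age_range[1] + 1))
    sex = "M" if rng.random() < 0.5 else "F"
    bundle.persons.append(Person(pid, anchor.year - age, sex))
    bundle.enrollment.append(EnrollmentSpan(pid, start, end))

    def add_dx_claim(date: _dt.date, codes: tuple[str, ...]) -> None:
        bundle.medical_claims.append(
            MedicalClaim(ids.claim(), pid, date, diagnosis_codes=codes)
        )

    def add_proc_claim(
        date: _dt.date, cs_name: str, codes: tuple[str, ...] = ()
    ) -> None:
        cs = codesets[cs_name]
        bundle.medical_claims.append(
            MedicalClaim(
                ids.claim(), pid, date,
                diagnosis_codes=codes,
                procedure_code=cs.example_code(),
                procedure_system=cs.system,
            )
        )

    def mm_code() -> tuple[str, ...]:
        return (_MM_DX_CODES[int(rng.integers(0, len(_MM_DX_CODES)))],)

    # --- MM diagnosis dates (distinct days) ---
    n_mm = max(1, int(rng.poisson(rates["mm_dx"] * years)))
    if is_case:
        n_pre = int(rng.binomial(n_mm - 1, cfg.pre_anchor_fraction[stratum])) if n_mm > 1 else 0
        mm_dates = _sample_distinct_days(rng, start, anchor - _DAY, n_pre)
        mm_dates.append(anchor)  # the confirmed diagnosis day is always coded
        n_post = n_mm - 1 - len(mm_dates[:-1])
        post_lo = anchor + _DAY
        if n_post > 0 and post_lo <= end:
            w = _burst_weights(cfg, (end - post_lo).days + 1)
            mm_dates.extend(_sample_distinct_days(rng, post_lo, end, n_post, weights=w))
    else:
        mm_dates = _sample_distinct_days(rng, start, end, n_mm)
    for d in mm_dates:
        add_dx_claim(d, mm_code())

    # --- diagnostic tests (per-claim counts, with replacement) ---
    for name in DIAGNOSTIC_TEST_SETS:
        count = int(rng.poisson(rates[name] * years))
        for _ in range(count):
            if is_case and rng.random() < cfg.test_near_anchor_fraction:
                w_lo = max(start, anchor - 90 * _DAY)
                off = int(rng.integers(0, (anchor - w_lo).days + 1))
                date = w_lo + off * _DAY
            else:
                date = start + int(rng.integers(0, duration)) * _DAY
            add_proc_claim(date, name)

    # --- chemotherapy ---
    mm_marker_dates: list[_dt.date] = []
    if stratum in _TREATED_STRATA:
        n_chemo = int(rng.poisson(rates["chemo_days"] * years))
        for d in _chemo_cycle_days(rng, anchor, end, n_chemo):
            add_proc_claim(d, "chemotherapy")
    if is_case and stratum.startswith("prevalent"):
        # the claim that makes this patient prevalent: pre-anchor
        # chemotherapy carrying an MM diagnosis code on the same record
        marker = start + int(rng.integers(10, (anchor - start).days - 10)) * _DAY
        add_proc_claim(marker, "chemotherapy", codes=mm_code())
        mm_marker_dates.append(marker)

    # --- window-level symptom / treatment draws ---
    probs = cfg.window_probs[_window_column(stratum)]
    if is_case:
        sym_lo, sym_hi = max(start, anchor - 180 * _DAY), anchor - _DAY
    else:
        sym_lo, sym_hi = start, end
    for name in SYMPTOM_SETS + TREATMENT_SETS:
        p = probs.get(name, 0.0)
        if rng.random() >= p or sym_lo > sym_hi:
            continue
        date = sym_lo + int(rng.integers(0, (sym_hi - sym_lo).days + 1)) * _DAY
        cs = codesets[name]
        if cs.system == "NDC":
            bundle.drug_claims.append(
                DrugClaim(ids.claim(), pid, date, cs.example_code(), days_supply=30)
            )
        elif cs.system == "ICD9DX":
            add_dx_claim(date, (cs.example_code(),))
        else:
            add_proc_claim(date, name)

    # --- EMR tables and the truth label ---
    if is_case:
        bundle.emr_oncology.append(
            OncologyEmrRecord(pid, anchor, anchor, "Multiple Myeloma")
        )
        labels.append(
            GoldLabel(
                patient_id=pid, label="case", anchor_date=anchor,
                incident=stratum.startswith("incident"),
                observation_start=start, observation_end=end,
            )
        )
    else:
        bundle.emr_notes.append(PrimaryCareNote(pid, start, "annual wellness visit"))
        bundle.emr_notes.append(PrimaryCareNote(pid, end, "routine follow-up"))
        labels.append(
            GoldLabel(
                patient_id=pid, label="control", anchor_date=start,
                incident=None, observation_start=start, observation_end=end,
            )
        )


# ---------------------------------------------------------------------------
# Archetypes: literal rule-clause instantiations with hand-derived outcomes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ArchetypeExpectation:
    """Expected flag day (relative to the archetype's day 0) per spec key,
    ``None`` meaning not flagged."""

    name: str
    patient_id: str
    day0: _dt.date
    expected: dict[str, Optional[int]]

    def expected_date(self, spec_key: str) -> Optional[_dt.date]:
        rel = self.expected[spec_key]
        return None if rel is None else self.day0 + rel * _DAY


_SPEC_KEYS = (
    "baseline",
    "algorithm2:or_standalone",
    "algorithm2:or_with_sequence",
    "algorithm2:or_inner",
)


def generate_archetypes(
    base_date: _dt.date = _dt.date(2010, 6, 1),
    codesets: Optional[CodeSetLibrary] = None,
) -> tuple[ClaimsBundle, list[ArchetypeExpectation]]:
    """A fixed micro-population of hand-built timelines.

    Each archetype's event days are offsets from its day 0 (``base_date``);
    enrollment spans day -365 .. +365 so every MM-diagnosis claim is
    panel-eligible.  Expected flag days were derived by hand-evaluating
    the earliest-qualifying-index scan over each timeline and are frozen
    here as the ground truth for the engine and the brute-force oracle.
    """
    codesets = codesets if codesets is not None else default_codesets()
    bundle = ClaimsBundle()
    expectations: list[ArchetypeExpectation] = []
    ids = _IdFactory()

    test_code = codesets["protein_electrophoresis"].example_code()
    bm_code = codesets["bone_marrow"].example_code()
    chemo_code = codesets["chemotherapy"].example_code()

    def build(
        name: str,
        mm_days: list[int],
        test_days: list[int] = (),
        bm_days: list[int] = (),
        chemo_days: list[int] = (),
        dup_mm_days: list[int] = (),
        expected: dict[str, Optional[int]] = None,
    ) -> None:
        pid = ids.patient()
        bundle.persons.append(Person(pid, base_date.year - 60, "F"))
        bundle.enrollment.append(
            EnrollmentSpan(pid, base_date - 365 * _DAY, base_date + 365 * _DAY)
        )
        for d in list(mm_days) + list(dup_mm_days):
            bundle.medical_claims.append(
                MedicalClaim(ids.claim(), pid, base_date + d * _DAY, ("20300",))
            )
        for d in test_days:
            bundle.medical_claims.append(
                MedicalClaim(
                    ids.claim(), pid, base_date + d * _DAY,
                    procedure_code=test_code, procedure_system="CPT4",
                )
            )
        for d in bm_days:
            bundle.medical_claims.append(
                MedicalClaim(
                    ids.claim(), pid, base_date + d * _DAY,
                    procedure_code=bm_code, procedure_system="CPT4",
                )
            )
        for d in chemo_days:
            bundle.medical_claims.append(
                MedicalClaim(
                    ids.claim(), pid, base_date + d * _DAY,
                    procedure_code=chemo_code, procedure_system="CPT4",
                )
            )
        expectations.append(
            ArchetypeExpectation(name=name, patient_id=pid, day0=base_date, expected=expected)
        )

    # A∧B∧C satisfied at day 0 (earlier indexes fail B: tests postdate them).
    build(
        "abc",
        mm_days=[-60, -50, 0, 45],
        test_days=[-40, -20],
        expected={
            "baseline": -60,
            "algorithm2:or_standalone": 0,
            "algorithm2:or_with_sequence": 0,
            "algorithm2:or_inner": 0,
        },
    )
    # Only the chemotherapy disjunct holds.
    build(
        "d_only",
        mm_days=[0],
        chemo_days=[10],
        expected={
            "baseline": None,
            "algorithm2:or_standalone": 0,
            "algorithm2:or_with_sequence": None,
            "algorithm2:or_inner": None,
        },
    )
    # B fails (a single test, no bone marrow, no chemotherapy).
    build(
        "fails_b",
        mm_days=[-60, -50, 0, 45],
        test_days=[-40],
        expected={
            "baseline": -60,
            "algorithm2:or_standalone": None,
            "algorithm2:or_with_sequence": None,
            "algorithm2:or_inner": None,
        },
    )
    # C boundary: one prior diagnosis coincides with the earliest test day,
    # so only one is STRICTLY before the anchor.
    build(
        "c_boundary_fail",
        mm_days=[-41, -40, 0, 45],
        test_days=[-40, -20],
        expected={
            "baseline": -41,
            "algorithm2:or_standalone": None,
            "algorithm2:or_with_sequence": None,
            "algorithm2:or_inner": None,
        },
    )
    # C boundary pass: both prior diagnoses strictly precede the anchor.
    build(
        "c_boundary_pass",
        mm_days=[-45, -41, 0, 45],
        test_days=[-40, -20],
        expected={
            "baseline": -45,
            "algorithm2:or_standalone": 0,
            "algorithm2:or_with_sequence": 0,
            "algorithm2:or_inner": 0,
        },
    )
    # Two distinct diagnosis dates and nothing else: baseline only.
    build(
        "baseline_pair",
        mm_days=[0, 10],
        expected={
            "baseline": 0,
            "algorithm2:or_standalone": None,
            "algorithm2:or_with_sequence": None,
            "algorithm2:or_inner": None,
        },
    )
    # Same-day duplicate billing must not qualify as "2 MM diagnoses".
    build(
        "duplicate_day",
        mm_days=[0],
        dup_mm_days=[0, 0],
        expected={
            "baseline": None,
            "algorithm2:or_standalone": None,
            "algorithm2:or_with_sequence": None,
            "algorithm2:or_inner": None,
        },
    )
    # B satisfied by a lone bone-marrow claim; anchor is the bone-marrow day.
    build(
        "bone_marrow_route",
        mm_days=[-60, -50, 0, 45],
        bm_days=[-5],
        expected={
            "baseline": -60,
            "algorithm2:or_standalone": 0,
            "algorithm2:or_with_sequence": 0,
            "algorithm2:or_inner": 0,
        },
    )

    bundle.validate()
    bundle.sort()
    return bundle, expectations
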