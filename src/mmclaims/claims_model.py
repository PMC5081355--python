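"""Longitudinal claims data model and delimited-table interchange format.

Every downstream module (cohort construction, panel building, the rule
engine) operates on the types defined here.  All temporal logic in the
package works on whole calendar days: claims carry service dates only, so
there are no times of day anywhere.

The on-disk interchange format is a directory of six comma-delimited UTF-8
tables with ISO-8601 dates (see :func:`read_bundle` / :func:`write_bundle`).
A medical claim may carry more than four diagnosis codes; the table format
has four fixed slots, so such a claim is written as several rows sharing a
``claim_id`` and reassembled on read.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "ClaimsDataError",
    "SchemaError",
    "RowParseError",
    "ReferentialIntegrityError",
    "ValidationError",
    "EnrollmentSpan",
    "MedicalClaim",
    "DrugClaim",
    "Person",
    "OncologyEmrRecord",
    "PrimaryCareNote",
    "ClaimsBundle",
    "PatientHistory",
    "canonicalize_code",
    "merge_enrollment",
    "spans_cover",
    "read_bundle",
    "write_bundle",
    "build_histories",
]

PROCEDURE_SYSTEMS = ("CPT4", "HCPCS", "ICD9PROC")
SEXES = ("M", "F", "U")

_MIN_BIRTH_YEAR = 1880
_MAX_DX_SLOTS = 4


class ClaimsDataError(Exception):
    """Base class for all data-layer failures."""


class SchemaError(ClaimsDataError):
    """A table is missing, or a required column is absent."""


class RowParseError(ClaimsDataError):
    """A row value could not be parsed; carries table name and row index."""

    def __init__(self, table: str, row: int, message: str):
        super().__init__(f"{table} row {row}: {message}")
        self.table = table
        self.row = row


class ReferentialIntegrityError(ClaimsDataError):
    """An event table references a patient_id absent from persons."""


class ValidationError(ClaimsDataError):
    """A record violates a field-level invariant."""


def canonicalize_code(code: str) -> str:
    """Return the canonical form of a clinical code: stripped, dotless, upper-case.

    Idempotent: canonicalizing a canonical code is a no-op.
    """
    return code.strip().replace(".", "").upper()


@dataclass(frozen=True)
class EnrollmentSpan:
    """One continuous insurance-coverage interval, inclusive on both ends."""

    patient_id: str
    start_date: _dt.date
    end_date: _dt.date

    def __post_init__(self) -> None:
        if self.start_date > self.end_date:
            raise ValidationError(
                f"enrollment span for {self.patient_id!r}: start_date "
                f"{self.start_date} after end_date {self.end_date}"
            )

    @property
    def n_days(self) -> int:
        return (self.end_date - self.start_date).days + 1

    def covers(self, lo: _dt.date, hi: _dt.date) -> bool:
        return self.start_date <= lo and hi <= self.end_date


@dataclass(frozen=True)
class MedicalClaim:
    """A medical service claim: diagnosis codes and/or one procedure code.

    Diagnosis codes are stored dotless and upper-case (canonical form).
    ``procedure_system`` is required whenever ``procedure_code`` is present.
    """

    claim_id: str
    patient_id: str
    service_date: _dt.date
    diagnosis_codes: tuple[str, ...] = ()
    procedure_code: Optional[str] = None
    procedure_system: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.diagnosis_codes and not self.procedure_code:
            raise ValidationError(
                f"claim {self.claim_id!r}: no diagnosis codes and no procedure code"
            )
        if self.procedure_code is not None and self.procedure_system not in PROCEDURE_SYSTEMS:
            raise ValidationError(
                f"claim {self.claim_id!r}: procedure_system must be one of "
                f"{PROCEDURE_SYSTEMS}, got {self.procedure_system!r}"
            )
        if self.procedure_code is None and self.procedure_system is not None:
            raise ValidationError(
                f"claim {self.claim_id!r}: procedure_system without procedure_code"
            )
        for c in self.diagnosis_codes:
            if "." in c or c != c.upper():
                raise ValidationError(
                    f"claim {self.claim_id!r}: diagnosis code {c!r} not canonical"
                )


@dataclass(frozen=True)
class DrugClaim:
    """An outpatient pharmacy fill identified by NDC."""

    claim_id: str
    patient_id: str
    fill_date: _dt.date
    ndc: str
    days_supply: int

    def __post_init__(self) -> None:
        if self.days_supply < 1:
            raise ValidationError(
                f"drug claim {self.claim_id!r}: days_supply must be >= 1"
            )


@dataclass(frozen=True)
class Person:
    patient_id: str
    birth_year: int
    sex: str = "U"

    def __post_init__(self) -> None:
        current_year = _dt.date.today().year
        if not (_MIN_BIRTH_YEAR <= self.birth_year <= current_year):
            raise ValidationError(
                f"person {self.patient_id!r}: implausible birth_year {self.birth_year}"
            )
        if self.sex not in SEXES:
            raise ValidationError(
                f"person {self.patient_id!r}: sex must be one of {SEXES}"
            )

    def age_at(self, date: _dt.date) -> int:
        """Age in whole years at ``date`` (year precision; claims extracts
        carry birth year only)."""
        return date.year - self.birth_year


@dataclass(frozen=True)
class OncologyEmrRecord:
    """An oncology-EMR diagnosis record; the case gold-standard source."""

    patient_id: str
    emr_dx_date: _dt.date
    visit_date: Optional[_dt.date]
    diagnosis_label: str


@dataclass(frozen=True)
class PrimaryCareNote:
    """A free-text primary-care EMR note; the control exclusion source."""

    patient_id: str
    note_date: _dt.date
    note_text: str


@dataclass
class ClaimsBundle:
    """All event tables for a population, keyed by patient_id.

    Invariant: every patient_id referenced by an event table exists in
    ``persons`` (checked by :meth:`validate`).
    """

    persons: list[Person] = field(default_factory=list)
    enrollment: list[EnrollmentSpan] = field(default_factory=list)
    medical_claims: list[MedicalClaim] = field(default_factory=list)
    drug_claims: list[DrugClaim] = field(default_factory=list)
    emr_oncology: list[OncologyEmrRecord] = field(default_factory=list)
    emr_notes: list[PrimaryCareNote] = field(default_factory=list)

    def patient_ids(self) -> set[str]:
        return {p.patient_id for p in self.persons}

    def validate(self) -> None:
        known = self.patient_ids()
        if len(known) != len(self.persons):
            raise ValidationError("duplicate patient_id in persons")
        for table, records in (
            ("enrollment", self.enrollment),
            ("medical_claims", self.medical_claims),
            ("drug_claims", self.drug_claims),
            ("emr_oncology", self.emr_oncology),
            ("emr_notes", self.emr_notes),
        ):
            for r in records:
                if r.patient_id not in known:
                    raise ReferentialIntegrityError(
                        f"{table}: patient_id {r.patient_id!r} not in persons"
                    )

    def sort(self) -> None:
        """Impose the canonical deterministic row order in place."""
        self.persons.sort(key=lambda p: p.patient_id)
        self.enrollment.sort(key=lambda s: (s.patient_id, s.start_date, s.end_date))
        self.medical_claims.sort(
            key=lambda c: (c.patient_id, c.service_date, c.claim_id)
        )
        self.drug_claims.sort(key=lambda c: (c.patient_id, c.fill_date, c.claim_id))
        self.emr_oncology.sort(
            key=lambda r: (r.patient_id, r.emr_dx_date, r.visit_date or r.emr_dx_date)
        )
        self.emr_notes.sort(key=lambda n: (n.patient_id, n.note_date, n.note_text))


@dataclass(frozen=True)
class PatientHistory:
    """One patient's complete event stream, with enrollment pre-merged."""

    person: Person
    spans: tuple[EnrollmentSpan, ...]
    medical_claims: tuple[MedicalClaim, ...]
    drug_claims: tuple[DrugClaim, ...]
    emr_oncology: tuple[OncologyEmrRecord, ...]
    notes: tuple[PrimaryCareNote, ...]


def merge_enrollment(
    spans: Sequence[EnrollmentSpan], gap_days: int = 0
) -> list[EnrollmentSpan]:
    """Collapse one patient's spans into a minimal non-overlapping set.

    Two spans merge when they overlap or when the gap between them is at
    most ``gap_days`` (default 0: the second must start exactly one day
    after the first ends).  Output is independent of input order.
    """
    if not spans:
        return []
    pids = {s.patient_id for s in spans}
    if len(pids) > 1:
        raise ValidationError(f"merge_enrollment: spans from multiple patients {pids}")
    ordered = sorted(spans, key=lambda s: (s.start_date, s.end_date))
    merged = [ordered[0]]
    for s in ordered[1:]:
        last = merged[-1]
        if (s.start_date - last.end_date).days <= 1 + gap_days:
            if s.end_date > last.end_date:
                merged[-1] = replace(last, end_date=s.end_date)
        else:
            merged.append(s)
    return merged


def spans_cover(
    spans: Iterable[EnrollmentSpan], lo: _dt.date, hi: _dt.date
) -> bool:
    """True iff a single span fully covers [lo, hi].  Spans must be merged."""
    return any(s.covers(lo, hi) for s in spans)


def build_histories(bundle: ClaimsBundle, gap_days: int = 0) -> dict[str, PatientHistory]:
    """Index a validated bundle by patient, merging enrollment spans."""
    by_pid: dict[str, dict[str, list]] = {
        p.patient_id: {"spans": [], "med": [], "drug": [], "onc": [], "notes": []}
        for p in bundle.persons
    }
    for s in bundle.enrollment:
        by_pid[s.patient_id]["spans"].append(s)
    for c in bundle.medical_claims:
        by_pid[c.patient_id]["med"].append(c)
    for c in bundle.drug_claims:
        by_pid[c.patient_id]["drug"].append(c)
    for r in bundle.emr_oncology:
        by_pid[r.patient_id]["onc"].append(r)
    for n in bundle.emr_notes:
        by_pid[n.patient_id]["notes"].append(n)
    out = {}
    for p in sorted(bundle.persons, key=lambda p: p.patient_id):
        d = by_pid[p.patient_id]
        out[p.patient_id] = PatientHistory(
            person=p,
            spans=tuple(merge_enrollment(d["spans"], gap_days=gap_days)),
            medical_claims=tuple(
                sorted(d["med"], key=lambda c: (c.service_date, c.claim_id))
            ),
            drug_claims=tuple(
                sorted(d["drug"], key=lambda c: (c.fill_date, c.claim_id))
            ),
            emr_oncology=tuple(sorted(d["onc"], key=lambda r: r.emr_dx_date)),
            notes=tuple(sorted(d["notes"], key=lambda n: (n.note_date, n.note_text))),
        )
    return out


# ---------------------------------------------------------------------------
# Delimited-table interchange
# ---------------------------------------------------------------------------

_TABLES: dict[str, list[str]] = {
    "persons": ["patient_id", "birth_year", "sex"],
    "enrollment": ["patient_id", "start_date", "end_date"],
    "medical_claims": [
        "claim_id", "patient_id", "service_date",
        "dx1", "dx2", "dx3", "dx4", "proc_code", "proc_system",
    ],
    "drug_claims": ["claim_id", "patient_id", "fill_date", "ndc", "days_supply"],
    "emr_oncology": ["patient_id", "emr_dx_date", "visit_date", "diagnosis_label"],
    "emr_notes": ["patient_id", "note_date", "note_text"],
}


def _read_table(directory: Path, name: str) -> pd.DataFrame:
    path = directory / f"{name}.csv"
    if not path.exists():
        raise SchemaError(f"missing table: {path.name}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in _TABLES[name]:
        if col not in df.columns:
            raise SchemaError(f"table {name!r}: missing column {col!r}")
    return df


def _parse_date(value: str, table: str, row: int, allow_empty: bool = False):
    if value == "":
        if allow_empty:
            return None
        raise RowParseError(table, row, "empty date")
    try:
        return _dt.date.fromisoformat(value)
    except ValueError as exc:
        raise RowParseError(table, row, f"unparseable date {value!r}") from exc


def read_bundle(directory: str | Path, gap_days: int = 0) -> ClaimsBundle:
    """Read, canonicalize, and validate a bundle directory.

    Rows are re-sorted into the canonical deterministic order; diagnosis
    codes are canonicalized (dots stripped, upper-cased); medical-claim
    rows sharing a claim_id are reassembled into a single claim.
    """
    directory = Path(directory)
    bundle = ClaimsBundle()

    df = _read_table(directory, "persons")
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            birth_year = int(row.birth_year)
        except ValueError as exc:
            raise RowParseError("persons", i, f"bad birth_year {row.birth_year!r}") from exc
        bundle.persons.append(Person(row.patient_id, birth_year, row.sex or "U"))

    df = _read_table(directory, "enrollment")
    for i, row in enumerate(df.itertuples(index=False)):
        bundle.enrollment.append(
            EnrollmentSpan(
                row.patient_id,
                _parse_date(row.start_date, "enrollment", i),
                _parse_date(row.end_date, "enrollment", i),
            )
        )

    df = _read_table(directory, "medical_claims")
    # Rows sharing claim_id are fragments of one claim (>4 dx codes).
    partial: dict[str, dict] = {}
    order: list[str] = []
    for i, row in enumerate(df.itertuples(index=False)):
        date = _parse_date(row.service_date, "medical_claims", i)
        dxs = [canonicalize_code(c) for c in (row.dx1, row.dx2, row.dx3, row.dx4) if c]
        if row.claim_id in partial:
            frag = partial[row.claim_id]
            if frag["patient_id"] != row.patient_id or frag["date"] != date:
                raise RowParseError(
                    "medical_claims", i,
                    f"claim_id {row.claim_id!r} fragments disagree on patient/date",
                )
            frag["dxs"].extend(dxs)
            if row.proc_code and not frag["proc"]:
                frag["proc"] = (row.proc_code, row.proc_system or None)
        else:
            order.append(row.claim_id)
            partial[row.claim_id] = {
                "patient_id": row.patient_id,
                "date": date,
                "dxs": dxs,
                "proc": (row.proc_code, row.proc_system or None) if row.proc_code else None,
            }
    for cid in order:
        frag = partial[cid]
        proc_code, proc_system = frag["proc"] if frag["proc"] else (None, None)
        bundle.medical_claims.append(
            MedicalClaim(
                claim_id=cid,
                patient_id=frag["patient_id"],
                service_date=frag["date"],
                diagnosis_codes=tuple(frag["dxs"]),
                procedure_code=proc_code,
                procedure_system=proc_system,
            )
        )

    df = _read_table(directory, "drug_claims")
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            days_supply = int(row.days_supply)
        except ValueError as exc:
            raise RowParseError(
                "drug_claims", i, f"bad days_supply {row.days_supply!r}"
            ) from exc
        bundle.drug_claims.append(
            DrugClaim(
                row.claim_id,
                row.patient_id,
                _parse_date(row.fill_date, "drug_claims", i),
                canonicalize_code(row.ndc),
                days_supply,
            )
        )

    df = _read_table(directory, "emr_oncology")
    for i, row in enumerate(df.itertuples(index=False)):
        bundle.emr_oncology.append(
            OncologyEmrRecord(
                row.patient_id,
                _parse_date(row.emr_dx_date, "emr_oncology", i),
                _parse_date(row.visit_date, "emr_oncology", i, allow_empty=True),
                row.diagnosis_label,
            )
        )

    df = _read_table(directory, "emr_notes")
    for i, row in enumerate(df.itertuples(index=False)):
        bundle.emr_notes.append(
            PrimaryCareNote(
                row.patient_id, _parse_date(row.note_date, "emr_notes", i), row.note_text
            )
        )

    bundle.validate()
    bundle.sort()
    return bundle


def _chunk(seq: Sequence[str], size: int) -> list[tuple[str, ...]]:
    return [tuple(seq[i : i + size]) for i in range(0, len(seq), size)] or [()]


def write_bundle(bundle: ClaimsBundle, directory: str | Path) -> None:
    """Write a bundle to the interchange layout.  read∘write is identity."""
    bundle.validate()
    bundle.sort()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    rows: Mapping[str, list] = {name: [] for name in _TABLES}
    for p in bundle.persons:
        rows["persons"].append((p.patient_id, p.birth_year, p.sex))
    for s in bundle.enrollment:
        rows["enrollment"].append(
            (s.patient_id, s.start_date.isoformat(), s.end_date.isoformat())
        )
    for c in bundle.medical_claims:
        for k, chunk in enumerate(_chunk(c.diagnosis_codes, _MAX_DX_SLOTS)):
            dx = list(chunk) + [""] * (_MAX_DX_SLOTS - len(chunk))
            proc = (c.procedure_code or "", c.procedure_system or "") if k == 0 else ("", "")
            rows["medical_claims"].append(
                (c.claim_id, c.patient_id, c.service_date.isoformat(), *dx, *proc)
            )
    for c in bundle.drug_claims:
        rows["drug_claims"].append(
            (c.claim_id, c.patient_id, c.fill_date.isoformat(), c.ndc, c.days_supply)
        )
    for r in bundle.emr_oncology:
        rows["emr_oncology"].append(
            (
                r.patient_id,
                r.emr_dx_date.isoformat(),
                r.visit_date.isoformat() if r.visit_date else "",
                r.diagnosis_label,
            )
        )
    for n in bundle.emr_notes:
        rows["emr_notes"].append((n.patient_id, n.note_date.isoformat(), n.note_text))

    for name, cols in _TABLES.items():
        pd.DataFrame(rows[name], columns=cols).to_csv(
            directory / f"{name}.csv", index=False
        )
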