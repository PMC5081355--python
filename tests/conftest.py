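import datetime as dt

import pytest

from mmclaims.claims_model import (
    ClaimsBundle,
    EnrollmentSpan,
    MedicalClaim,
    OncologyEmrRecord,
    Person,
    PrimaryCareNote,
    build_histories,
)
from mmclaims.codesets import default_codesets
from mmclaims.synthetic_data import default_config_from_tables, generate_population


def D(iso: str) -> dt.date:
    return dt.date.fromisoformat(iso)


@pytest.fixture(scope="session")
def codesets():
    return default_codesets()


@pytest.fixture(scope="session")
def small_population(codesets):
    """A modest mixed-strata population shared by read-only tests."""
    config = default_config_from_tables(
        n={
            "control": 60,
            "incident_untreated": 12,
            "prevalent_untreated": 6,
            "incident_treated": 15,
            "prevalent_treated": 8,
        },
        seed=11,
    )
    bundle, truth = generate_population(config, codesets=codesets)
    return bundle, truth, build_histories(bundle)


class BundleBuilder:
    """Hand-construct tiny bundles for scenario tests."""

    def __init__(self):
        self.bundle = ClaimsBundle()
        self._claim_seq = 0

    def _cid(self) -> str:
        self._claim_seq += 1
        return f"X{self._claim_seq:04d}"

    def person(self, pid: str, birth_year: int = 1950, sex: str = "F"):
        self.bundle.persons.append(Person(pid, birth_year, sex))
        return self

    def enroll(self, pid: str, start: str, end: str):
        self.bundle.enrollment.append(EnrollmentSpan(pid, D(start), D(end)))
        return self

    def dx(self, pid: str, date: str, *codes: str):
        self.bundle.medical_claims.append(
            MedicalClaim(self._cid(), pid, D(date), diagnosis_codes=codes)
        )
        return self

    def proc(self, pid: str, date: str, code: str, system: str = "CPT4", dx=()):
        self.bundle.medical_claims.append(
            MedicalClaim(
                self._cid(), pid, D(date),
                diagnosis_codes=tuple(dx),
                procedure_code=code,
                procedure_system=system,
            )
        )
        return self

    def emr(self, pid: str, date: str, label: str = "Multiple Myeloma", visit=True):
        self.bundle.emr_oncology.append(
            OncologyEmrRecord(pid, D(date), D(date) if visit else None, label)
        )
        return self

    def note(self, pid: str, date: str, text: str):
        self.bundle.emr_notes.append(PrimaryCareNote(pid, D(date), text))
        return self

    def build(self) -> ClaimsBundle:
        self.bundle.validate()
        self.bundle.sort()
        return self.bundle

    def histories(self):
        return build_histories(self.build())


@pytest.fixture
def builder():
    return BundleBuilder()
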