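"""Configurable clinical code sets with trailing-wildcard matching.

A code pattern is a code string that may end in a run of ``x`` wildcard
characters (dots optional), e.g. ``203.0x``.  Two wildcard dialects are
supported:

``zero_or_more`` (default)
    The trailing wildcard run matches *zero or more* additional characters,
    so ``203.0x`` matches the 4-digit ``2030`` as well as ``20300``–``20309``.
    Real extracts code ICD-9-CM families at mixed specificity.

``one_char_each``
    Each wildcard character matches exactly one character.

All code sets except ``mm_diagnosis`` ship as clearly labelled PLACEHOLDER
lists in the packaged default configuration; users supply real lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Union

import yaml

from .claims_model import DrugClaim, MedicalClaim, canonicalize_code

__all__ = [
    "ConfigurationError",
    "CodePattern",
    "CodeSet",
    "CodeSetLibrary",
    "pattern_matches",
    "claim_in_codeset",
    "load_codesets",
    "default_codesets",
    "DIAGNOSTIC_TEST_SETS",
    "SYMPTOM_SETS",
    "TREATMENT_SETS",
]

SYSTEMS = ("ICD9DX", "CPT4", "HCPCS", "NDC", "ICD9PROC")
PROC_SYSTEMS = ("CPT4", "HCPCS", "ICD9PROC")

#: The eight diagnostic-test code sets whose union defines "diagnostic tests"
#: in the built-in algorithms.
DIAGNOSTIC_TEST_SETS = (
    "protein_electrophoresis",
    "quantitative_immunoglobulin",
    "serum_free_light_chain",
    "serum_albumin",
    "beta2_microglobulin",
    "bone_marrow",
    "skeletal_survey",
    "ldh",
)

SYMPTOM_SETS = (
    "monoclonal_gammopathy",
    "other_malignancy",
    "anemia_diagnosis",
    "osteoporosis_diagnosis",
    "skeletal_related_event",
    "bone_pain_lesion",
    "fatigue",
    "shortness_of_breath",
    "chest_pain",
    "peripheral_neuropathy",
    "renal_failure",
    "hypercalcemia",
    "pneumonia",
    "herpes_zoster",
    "urinary_tract_infection",
)

TREATMENT_SETS = ("corticosteroid", "bisphosphonate", "anemia_treatment")


class ConfigurationError(Exception):
    """A code pattern or code-set configuration is malformed."""


@dataclass(frozen=True)
class CodePattern:
    """One code pattern in a given coding system."""

    system: str
    pattern: str

    def __post_init__(self) -> None:
        if self.system not in SYSTEMS:
            raise ConfigurationError(
                f"unknown coding system {self.system!r}; expected one of {SYSTEMS}"
            )
        stripped = self.pattern.replace(".", "")
        body = stripped.rstrip("xX")
        if "x" in body.lower():
            raise ConfigurationError(
                f"pattern {self.pattern!r}: wildcards allowed only as a trailing run"
            )
        if not body:
            raise ConfigurationError(
                f"pattern {self.pattern!r}: empty after removing dots and wildcards"
            )

    @property
    def prefix(self) -> str:
        """Fixed canonical prefix: dots removed, wildcards stripped, upper-case."""
        return self.pattern.replace(".", "").rstrip("xX").upper()

    @property
    def n_wildcards(self) -> int:
        stripped = self.pattern.replace(".", "")
        return len(stripped) - len(stripped.rstrip("xX"))

    def example_code(self) -> str:
        """A concrete canonical code matched by this pattern (wildcards -> '0')."""
        return self.prefix + "0" * self.n_wildcards


def pattern_matches(
    pattern: CodePattern, code: str, mode: str = "zero_or_more"
) -> bool:
    """True iff canonical ``code`` is matched by ``pattern``.

    ``code`` must already be canonical (dotless, upper-case).
    """
    prefix = pattern.prefix
    if pattern.n_wildcards == 0:
        return code == prefix
    if not code.startswith(prefix):
        return False
    extra = len(code) - len(prefix)
    if mode == "zero_or_more":
        return True
    if mode == "one_char_each":
        return extra == pattern.n_wildcards
    raise ConfigurationError(f"unknown wildcard mode {mode!r}")


@dataclass(frozen=True)
class CodeSet:
    """A named collection of code patterns (one coding system per set)."""

    name: str
    patterns: tuple[CodePattern, ...]
    wildcard_mode: str = "zero_or_more"

    @property
    def system(self) -> str:
        return self.patterns[0].system if self.patterns else "ICD9DX"

    def match_code(self, code: str) -> bool:
        return any(pattern_matches(p, code, self.wildcard_mode) for p in self.patterns)

    def example_code(self) -> str:
        if not self.patterns:
            raise ConfigurationError(f"code set {self.name!r} is empty")
        return self.patterns[0].example_code()


def claim_in_codeset(
    claim: Union[MedicalClaim, DrugClaim],
    codeset: CodeSet,
    dx_position_restricted: bool = False,
) -> bool:
    """True iff any relevant code field of ``claim`` matches ``codeset``.

    ICD9DX patterns are checked against every diagnosis slot (primary and
    secondary) unless ``dx_position_restricted``; procedure-system patterns
    against ``procedure_code`` when the claim's procedure system agrees;
    NDC patterns against ``ndc``.
    """
    for p in codeset.patterns:
        if isinstance(claim, MedicalClaim):
            if p.system == "ICD9DX":
                slots = claim.diagnosis_codes[:1] if dx_position_restricted else claim.diagnosis_codes
                if any(pattern_matches(p, c, codeset.wildcard_mode) for c in slots):
                    return True
            elif p.system in PROC_SYSTEMS:
                if (
                    claim.procedure_code is not None
                    and claim.procedure_system == p.system
                    and pattern_matches(
                        p, canonicalize_code(claim.procedure_code), codeset.wildcard_mode
                    )
                ):
                    return True
        elif isinstance(claim, DrugClaim):
            if p.system == "NDC" and pattern_matches(p, claim.ndc, codeset.wildcard_mode):
                return True
    return False


@dataclass
class CodeSetLibrary:
    """All configured code sets, by name.  ``mm_diagnosis`` is mandatory."""

    sets: dict[str, CodeSet] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "mm_diagnosis" not in self.sets:
            raise ConfigurationError("configuration must define the mm_diagnosis code set")

    def __getitem__(self, name: str) -> CodeSet:
        try:
            return self.sets[name]
        except KeyError:
            raise ConfigurationError(f"no code set named {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return sorted(self.sets)

    @property
    def mm_diagnosis(self) -> CodeSet:
        return self.sets["mm_diagnosis"]

    def test_sets(self) -> list[CodeSet]:
        """The diagnostic-test sets present in this configuration."""
        return [self.sets[n] for n in DIAGNOSTIC_TEST_SETS if n in self.sets]

    def membership(self, claim: Union[MedicalClaim, DrugClaim]) -> set[str]:
        """Names of every code set this claim belongs to."""
        return {name for name, cs in self.sets.items() if claim_in_codeset(claim, cs)}


def _library_from_mapping(raw: dict, wildcard_mode: str) -> CodeSetLibrary:
    sets = {}
    for name, entry in raw.items():
        if not isinstance(entry, dict) or "system" not in entry or "patterns" not in entry:
            raise ConfigurationError(
                f"code set {name!r}: expected mapping with 'system' and 'patterns'"
            )
        patterns = tuple(
            CodePattern(entry["system"], str(p)) for p in entry["patterns"]
        )
        sets[name] = CodeSet(name=name, patterns=patterns, wildcard_mode=wildcard_mode)
    return CodeSetLibrary(sets=sets)


def load_codesets(path: str | Path, wildcard_mode: str = "zero_or_more") -> CodeSetLibrary:
    """Load a code-set configuration from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: expected a top-level mapping")
    return _library_from_mapping(raw, wildcard_mode)


def default_codesets(wildcard_mode: str = "zero_or_more") -> CodeSetLibrary:
    """The packaged default configuration.

    Only ``mm_diagnosis`` (203.0x) is authoritative; every other list is a
    placeholder to be replaced with a real, clinically curated list.
    """
    text = resources.files("mmclaims").joinpath("data/codesets.yaml").read_text("utf-8")
    raw = yaml.safe_load(text)
    return _library_from_mapping(raw, wildcard_mode)
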