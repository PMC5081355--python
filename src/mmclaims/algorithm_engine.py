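"""Temporal boolean rule engine for claims-based case finding.

A case-finding algorithm is an AND/OR clause tree whose leaves are windowed
predicates evaluated relative to an index diagnosis.  A patient is flagged
at the EARLIEST panel-eligible index diagnosis satisfying the tree; if an
index fails, the next one in date order is evaluated.

Two algorithms ship as named built-ins:

``baseline``
    At least 2 distinct MM-diagnosis service dates: the index plus >= 1
    additional MM diagnosis anywhere in [index-180, index+180].  Duplicate
    same-day billing rows never qualify on their own.

``algorithm2``
    (A and B and C) or D, where

    * A: >= 1 additional MM diagnosis more than 30 days after the index
      (window [index+31, index+180]);
    * B: >= 2 claims from the union of the eight diagnostic-test code sets
      in [index-90, index], OR >= 1 bone-marrow claim in that window;
    * C: >= 2 MM-diagnosis distinct dates strictly BEFORE the earliest test
      date used to satisfy B, within [index-180, index-1];
    * D: >= 1 chemotherapy claim in [index, index+180].

    The grouping of the chemotherapy disjunct is the central ambiguity of
    the rule as stated in prose; chemotherapy was an "OR" added to improve
    sensitivity rather than a requirement, which the standalone-D reading
    maximises.  Three named precedence variants are provided:

    * ``or_standalone``   -> (A and B and C) or D      (default)
    * ``or_with_sequence``-> A and B and (C or D)
    * ``or_inner``        -> A and ((B and C) or D)

``brute_force_flag`` re-derives the flag for the built-ins by direct
exhaustive scanning of raw events, sharing no windowing code with the
engine; it exists as an independent test oracle.
"""

from __future__ import annotations

import datetime as _dt
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import yaml

from .claims_model import PatientHistory
from .codesets import CodeSetLibrary, claim_in_codeset
from .panel import IndexDiagnosis, PanelParams, build_panel

__all__ = [
    "SpecificationError",
    "Predicate",
    "AllOf",
    "AnyOf",
    "AlgorithmSpec",
    "FlagResult",
    "TaggedEvents",
    "tag_events",
    "evaluate_at_index",
    "flag_patient",
    "baseline_spec",
    "algorithm2_spec",
    "algorithm2_clauses",
    "ALGORITHM2_VARIANTS",
    "spec_to_dict",
    "spec_from_dict",
    "save_spec",
    "load_spec",
    "brute_force_flag",
]

_DAY = _dt.timedelta(days=1)

PREDICATE_KINDS = (
    "mm_dx_count",
    "diagnostic_test_count",
    "bone_marrow_count",
    "chemo_present",
)

ALGORITHM2_VARIANTS = ("or_standalone", "or_with_sequence", "or_inner")


class SpecificationError(Exception):
    """An algorithm spec is malformed."""


@dataclass(frozen=True)
class Predicate:
    """A thresholded count of events in a window relative to the index.

    ``window`` is an inclusive pair of day offsets (start <= end).  When
    ``sequence_anchor`` is ``"before_earliest_qualifying_test"``, counted
    MM-diagnosis dates must additionally fall strictly before the anchor:
    the earliest test date within ``anchor_window`` when at least
    ``anchor_test_threshold`` test claims are present, otherwise the
    earliest bone-marrow date; with no anchor the predicate is false.
    """

    kind: str
    window: tuple[int, int]
    threshold: int = 1
    sequence_anchor: Optional[str] = None
    anchor_window: tuple[int, int] = (-90, 0)
    anchor_test_threshold: int = 2
    distinct_test_types: bool = False

    def __post_init__(self) -> None:
        if self.kind not in PREDICATE_KINDS:
            raise SpecificationError(f"unknown predicate kind {self.kind!r}")
        if self.window[0] > self.window[1]:
            raise SpecificationError(f"window {self.window} has start > end")
        if self.threshold < 1:
            raise SpecificationError("threshold must be >= 1")
        if self.sequence_anchor not in (None, "before_earliest_qualifying_test"):
            raise SpecificationError(
                f"unknown sequence_anchor {self.sequence_anchor!r}"
            )


@dataclass(frozen=True)
class AllOf:
    clauses: tuple["ClauseNode", ...]

    def __post_init__(self) -> None:
        if not self.clauses:
            raise SpecificationError("empty conjunction")


@dataclass(frozen=True)
class AnyOf:
    clauses: tuple["ClauseNode", ...]

    def __post_init__(self) -> None:
        if not self.clauses:
            raise SpecificationError("empty disjunction")


ClauseNode = Union[Predicate, AllOf, AnyOf]


@dataclass(frozen=True)
class AlgorithmSpec:
    algorithm_id: str
    tree: ClauseNode


@dataclass(frozen=True)
class FlagResult:
    patient_id: str
    flagged: bool
    flag_date: Optional[_dt.date] = None
    qualifying_index: Optional[IndexDiagnosis] = None

    def __post_init__(self) -> None:
        if self.flagged != (self.flag_date is not None):
            raise ValueError("flagged must agree with flag_date presence")


# ---------------------------------------------------------------------------
# Event tagging: one pass over a patient's claims, then fast window counts.
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TaggedEvents:
    """Sorted day-ordinal views of one patient's code-set events."""

    patient_id: str
    mm_dx_ordinals: tuple[int, ...]       # distinct, sorted
    test_ordinals: tuple[int, ...]        # per-claim, sorted
    test_names: tuple[str, ...]           # aligned with test_ordinals
    bone_marrow_ordinals: tuple[int, ...] # per-claim, sorted
    chemo_ordinals: tuple[int, ...]       # per-claim, sorted


def tag_events(history: PatientHistory, codesets: CodeSetLibrary) -> TaggedEvents:
    mm = codesets.mm_diagnosis
    chemo = codesets["chemotherapy"]
    tests = codesets.test_sets()
    mm_days: set[int] = set()
    test_pairs: list[tuple[int, str]] = []
    bm: list[int] = []
    chemo_days: list[int] = []
    for c in history.medical_claims:
        o = c.service_date.toordinal()
        if claim_in_codeset(c, mm):
            mm_days.add(o)
        for cs in tests:
            if claim_in_codeset(c, cs):
                test_pairs.append((o, cs.name))
                if cs.name == "bone_marrow":
                    bm.append(o)
                break  # a claim counts once toward the test union
        if claim_in_codeset(c, chemo):
            chemo_days.append(o)
    for c in history.drug_claims:
        if claim_in_codeset(c, chemo):
            chemo_days.append(c.fill_date.toordinal())
    test_pairs.sort()
    return TaggedEvents(
        patient_id=history.person.patient_id,
        mm_dx_ordinals=tuple(sorted(mm_days)),
        test_ordinals=tuple(o for o, _ in test_pairs),
        test_names=tuple(n for _, n in test_pairs),
        bone_marrow_ordinals=tuple(sorted(bm)),
        chemo_ordinals=tuple(sorted(chemo_days)),
    )


def _count_in(sorted_ordinals: Sequence[int], lo: int, hi: int) -> int:
    return bisect_right(sorted_ordinals, hi) - bisect_left(sorted_ordinals, lo)


def _anchor_ordinal(pred: Predicate, index_ord: int, events: TaggedEvents) -> Optional[int]:
    """Earliest qualifying-test date for a sequence-anchored predicate."""
    lo = index_ord + pred.anchor_window[0]
    hi = index_ord + pred.anchor_window[1]
    i0 = bisect_left(events.test_ordinals, lo)
    i1 = bisect_right(events.test_ordinals, hi)
    if i1 - i0 >= pred.anchor_test_threshold:
        return events.test_ordinals[i0]
    j0 = bisect_left(events.bone_marrow_ordinals, lo)
    j1 = bisect_right(events.bone_marrow_ordinals, hi)
    if j1 - j0 >= 1:
        return events.bone_marrow_ordinals[j0]
    return None


def _eval_predicate(pred: Predicate, index_ord: int, events: TaggedEvents) -> bool:
    lo = index_ord + pred.window[0]
    hi = index_ord + pred.window[1]
    if pred.kind == "mm_dx_count":
        if pred.sequence_anchor is not None:
            anchor = _anchor_ordinal(pred, index_ord, events)
            if anchor is None:
                return False
            hi = min(hi, anchor - 1)  # strictly before the anchor
            if lo > hi:
                return False
        return _count_in(events.mm_dx_ordinals, lo, hi) >= pred.threshold
    if pred.kind == "diagnostic_test_count":
        if pred.distinct_test_types:
            i0 = bisect_left(events.test_ordinals, lo)
            i1 = bisect_right(events.test_ordinals, hi)
            return len(set(events.test_names[i0:i1])) >= pred.threshold
        return _count_in(events.test_ordinals, lo, hi) >= pred.threshold
    if pred.kind == "bone_marrow_count":
        return _count_in(events.bone_marrow_ordinals, lo, hi) >= pred.threshold
    if pred.kind == "chemo_present":
        return _count_in(events.chemo_ordinals, lo, hi) >= pred.threshold
    raise SpecificationError(f"unknown predicate kind {pred.kind!r}")


def _eval_node(node: ClauseNode, index_ord: int, events: TaggedEvents) -> bool:
    if isinstance(node, Predicate):
        return _eval_predicate(node, index_ord, events)
    if isinstance(node, AllOf):
        return all(_eval_node(c, index_ord, events) for c in node.clauses)
    if isinstance(node, AnyOf):
        return any(_eval_node(c, index_ord, events) for c in node.clauses)
    raise SpecificationError(f"malformed clause tree node {node!r}")


def evaluate_at_index(
    spec: AlgorithmSpec,
    index: IndexDiagnosis,
    events: TaggedEvents,
    codesets: CodeSetLibrary = None,  # accepted for interface symmetry
) -> bool:
    """Recursive truth evaluation of the clause tree at one index."""
    return _eval_node(spec.tree, index.index_date.toordinal(), events)


def flag_patient(
    spec: AlgorithmSpec,
    panel: Sequence[IndexDiagnosis],
    history: PatientHistory,
    codesets: CodeSetLibrary,
    events: Optional[TaggedEvents] = None,
) -> FlagResult:
    """Scan panel indexes in date order; flag at the first that qualifies."""
    pid = history.person.patient_id
    if events is None:
        events = tag_events(history, codesets)
    for index in panel:
        if evaluate_at_index(spec, index, events):
            return FlagResult(
                patient_id=pid,
                flagged=True,
                flag_date=index.index_date,
                qualifying_index=index,
            )
    return FlagResult(patient_id=pid, flagged=False)


# ---------------------------------------------------------------------------
# Built-in specs
# ---------------------------------------------------------------------------


def baseline_spec(window_days: int = 180) -> AlgorithmSpec:
    """>= 2 distinct MM-diagnosis service dates within +/- window_days of
    the index (the index date itself counts as one)."""
    return AlgorithmSpec(
        algorithm_id="baseline",
        tree=Predicate(kind="mm_dx_count", window=(-window_days, window_days), threshold=2),
    )


def algorithm2_clauses(
    window_days: int = 180,
    test_lookback_days: int = 90,
    post_gap_days: int = 30,
    distinct_test_types: bool = False,
) -> dict[str, ClauseNode]:
    """The four clauses of the best-performing built-in, individually."""
    anchor_window = (-test_lookback_days, 0)
    return {
        "A": Predicate(kind="mm_dx_count", window=(post_gap_days + 1, window_days), threshold=1),
        "B": AnyOf(
            (
                Predicate(
                    kind="diagnostic_test_count",
                    window=anchor_window,
                    threshold=2,
                    distinct_test_types=distinct_test_types,
                ),
                Predicate(kind="bone_marrow_count", window=anchor_window, threshold=1),
            )
        ),
        "C": Predicate(
            kind="mm_dx_count",
            window=(-window_days, -1),
            threshold=2,
            sequence_anchor="before_earliest_qualifying_test",
            anchor_window=anchor_window,
        ),
        "D": Predicate(kind="chemo_present", window=(0, window_days), threshold=1),
    }


def algorithm2_spec(variant: str = "or_standalone", **kwargs) -> AlgorithmSpec:
    """The high-specificity built-in, under one of three precedence variants."""
    c = algorithm2_clauses(**kwargs)
    if variant == "or_standalone":
        tree: ClauseNode = AnyOf((AllOf((c["A"], c["B"], c["C"])), c["D"]))
    elif variant == "or_with_sequence":
        tree = AllOf((c["A"], c["B"], AnyOf((c["C"], c["D"]))))
    elif variant == "or_inner":
        tree = AllOf((c["A"], AnyOf((AllOf((c["B"], c["C"])), c["D"]))))
    else:
        raise SpecificationError(
            f"unknown variant {variant!r}; expected one of {ALGORITHM2_VARIANTS}"
        )
    suffix = "" if variant == "or_standalone" else f":{variant}"
    return AlgorithmSpec(algorithm_id=f"algorithm2{suffix}", tree=tree)


# ---------------------------------------------------------------------------
# Serialization (same structured-text dialect as the code-set config)
# ---------------------------------------------------------------------------


def _node_to_dict(node: ClauseNode) -> dict:
    if isinstance(node, Predicate):
        d = {
            "predicate": {
                "kind": node.kind,
                "window": list(node.window),
                "threshold": node.threshold,
            }
        }
        if node.sequence_anchor is not None:
            d["predicate"]["sequence_anchor"] = node.sequence_anchor
            d["predicate"]["anchor_window"] = list(node.anchor_window)
            d["predicate"]["anchor_test_threshold"] = node.anchor_test_threshold
        if node.distinct_test_types:
            d["predicate"]["distinct_test_types"] = True
        return d
    if isinstance(node, AllOf):
        return {"all": [_node_to_dict(c) for c in node.clauses]}
    if isinstance(node, AnyOf):
        return {"any": [_node_to_dict(c) for c in node.clauses]}
    raise SpecificationError(f"cannot serialize node {node!r}")


def _node_from_dict(d: dict) -> ClauseNode:
    if not isinstance(d, dict) or len(d) != 1:
        raise SpecificationError(f"malformed clause node {d!r}")
    key, value = next(iter(d.items()))
    if key == "all":
        return AllOf(tuple(_node_from_dict(c) for c in value))
    if key == "any":
        return AnyOf(tuple(_node_from_dict(c) for c in value))
    if key == "predicate":
        p = dict(value)
        p["window"] = tuple(p["window"])
        if "anchor_window" in p:
            p["anchor_window"] = tuple(p["anchor_window"])
        return Predicate(**p)
    raise SpecificationError(f"unknown clause key {key!r}")


def spec_to_dict(spec: AlgorithmSpec) -> dict:
    return {"algorithm_id": spec.algorithm_id, "clauses": _node_to_dict(spec.tree)}


def spec_from_dict(d: dict) -> AlgorithmSpec:
    try:
        return AlgorithmSpec(
            algorithm_id=d["algorithm_id"], tree=_node_from_dict(d["clauses"])
        )
    except (KeyError, TypeError) as exc:
        raise SpecificationError(f"malformed algorithm spec: {exc}") from exc


def save_spec(spec: AlgorithmSpec, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(spec_to_dict(spec), fh, sort_keys=False)


def load_spec(path) -> AlgorithmSpec:
    with open(path, "r", encoding="utf-8") as fh:
        return spec_from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Independent brute-force oracle (tests only).  Deliberately shares no
# windowing, merging, or panel code with the engine above: enrollment
# coverage is re-derived from a day set built from the RAW spans, and every
# clause is a direct comprehension over raw claims.
# ---------------------------------------------------------------------------


def brute_force_flag(
    spec: AlgorithmSpec,
    history: PatientHistory,
    codesets: CodeSetLibrary,
    raw_spans=None,
) -> FlagResult:
    pid = history.person.patient_id
    spans = raw_spans if raw_spans is not None else history.spans
    covered: set[_dt.date] = set()
    for s in spans:
        d = s.start_date
        while d <= s.end_date:
            covered.add(d)
            d += _DAY

    mm = codesets.mm_diagnosis
    chemo_cs = codesets["chemotherapy"]
    test_sets = codesets.test_sets()

    mm_claims = sorted(
        (c for c in history.medical_claims if claim_in_codeset(c, mm)),
        key=lambda c: (c.service_date, c.claim_id),
    )
    mm_dates = sorted({c.service_date for c in mm_claims})
    test_dates = sorted(
        c.service_date
        for c in history.medical_claims
        if any(claim_in_codeset(c, cs) for cs in test_sets)
    )
    bm_dates = sorted(
        c.service_date
        for c in history.medical_claims
        if claim_in_codeset(c, codesets["bone_marrow"])
    )
    chemo_dates = sorted(
        [c.service_date for c in history.medical_claims if claim_in_codeset(c, chemo_cs)]
        + [c.fill_date for c in history.drug_claims if claim_in_codeset(c, chemo_cs)]
    )

    algo = spec.algorithm_id

    def qualifies(d0: _dt.date) -> bool:
        if algo == "baseline":
            n = len([d for d in mm_dates if abs((d - d0).days) <= 180])
            return n >= 2
        if algo.startswith("algorithm2"):
            a = any(30 < (d - d0).days <= 180 for d in mm_dates)
            tests_win = [t for t in test_dates if -90 <= (t - d0).days <= 0]
            bm_win = [t for t in bm_dates if -90 <= (t - d0).days <= 0]
            b = len(tests_win) >= 2 or len(bm_win) >= 1
            if len(tests_win) >= 2:
                anchor = min(tests_win)
            elif bm_win:
                anchor = min(bm_win)
            else:
                anchor = None
            c = anchor is not None and (
                len([d for d in mm_dates if -180 <= (d - d0).days <= -1 and d < anchor]) >= 2
            )
            dd = any(0 <= (t - d0).days <= 180 for t in chemo_dates)
            if algo.endswith("or_with_sequence"):
                return a and b and (c or dd)
            if algo.endswith("or_inner"):
                return a and ((b and c) or dd)
            return (a and b and c) or dd
        raise SpecificationError(
            f"brute_force_flag implements built-ins only, got {algo!r}"
        )

    for claim in mm_claims:
        d0 = claim.service_date
        eligible = all(
            (d0 + _dt.timedelta(days=k)) in covered for k in range(-90, 31)
        )
        if not eligible:
            continue
        if qualifies(d0):
            return FlagResult(
                patient_id=pid,
                flagged=True,
                flag_date=d0,
                qualifying_index=IndexDiagnosis(pid, d0, claim.claim_id),
            )
    return FlagResult(patient_id=pid, flagged=False)
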