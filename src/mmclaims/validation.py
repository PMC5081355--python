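"""Patient-level diagnostic-accuracy metrics and the derived-PPV formula.

Sensitivity and specificity are computed directly from flags and gold
labels.  PPV cannot be computed directly when cases and controls come from
different source populations, so it is *derived* from sensitivity,
specificity, and the fraction ``f`` of a reference population the
algorithm flags::

    PPV = sens * (f + spec - 1) / (f * (sens + spec - 1))

which is algebraically the Bayes-rule PPV at the prevalence implied by
``f``::

    p = (f + spec - 1) / (sens + spec - 1)

The reference population for ``f`` defaults to patients with at least one
MM-diagnosis claim rather than the whole population (configurable at the
call site by passing the appropriate id set).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .algorithm_engine import FlagResult
from .cohort import GoldLabel

__all__ = [
    "MetricsError",
    "UndefinedMetricError",
    "InconsistentInputsError",
    "PerformanceMetrics",
    "confusion_counts",
    "sensitivity_specificity",
    "flagged_fraction",
    "derived_ppv",
    "implied_prevalence",
    "compute_metrics",
]


class MetricsError(Exception):
    pass


class UndefinedMetricError(MetricsError):
    """A ratio has a zero denominator."""


class InconsistentInputsError(MetricsError):
    """The (sensitivity, specificity, flagged fraction) triple is
    impossible; the message names the violated inequality."""


@dataclass(frozen=True)
class PerformanceMetrics:
    algorithm_id: str
    sample: str
    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity: float
    specificity: float
    flagged_fraction: float | None = None
    derived_ppv: float | None = None
    implied_prevalence: float | None = None


def _flagged(value) -> bool:
    return value.flagged if isinstance(value, FlagResult) else bool(value)


def confusion_counts(
    flags: Mapping[str, FlagResult | bool], labels: Sequence[GoldLabel]
) -> tuple[int, int, int, int]:
    """(tp, fn, tn, fp) at patient level.

    Every labelled patient must have a flag result; the reverse need not
    hold (flags computed on a wider population are fine).
    """
    tp = fn = tn = fp = 0
    for label in labels:
        if label.patient_id not in flags:
            raise MetricsError(f"no flag result for labelled patient {label.patient_id!r}")
        hit = _flagged(flags[label.patient_id])
        if label.label == "case":
            tp += hit
            fn += not hit
        else:
            fp += hit
            tn += not hit
    return tp, fn, tn, fp


def sensitivity_specificity(counts: tuple[int, int, int, int]) -> tuple[float, float]:
    tp, fn, tn, fp = counts
    if tp + fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no cases (tp + fn = 0)")
    if tn + fp == 0:
        raise UndefinedMetricError("specificity undefined: no controls (tn + fp = 0)")
    return tp / (tp + fn), tn / (tn + fp)


def flagged_fraction(
    flags: Mapping[str, FlagResult | bool], reference_population: Iterable[str]
) -> float:
    """Fraction of the reference population flagged.  Patients absent from
    ``flags`` count as unflagged."""
    ref = list(reference_population)
    if not ref:
        raise MetricsError("empty reference population")
    n_flagged = sum(1 for pid in ref if pid in flags and _flagged(flags[pid]))
    return n_flagged / len(ref)


def _check_triple(sensitivity: float, specificity: float, f: float) -> None:
    if sensitivity + specificity <= 1:
        raise InconsistentInputsError(
            f"requires sensitivity + specificity > 1, got "
            f"{sensitivity} + {specificity} = {sensitivity + specificity}"
        )
    if f <= 0:
        raise InconsistentInputsError(f"requires flagged_fraction > 0, got {f}")
    if f < 1 - specificity:
        raise InconsistentInputsError(
            f"requires flagged_fraction >= 1 - specificity "
            f"({f} < {1 - specificity}): implied prevalence would be negative"
        )
    if f > sensitivity:
        raise InconsistentInputsError(
            f"requires flagged_fraction <= sensitivity ({f} > {sensitivity}): "
            f"implied prevalence would exceed 1"
        )


def derived_ppv(sensitivity: float, specificity: float, flagged_fraction: float) -> float:
    """PPV derived from the flagged fraction of a reference population."""
    _check_triple(sensitivity, specificity, flagged_fraction)
    return (
        sensitivity
        * (flagged_fraction + specificity - 1)
        / (flagged_fraction * (sensitivity + specificity - 1))
    )


def implied_prevalence(
    sensitivity: float, specificity: float, flagged_fraction: float
) -> float:
    """The prevalence at which the expected flagged fraction equals ``f``."""
    _check_triple(sensitivity, specificity, flagged_fraction)
    return (flagged_fraction + specificity - 1) / (sensitivity + specificity - 1)


def compute_metrics(
    algorithm_id: str,
    sample: str,
    flags: Mapping[str, FlagResult | bool],
    labels: Sequence[GoldLabel],
    reference_population: Iterable[str] | None = None,
) -> PerformanceMetrics:
    """Confusion counts + ratios, with derived PPV when a reference
    population is supplied and the triple is consistent."""
    counts = confusion_counts(flags, labels)
    sens, spec = sensitivity_specificity(counts)
    f = ppv = prev = None
    if reference_population is not None:
        f = flagged_fraction(flags, reference_population)
        try:
            ppv = derived_ppv(sens, spec, f)
            prev = implied_prevalence(sens, spec, f)
        except InconsistentInputsError:
            ppv = prev = None
    return PerformanceMetrics(
        algorithm_id=algorithm_id,
        sample=sample,
        tp=counts[0],
        fn=counts[1],
        tn=counts[2],
        fp=counts[3],
        sensitivity=sens,
        specificity=spec,
        flagged_fraction=f,
        derived_ppv=ppv,
        implied_prevalence=prev,
    )
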