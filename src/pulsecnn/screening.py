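"""Cohort screening: assign each subject a pulse pattern or exclude them.

Two classification criteria are supported.

* Criterion 1 (disease-based): a subject with exactly one of the five study
  diseases gets that disease's pattern; the hypertension+atherosclerosis
  comorbidity is its own pattern (HCA); subjects with no disease form the
  healthy control group (H1).  Any other comorbidity, or a disease outside
  the study vocabulary, is excluded.

* Criterion 2 (parameter-based): a subject with exactly one physiological
  parameter beyond its reference range (blood pressure > 140/90 mmHg,
  CAVI > 9.0, baPWV > 1400 cm/s, blood viscosity > 5.0) gets that
  parameter's pattern; all-in-range subjects form the healthy control group
  (H2); two or more out-of-range parameters exclude the subject.

After per-subject decisions, patterns with too few kept subjects (<= 20 by
default) are dropped entirely.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

from .synthetic import SubjectProfile

__all__ = [
    "ScreeningThresholds",
    "ScreeningDecision",
    "IncompleteRecordError",
    "DS1_SINGLE_DISEASE_PATTERNS",
    "assign_pattern_ds1",
    "assign_pattern_ds2",
    "screen_cohort",
]


@dataclass(frozen=True)
class ScreeningThresholds:
    """Exclusive lower bounds ("greater than" semantics) plus the class-size floor."""

    bp_systolic: float = 140.0
    bp_diastolic: float = 90.0
    cavi: float = 9.0
    bapwv: float = 1400.0
    viscosity: float = 5.0
    min_class_size: int = 20

    def __post_init__(self) -> None:
        for f in ("bp_systolic", "bp_diastolic", "cavi", "bapwv", "viscosity", "min_class_size"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


@dataclass
class ScreeningDecision:
    subject_id: str
    dataset: int
    outcome: str                 # "kept" | "excluded"
    pattern: str | None = None   # set iff kept
    reason: str | None = None    # set iff excluded

    def __post_init__(self) -> None:
        if self.outcome == "kept" and self.pattern is None:
            raise ValueError("kept decision requires a pattern")
        if self.outcome == "excluded" and self.reason is None:
            raise ValueError("excluded decision requires a reason")


class IncompleteRecordError(ValueError):
    """A subject lacks one of the four physiological parameters."""


DS1_SINGLE_DISEASE_PATTERNS = {
    "hypertension": "Hn",
    "atherosclerosis": "At",
    "hyperlipidaemia": "Ha",
    "type 2 diabetes": "Td",
}
_HCA_SET = frozenset({"hypertension", "atherosclerosis"})


def assign_pattern_ds1(
    subject: SubjectProfile,
    allowed_diseases: Iterable[str] | None = None,
) -> ScreeningDecision:
    """Disease-based pattern assignment (data set 1)."""
    vocab = set(allowed_diseases) if allowed_diseases is not None else set(DS1_SINGLE_DISEASE_PATTERNS)
    diseases = set(subject.diseases)
    if not diseases:
        return ScreeningDecision(subject.subject_id, 1, "kept", pattern="H1")
    if diseases == _HCA_SET:
        return ScreeningDecision(subject.subject_id, 1, "kept", pattern="HCA")
    if len(diseases) == 1:
        (d,) = diseases
        if d in vocab:
            return ScreeningDecision(subject.subject_id, 1, "kept",
                                     pattern=DS1_SINGLE_DISEASE_PATTERNS[d])
        return ScreeningDecision(subject.subject_id, 1, "excluded",
                                 reason="unknown_disease")
    return ScreeningDecision(subject.subject_id, 1, "excluded", reason="comorbid")


def assign_pattern_ds2(
    subject: SubjectProfile,
    thresholds: ScreeningThresholds = ScreeningThresholds(),
) -> ScreeningDecision:
    """Parameter-based pattern assignment (data set 2).

    Blood pressure counts as one parameter, out of range when systolic >
    140 OR diastolic > 90 mmHg (the usual hypertension-definition reading of
    ">90/140 mmHg").
    """
    import math

    for name in ("systolic", "diastolic", "cavi", "bapwv", "viscosity"):
        v = getattr(subject, name, None)
        if v is None or not math.isfinite(v):
            raise IncompleteRecordError(f"subject {subject.subject_id} lacks {name}")

    out: list[str] = []
    if subject.systolic > thresholds.bp_systolic or subject.diastolic > thresholds.bp_diastolic:
        out.append("BP")
    if subject.cavi > thresholds.cavi:
        out.append("CAVI")
    if subject.bapwv > thresholds.bapwv:
        out.append("baPWV")
    if subject.viscosity > thresholds.viscosity:
        out.append("BV")

    if len(out) == 0:
        return ScreeningDecision(subject.subject_id, 2, "kept", pattern="H2")
    if len(out) == 1:
        return ScreeningDecision(subject.subject_id, 2, "kept", pattern=out[0])
    return ScreeningDecision(subject.subject_id, 2, "excluded",
                             reason="multiple_parameters_out_of_range")


def screen_cohort(
    cohort: Sequence[SubjectProfile],
    criteria: int,
    thresholds: ScreeningThresholds = ScreeningThresholds(),
    quality_gate: Callable[[SubjectProfile], bool] | None = None,
) -> tuple[list[ScreeningDecision], Counter]:
    """Screen a cohort under criterion 1 or 2 and enforce the class-size floor.

    Patterns whose kept count is <= ``thresholds.min_class_size`` are dropped:
    their subjects are re-marked excluded with reason ``class_too_small``.
    ``quality_gate`` (criterion "no serious abnormality in pulse waves") may
    reject a subject's record before pattern assignment.  Returns all
    decisions plus kept counts per pattern.
    """
    if criteria not in (1, 2):
        raise ValueError("criteria must be 1 (diseases) or 2 (parameters)")

    decisions: list[ScreeningDecision] = []
    for subject in cohort:
        if quality_gate is not None and not quality_gate(subject):
            decisions.append(ScreeningDecision(
                subject.subject_id, criteria, "excluded", reason="failed_quality_gate"
            ))
            continue
        if criteria == 1:
            decisions.append(assign_pattern_ds1(subject))
        else:
            decisions.append(assign_pattern_ds2(subject, thresholds))

    counts = Counter(d.pattern for d in decisions if d.outcome == "kept")
    small = {p for p, n in counts.items() if n <= thresholds.min_class_size}
    if small:
        for d in decisions:
            if d.outcome == "kept" and d.pattern in small:
                d.outcome, d.pattern, d.reason = "excluded", None, "class_too_small"
        counts = Counter(d.pattern for d in decisions if d.outcome == "kept")
    return decisions, counts
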