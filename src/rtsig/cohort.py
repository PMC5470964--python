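"""Clinical-cohort composition and outcome summaries.

The outcome summary restricts a cohort table to one diagnosis group and
to adult-onset cases (age strictly above a cutoff, 15 years by default),
then counts cases with a recorded outcome, deaths of disease (DOD), and
the median follow-up over cases with a numeric follow-up.  Cases with an
outcome but no usable follow-up still count toward the outcome totals.

Grouping convention: the "RT" outcome group is the cases whose corrected
diagnosis is RT; the "SD-NRT" group aggregates cases whose corrected
diagnosis is the generic SD-NRT call, epithelioid sarcoma or renal
medullary carcinoma, while a case re-assigned to undifferentiated
chordoma is tallied with that specific entity rather than the aggregate.
Both label sets are overridable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import ValidationError
from .io import SampleAnnotation

#: Corrected-diagnosis labels counted in each outcome group.
OUTCOME_GROUPS: dict[str, frozenset[str]] = {
    "RT": frozenset({"RT"}),
    "SD-NRT": frozenset({"SD-NRT", "ES", "RMC"}),
}


@dataclass(frozen=True)
class OutcomeSummary:
    group: str
    min_age_years: float
    n_with_outcome: int
    n_dod: int
    median_followup: float | None   # None (flagged) when no numeric follow-up
    n_followup: int

    def __post_init__(self) -> None:
        if self.n_dod > self.n_with_outcome:
            raise ValidationError("DOD count exceeds outcome count")


def outcome_summary(annotations: Iterable[SampleAnnotation], group: str,
                    min_age_years: float = 15.0,
                    group_labels: Sequence[str] | None = None,
                    ) -> OutcomeSummary:
    """Outcome counts and median follow-up for one adult-onset group.

    Filters to the diagnosis labels of ``group`` (see OUTCOME_GROUPS,
    overridable via ``group_labels``), to age strictly greater than
    ``min_age_years``, and to cases with a recorded outcome.  The median
    follow-up is taken over the filtered cases with a numeric follow-up;
    it is None (flagged) when the filtered set is empty of them.
    """
    if group_labels is None:
        if group not in OUTCOME_GROUPS:
            raise ValidationError(f"unknown group {group!r}")
        labels = OUTCOME_GROUPS[group]
    else:
        labels = frozenset(group_labels)
    selected = [a for a in annotations
                if a.diagnosis_label in labels
                and a.age_years is not None and a.age_years > min_age_years
                and a.outcome is not None]
    followups = [a.followup_days for a in selected
                 if a.followup_days is not None]
    return OutcomeSummary(
        group=group,
        min_age_years=min_age_years,
        n_with_outcome=len(selected),
        n_dod=sum(1 for a in selected if a.outcome == "DOD"),
        median_followup=float(np.median(followups)) if followups else None,
        n_followup=len(followups),
    )


def composition_summary(annotations: Iterable[SampleAnnotation],
                        cohort: str | None = None) -> dict[str, int]:
    """Counts of samples per diagnosis label (optionally one cohort only).

    The returned dict also carries the total under the key "total".
    """
    selected = [a for a in annotations
                if cohort is None or a.cohort == cohort]
    counts = Counter(a.diagnosis_label for a in selected)
    out = dict(sorted(counts.items()))
    out["total"] = len(selected)
    return out
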