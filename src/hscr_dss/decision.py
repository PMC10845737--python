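"""Case classification, referral resolution and cohort summarization.

The DSS combines the per-set algorithm score with the per-set pathologist
score through a fixed decision rule:

1. ``positive`` (ganglion cells present, non-HSCR) -- the pathologist gave
   the certain score (5) to at least two image sets; the algorithm score is
   ignored on this branch.
2. ``negative`` (HSCR) -- the positive criterion is not met AND the mean
   algorithm score over all of the case's image sets is strictly below the
   cutoff (default 0.6).
3. ``in_doubt`` -- the positive criterion is not met AND the mean algorithm
   score is >= the cutoff; the case is referred to an expert who reviews
   the presented image sets and issues the final call.

The mean is unweighted over all presented sets (at most 12 per case).
Boundary conventions: "< 0.6" is strict for negative and the in-doubt
branch includes 0.6 exactly; pathologist scores of 4 never count toward
the positive criterion.
"""

from __future__ import annotations

import enum
import statistics
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .records import CaseRecord, GroundTruth, ValidationError


class CaseLabel(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    IN_DOUBT = "in_doubt"


class ExpertCallRequired(ValidationError):
    """An in-doubt case cannot be resolved without an expert call."""


@dataclass(frozen=True)
class DSSClassification:
    """Outcome of the decision rule for one case.

    ``mean_dsa`` is the unweighted mean algorithm score over all image
    sets; ``n_certain_sets`` counts sets with the certain pathologist
    score (5 by default).
    """

    label: CaseLabel
    mean_dsa: float
    n_certain_sets: int


@dataclass(frozen=True)
class CohortSummary:
    """Aggregate DSS performance for a collection of cases.

    Sensitivity is reported among ganglion-present cases only, both
    pre-referral (in-doubt cases counted as not yet correct) and
    post-referral (after expert resolution). Values are percentages in
    [0, 100], or ``None`` when the cohort has no ganglion-present cases.
    """

    n_cases: int
    n_hscr: int
    n_non_hscr: int
    n_correct: int
    n_incorrect: int
    n_referrals: int
    sensitivity_positive_cases_pre_referral: Optional[float]
    sensitivity_positive_cases_post_referral: Optional[float]


def classify_case(
    case: CaseRecord,
    ai_cutoff: float = 0.6,
    certain_score: int = 5,
    n_certain_required: int = 2,
) -> DSSClassification:
    """Apply the DSS decision rule to one case.

    Returns ``positive`` if at least ``n_certain_required`` image sets carry
    the certain pathologist score, else ``negative`` if the mean algorithm
    score is strictly below ``ai_cutoff``, else ``in_doubt``.
    """
    if not case.image_sets:
        raise ValidationError(f"case {case.case_id!r} has no image sets; unclassifiable")
    n_certain = sum(
        1 for s in case.image_sets if s.pathologist_score == certain_score
    )
    mean_dsa = statistics.fmean(s.dsa_score for s in case.image_sets)
    if n_certain >= n_certain_required:
        label = CaseLabel.POSITIVE
    elif mean_dsa < ai_cutoff:
        label = CaseLabel.NEGATIVE
    else:
        label = CaseLabel.IN_DOUBT
    return DSSClassification(label=label, mean_dsa=mean_dsa, n_certain_sets=n_certain)


def resolve_referral(
    classification: DSSClassification, case: CaseRecord
) -> GroundTruth:
    """Map a DSS classification to a final ganglion-status call.

    Positive and negative classifications stand as issued (the expert call
    is ignored even if present); an in-doubt classification is replaced by
    the expert's call, which must be available.
    """
    if classification.label is CaseLabel.POSITIVE:
        return GroundTruth.GANGLION_PRESENT
    if classification.label is CaseLabel.NEGATIVE:
        return GroundTruth.GANGLION_ABSENT
    if case.expert_call is None:
        raise ExpertCallRequired(
            f"case {case.case_id!r} is in doubt and has no expert call"
        )
    return case.expert_call


def summarize_cohort(
    cases: Iterable[CaseRecord],
    ai_cutoff: float = 0.6,
    certain_score: int = 5,
    n_certain_required: int = 2,
) -> CohortSummary:
    """Classify every case and tabulate cohort-level performance.

    Correctness compares the post-referral call with the recorded ground
    truth; referrals count cases classified in_doubt before resolution.
    """
    cases = list(cases)
    if not cases:
        raise ValidationError("cannot summarize an empty cohort")

    n_hscr = n_correct = n_referrals = 0
    n_positive_truth = 0
    n_pos_correct_pre = 0
    n_pos_correct_post = 0
    for case in cases:
        cls = classify_case(
            case,
            ai_cutoff=ai_cutoff,
            certain_score=certain_score,
            n_certain_required=n_certain_required,
        )
        referred = cls.label is CaseLabel.IN_DOUBT
        final = resolve_referral(cls, case)
        correct = final == case.ground_truth
        if case.ground_truth is GroundTruth.GANGLION_ABSENT:
            n_hscr += 1
        else:
            n_positive_truth += 1
            if correct:
                n_pos_correct_post += 1
                if not referred:
                    n_pos_correct_pre += 1
        n_correct += correct
        n_referrals += referred

    def _pct(k: int) -> Optional[float]:
        if n_positive_truth == 0:
            return None
        return 100.0 * k / n_positive_truth

    return CohortSummary(
        n_cases=len(cases),
        n_hscr=n_hscr,
        n_non_hscr=len(cases) - n_hscr,
        n_correct=n_correct,
        n_incorrect=len(cases) - n_correct,
        n_referrals=n_referrals,
        sensitivity_positive_cases_pre_referral=_pct(n_pos_correct_pre),
        sensitivity_positive_cases_post_referral=_pct(n_pos_correct_post),
    )
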