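"""Core record types shared across the pipeline.

The unit of presentation in the decision support system (DSS) is the *image
set*: a group of candidate images extracted from a case's digital slides by
the upstream detection algorithm (the DSA), scored by that algorithm on
[0, 1] and independently by a pathologist on an ordinal 1-5 scale
(1 = certainly no ganglion cells, 5 = certainly ganglion cells present).
A *case* is a clinical specimen with up to 12 image sets, a cohort (source
laboratory) label, a scanner label and a pathological ground truth.

Sign convention, stated explicitly to avoid inversion bugs: a "positive"
classification means ganglion cells are PRESENT, i.e. the case is
non-Hirschsprung; Hirschsprung's disease (HSCR) is the ABSENCE of ganglion
cells, encoded here as ``GroundTruth.GANGLION_ABSENT``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import FrozenSet, Optional, Sequence, Tuple

MAX_SETS_PER_CASE = 12
PATHOLOGIST_SCORES = (1, 2, 3, 4, 5)


class ValidationError(ValueError):
    """Raised when a record violates its invariants."""


class GroundTruth(str, enum.Enum):
    """Case-level truth. ``GANGLION_ABSENT`` is equivalent to HSCR."""

    GANGLION_PRESENT = "ganglion_present"
    GANGLION_ABSENT = "ganglion_absent"


class Cause(str, enum.Enum):
    """Causative factors annotated on discordant image sets.

    ``TECHNICAL``: slide preparation / digitization problems (staining
    intensity, artifacts, focus). ``MISSING_SENS_SPEC``: the algorithm
    under-scored a true ganglion cell (sensitivity) or over-scored a
    mimic (specificity). ``NEW_ABNORMAL``: tissue or pathology the
    algorithm was never exposed to. ``UNKNOWN``: no factor identified.
    """

    TECHNICAL = "technical"
    MISSING_SENS_SPEC = "missing_sens_spec"
    NEW_ABNORMAL = "new_abnormal"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class ImageSetRecord:
    """One image set presented to the pathologist.

    Parameters
    ----------
    case_id
        Opaque case identifier.
    set_index
        1-based position of the set within its case; unique per case.
    dsa_score
        The set's algorithm confidence in [0, 1] (best candidate score).
    pathologist_score
        Ordinal score in {1..5}; missing scores are rejected, not imputed.
    cause_annotations
        Expert-assigned causative factors; meaningful only for discordant
        sets and carried as data (never inferred from images).
    """

    case_id: str
    set_index: int
    dsa_score: float
    pathologist_score: int
    cause_annotations: FrozenSet[Cause] = frozenset()

    def __post_init__(self) -> None:
        if not isinstance(self.set_index, int) or self.set_index < 1:
            raise ValidationError(
                f"set_index must be an integer >= 1, got {self.set_index!r}"
            )
        if not isinstance(self.dsa_score, (int, float)) or isinstance(
            self.dsa_score, bool
        ):
            raise ValidationError(f"dsa_score must be numeric, got {self.dsa_score!r}")
        if math.isnan(self.dsa_score) or not 0.0 <= self.dsa_score <= 1.0:
            raise ValidationError(
                f"dsa_score must lie in [0, 1], got {self.dsa_score!r}"
            )
        if (
            isinstance(self.pathologist_score, bool)
            or self.pathologist_score not in PATHOLOGIST_SCORES
        ):
            raise ValidationError(
                "pathologist_score must be an integer in {1..5}, got "
                f"{self.pathologist_score!r}"
            )
        object.__setattr__(
            self, "cause_annotations", frozenset(Cause(c) for c in self.cause_annotations)
        )


@dataclass(frozen=True)
class CaseRecord:
    """A clinical case: cohort/scanner provenance, truth and its image sets.

    ``expert_call`` is the outcome of expert consultation and is consulted
    only when the DSS classification is ``in_doubt``.
    """

    case_id: str
    cohort: str
    scanner: str
    ground_truth: GroundTruth
    image_sets: Tuple[ImageSetRecord, ...]
    expert_call: Optional[GroundTruth] = None

    def __post_init__(self) -> None:
        sets = tuple(self.image_sets)
        object.__setattr__(self, "image_sets", sets)
        object.__setattr__(self, "ground_truth", GroundTruth(self.ground_truth))
        if self.expert_call is not None:
            object.__setattr__(self, "expert_call", GroundTruth(self.expert_call))
        if not 1 <= len(sets) <= MAX_SETS_PER_CASE:
            raise ValidationError(
                f"case {self.case_id!r} must have 1-{MAX_SETS_PER_CASE} image "
                f"sets, got {len(sets)}"
            )
        for s in sets:
            if s.case_id != self.case_id:
                raise ValidationError(
                    f"image set {s.set_index} carries case_id {s.case_id!r}, "
                    f"expected {self.case_id!r}"
                )
        indices = [s.set_index for s in sets]
        if len(set(indices)) != len(indices):
            raise ValidationError(
                f"case {self.case_id!r} has duplicated set_index values: {indices}"
            )

    @property
    def dsa_scores(self) -> Tuple[float, ...]:
        return tuple(s.dsa_score for s in self.image_sets)
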