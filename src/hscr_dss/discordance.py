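"""Image-set-level discordance detection, tabulation and comparison.

A set is a *false negative* when the pathologist is certain ganglion cells
are present (score 5) while the algorithm scored it below 0.3 -- the
detector under-scored a true ganglion cell. A *false positive* is the
mirror image: pathologist certain there are none (score 1) while the
algorithm scored above 0.7. Cutoffs are strict: 0.3 and 0.7 exactly are
concordant. Everything else is concordant by definition, so no set can be
both (the two conditions require different pathologist scores).

Per-stratum tables mirror the error-rate tables of a multi-center
robustness study: counts and rates of each error type plus a cause
breakdown, with cause percentages taken relative to the error-type total
(not to all sets). Strata are compared with a Pearson chi-square test of
independence.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
from scipy import stats

from .records import CaseRecord, Cause, ImageSetRecord, ValidationError

logger = logging.getLogger(__name__)

FN_CUTOFF = 0.3
FP_CUTOFF = 0.7


class DiscordanceLabel(str, enum.Enum):
    FALSE_POSITIVE = "false_positive"
    FALSE_NEGATIVE = "false_negative"
    CONCORDANT = "concordant"


class DegenerateTableError(ValidationError):
    """A contingency table with a zero marginal cannot be tested."""


def label_discordance(
    image_set: ImageSetRecord,
    fn_cutoff: float = FN_CUTOFF,
    fp_cutoff: float = FP_CUTOFF,
) -> DiscordanceLabel:
    """Classify one image set as false positive, false negative or concordant."""
    if image_set.pathologist_score == 5 and image_set.dsa_score < fn_cutoff:
        return DiscordanceLabel.FALSE_NEGATIVE
    if image_set.pathologist_score == 1 and image_set.dsa_score > fp_cutoff:
        return DiscordanceLabel.FALSE_POSITIVE
    return DiscordanceLabel.CONCORDANT


@dataclass(frozen=True)
class DiscordanceTable:
    """Error counts, rates (percent) and cause breakdown for one stratum.

    ``fp_causes`` / ``fn_causes`` count cause annotations over discordant
    sets only; a discordant set with no annotation is tallied as
    ``unknown``, and a set may contribute to several causes at once.
    Rates keep full precision; display rounding happens in the reporters.
    """

    stratum: str
    n_sets: int
    n_fp: int
    n_fn: int
    fp_rate: float
    fn_rate: float
    total_error_rate: float
    fp_causes: Mapping[Cause, int] = field(default_factory=dict)
    fn_causes: Mapping[Cause, int] = field(default_factory=dict)


def _tally_causes(sets: Sequence[ImageSetRecord]) -> Dict[Cause, int]:
    counts = {c: 0 for c in Cause}
    for s in sets:
        causes = s.cause_annotations or frozenset({Cause.UNKNOWN})
        for c in causes:
            counts[c] += 1
    return counts


def tabulate_discordance(
    sets_by_stratum: Mapping[str, Sequence[ImageSetRecord]],
    fn_cutoff: float = FN_CUTOFF,
    fp_cutoff: float = FP_CUTOFF,
) -> List[DiscordanceTable]:
    """Build one :class:`DiscordanceTable` per stratum.

    Strata with no image sets are excluded with a logged warning. Rates
    satisfy ``fp_rate + fn_rate == total_error_rate`` exactly (before any
    display rounding).
    """
    tables: List[DiscordanceTable] = []
    for stratum, sets in sets_by_stratum.items():
        sets = list(sets)
        if not sets:
            logger.warning("stratum %r has no image sets; excluded", stratum)
            continue
        fps = [
            s for s in sets
            if label_discordance(s, fn_cutoff, fp_cutoff) is DiscordanceLabel.FALSE_POSITIVE
        ]
        fns = [
            s for s in sets
            if label_discordance(s, fn_cutoff, fp_cutoff) is DiscordanceLabel.FALSE_NEGATIVE
        ]
        n = len(sets)
        fp_rate = 100.0 * len(fps) / n
        fn_rate = 100.0 * len(fns) / n
        tables.append(
            DiscordanceTable(
                stratum=str(stratum),
                n_sets=n,
                n_fp=len(fps),
                n_fn=len(fns),
                fp_rate=fp_rate,
                fn_rate=fn_rate,
                total_error_rate=fp_rate + fn_rate,
                fp_causes=_tally_causes(fps),
                fn_causes=_tally_causes(fns),
            )
        )
    return tables


def group_image_sets(
    cases: Iterable[CaseRecord], by: str = "cohort"
) -> Dict[str, List[ImageSetRecord]]:
    """Pool image sets across cases, keyed by cohort or scanner label."""
    if by not in ("cohort", "scanner"):
        raise ValidationError(f"stratify-by must be 'cohort' or 'scanner', got {by!r}")
    grouped: Dict[str, List[ImageSetRecord]] = {}
    for case in cases:
        grouped.setdefault(getattr(case, by), []).extend(case.image_sets)
    return grouped


@dataclass(frozen=True)
class ContingencyTable:
    """An r x c table of non-negative integer counts with axis labels."""

    counts: np.ndarray
    row_labels: Tuple[str, ...]
    col_labels: Tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
            raise ValidationError(
                f"contingency table must be at least 2x2, got shape {counts.shape}"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValidationError("contingency table cells must be integers")
            counts = np.round(counts).astype(np.int64)
        if (counts < 0).any():
            raise ValidationError("contingency table cells must be non-negative")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "row_labels", tuple(self.row_labels))
        object.__setattr__(self, "col_labels", tuple(self.col_labels))
        if len(self.row_labels) != counts.shape[0] or len(self.col_labels) != counts.shape[1]:
            raise ValidationError("axis labels do not match table shape")


def error_contingency(tables: Sequence[DiscordanceTable]) -> ContingencyTable:
    """Strata x {false_negative, false_positive} counts for chi-square tests."""
    if len(tables) < 2:
        raise ValidationError("need at least two strata for a contingency table")
    counts = np.array([[t.n_fn, t.n_fp] for t in tables], dtype=np.int64)
    return ContingencyTable(
        counts=counts,
        row_labels=tuple(t.stratum for t in tables),
        col_labels=("false_negative", "false_positive"),
    )


def chi_square_independence(
    table: ContingencyTable, yates: bool = False
) -> Tuple[float, int, float]:
    """Pearson chi-square test of independence.

    Expected counts are ``E = row_total * col_total / N``; the statistic is
    ``sum((O - E)^2 / E)`` with ``df = (r - 1)(c - 1)`` and an upper-tail
    p-value from the chi-square distribution (regularized upper incomplete
    gamma function). ``yates`` applies the continuity correction
    ``(|O - E| - 0.5)`` clipped at zero, intended for 2x2 tables.

    Returns ``(statistic, df, p)``. Raises :class:`DegenerateTableError`
    when a row or column marginal is zero.
    """
    counts = table.counts.astype(np.float64)
    row = counts.sum(axis=1, keepdims=True)
    col = counts.sum(axis=0, keepdims=True)
    total = counts.sum()
    if (row == 0).any() or (col == 0).any() or total == 0:
        raise DegenerateTableError("contingency table has a zero marginal")
    expected = row @ col / total
    dev = np.abs(counts - expected)
    if yates:
        dev = np.clip(dev - 0.5, 0.0, None)
    statistic = float((dev**2 / expected).sum())
    df = (counts.shape[0] - 1) * (counts.shape[1] - 1)
    p = float(stats.chi2.sf(statistic, df))
    return statistic, df, max(p, np.finfo(float).tiny)


def bonferroni(p_values: Sequence[float]) -> List[float]:
    """Bonferroni-adjust a family of p-values (clipped at 1).

    Pairwise stratum comparisons are reported uncorrected by default;
    this is the optional family-wise correction.
    """
    m = len(p_values)
    return [min(1.0, p * m) for p in p_values]
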