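"""Report assembly: JSON-ready dictionaries and fixed-width text tables.

JSON payloads keep rates at full float precision; the text renderers apply
the display convention used throughout: percentages below 1% are shown
with two decimals, all others with one.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Union

from .decision import CohortSummary, summarize_cohort
from .discordance import (
    DiscordanceTable,
    group_image_sets,
    tabulate_discordance,
)
from .records import CaseRecord, Cause, ValidationError


def format_rate(pct: float) -> str:
    """Display rounding: two decimals below 1%, one decimal otherwise."""
    return f"{pct:.2f}" if pct < 1.0 else f"{pct:.1f}"


def _summary_dict(s: CohortSummary) -> Dict[str, object]:
    return dataclasses.asdict(s)


def cohort_report(
    cases: Sequence[CaseRecord],
    stratify_by: str = "cohort",
    **classify_kwargs,
) -> Dict[str, object]:
    """Per-stratum and total cohort summaries as a JSON-ready mapping."""
    if stratify_by not in ("cohort", "scanner"):
        raise ValidationError(f"stratify_by must be 'cohort' or 'scanner', got {stratify_by!r}")
    strata: Dict[str, List[CaseRecord]] = {}
    for case in cases:
        strata.setdefault(getattr(case, stratify_by), []).append(case)
    report = {
        "stratify_by": stratify_by,
        "strata": {
            label: _summary_dict(summarize_cohort(group, **classify_kwargs))
            for label, group in sorted(strata.items())
        },
        "total": _summary_dict(summarize_cohort(list(cases), **classify_kwargs)),
    }
    return report


def render_cohort_table(report: Mapping[str, object]) -> str:
    """Fixed-width text table of case counts, truth and DSS performance."""
    header = (
        f"{'Stratum':<14}{'Cases':>7}{'HSCR':>7}{'non-HSCR':>10}"
        f"{'Correct':>9}{'Incorrect':>11}{'Referrals':>11}"
    )
    lines = [header, "-" * len(header)]

    def _row(label: str, s: Mapping[str, object]) -> str:
        return (
            f"{label:<14}{s['n_cases']:>7}{s['n_hscr']:>7}{s['n_non_hscr']:>10}"
            f"{s['n_correct']:>9}{s['n_incorrect']:>11}{s['n_referrals']:>11}"
        )

    for label, s in report["strata"].items():
        lines.append(_row(label, s))
    lines.append("-" * len(header))
    lines.append(_row("Total", report["total"]))
    return "\n".join(lines)


def _table_dict(t: DiscordanceTable) -> Dict[str, object]:
    return {
        "stratum": t.stratum,
        "n_sets": t.n_sets,
        "n_fp": t.n_fp,
        "n_fn": t.n_fn,
        "fp_rate": t.fp_rate,
        "fn_rate": t.fn_rate,
        "total_error_rate": t.total_error_rate,
        "fp_causes": {c.value: n for c, n in t.fp_causes.items()},
        "fn_causes": {c.value: n for c, n in t.fn_causes.items()},
    }


def discordance_report(
    cases: Sequence[CaseRecord],
    stratify_by: str = "cohort",
    fn_cutoff: float = 0.3,
    fp_cutoff: float = 0.7,
) -> Dict[str, object]:
    """Per-stratum discordance tables as a JSON-ready mapping."""
    grouped = group_image_sets(cases, by=stratify_by)
    grouped = dict(sorted(grouped.items()))
    tables = tabulate_discordance(grouped, fn_cutoff=fn_cutoff, fp_cutoff=fp_cutoff)
    return {
        "stratify_by": stratify_by,
        "fn_cutoff": fn_cutoff,
        "fp_cutoff": fp_cutoff,
        "strata": [_table_dict(t) for t in tables],
    }


def render_discordance_table(report: Mapping[str, object]) -> str:
    """Text rendering of error rates and cause breakdowns per stratum."""
    lines: List[str] = []
    cause_order = [c.value for c in Cause]
    for t in report["strata"]:
        total = t["fp_rate"] + t["fn_rate"]
        lines.append(
            f"{t['stratum']}: {t['n_sets']} image sets, "
            f"{t['n_fp'] + t['n_fn']} errors ({format_rate(total)}%)"
        )
        for kind, n, rate, causes in (
            ("False positive", t["n_fp"], t["fp_rate"], t["fp_causes"]),
            ("False negative", t["n_fn"], t["fn_rate"], t["fn_causes"]),
        ):
            parts = []
            for c in cause_order:
                k = causes.get(c, 0)
                pct = 100.0 * k / n if n else 0.0
                parts.append(f"{c}={k} ({format_rate(pct)}%)")
            lines.append(f"  {kind}: {n} ({format_rate(rate)}%)  " + "  ".join(parts))
    return "\n".join(lines)


def write_json(payload: Mapping[str, object], path: Union[str, Path]) -> None:
    """Deterministic JSON serialization (sorted keys, no timestamps)."""
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_json(path: Union[str, Path]) -> Dict[str, object]:
    return json.loads(Path(path).read_text())
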