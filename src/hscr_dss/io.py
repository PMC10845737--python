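"""Reading and writing score tables, case tables and image manifests.

Score table (CSV/TSV by extension): one row per image set with columns
``case_id, cohort, scanner, set_index, dsa_score, pathologist_score,
causes`` (semicolon-separated cause annotations, optional/empty allowed).
Case table (CSV): ``case_id, ground_truth, expert_call`` (optional).
Image manifest (CSV): ``path, case_id, cohort, scanner``.

Dialect: comma-separated (tab for ``.tsv``), UTF-8, header required,
'.' decimal separator.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, List, Sequence, Union

import numpy as np
import pandas as pd

from .records import CaseRecord, Cause, GroundTruth, ImageSetRecord, ValidationError

PathLike = Union[str, Path]

SCORE_COLUMNS = ("case_id", "cohort", "scanner", "set_index", "dsa_score", "pathologist_score")
CASE_COLUMNS = ("case_id", "ground_truth")
MANIFEST_COLUMNS = ("path", "case_id", "cohort", "scanner")


def _read_table(path: PathLike, required: Sequence[str], what: str) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    try:
        # round_trip parsing keeps scores bit-exact across write/read
        df = pd.read_csv(path, sep=sep, dtype={"case_id": str}, float_precision="round_trip")
    except Exception as exc:  # malformed CSV surfaces as a validation error
        raise ValidationError(f"cannot parse {what} {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{what} {path} is missing columns: {missing}")
    return df


def read_score_table(path: PathLike) -> pd.DataFrame:
    """Load a per-image-set score table, parsing cause annotations."""
    df = _read_table(path, SCORE_COLUMNS, "score table")
    if "causes" not in df.columns:
        df["causes"] = ""
    df["causes"] = df["causes"].fillna("")
    return df


def read_case_table(path: PathLike) -> pd.DataFrame:
    """Load the per-case ground-truth table."""
    df = _read_table(path, CASE_COLUMNS, "case table")
    if "expert_call" not in df.columns:
        df["expert_call"] = None
    return df


def read_manifest(path: PathLike) -> pd.DataFrame:
    """Load an image manifest mapping tile paths to case/cohort/scanner."""
    df = _read_table(path, MANIFEST_COLUMNS, "image manifest")
    if df.empty:
        raise ValidationError(f"image manifest {path} lists no images")
    return df


def _parse_causes(raw: object) -> frozenset:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return frozenset()
    parts = [p.strip() for p in str(raw).split(";") if p.strip()]
    try:
        return frozenset(Cause(p) for p in parts)
    except ValueError as exc:
        raise ValidationError(f"unknown cause annotation in {raw!r}") from exc


def cases_from_tables(
    scores: pd.DataFrame, case_table: pd.DataFrame
) -> List[CaseRecord]:
    """Join score rows onto case rows, validating referential integrity.

    Every score row must reference a case in the case table; duplicated
    ``set_index`` within a case, out-of-range scores and missing
    pathologist scores are itemized validation errors.
    """
    problems: List[str] = []
    case_ids = set(case_table["case_id"].astype(str))
    unknown = sorted(set(scores["case_id"].astype(str)) - case_ids)
    if unknown:
        problems.append(f"score rows reference unknown case ids: {unknown}")

    truth_by_case = {}
    expert_by_case = {}
    for row in case_table.itertuples(index=False):
        cid = str(row.case_id)
        try:
            truth_by_case[cid] = GroundTruth(row.ground_truth)
        except ValueError:
            problems.append(f"case {cid!r}: invalid ground_truth {row.ground_truth!r}")
            continue
        call = getattr(row, "expert_call", None)
        if call is None or (isinstance(call, float) and math.isnan(call)) or call == "":
            expert_by_case[cid] = None
        else:
            try:
                expert_by_case[cid] = GroundTruth(call)
            except ValueError:
                problems.append(f"case {cid!r}: invalid expert_call {call!r}")

    cases: List[CaseRecord] = []
    for cid, group in scores.groupby("case_id", sort=True):
        cid = str(cid)
        if cid not in truth_by_case:
            continue
        sets = []
        for row in group.itertuples(index=False):
            if pd.isna(row.pathologist_score):
                problems.append(f"case {cid!r} set {row.set_index}: missing pathologist score")
                continue
            try:
                sets.append(
                    ImageSetRecord(
                        case_id=cid,
                        set_index=int(row.set_index),
                        dsa_score=float(row.dsa_score),
                        pathologist_score=int(row.pathologist_score),
                        cause_annotations=_parse_causes(row.causes),
                    )
                )
            except (ValidationError, ValueError) as exc:
                problems.append(f"case {cid!r} set {row.set_index}: {exc}")
        if not sets:
            problems.append(f"case {cid!r} has no valid image sets")
            continue
        try:
            cases.append(
                CaseRecord(
                    case_id=cid,
                    cohort=str(group["cohort"].iloc[0]),
                    scanner=str(group["scanner"].iloc[0]),
                    ground_truth=truth_by_case[cid],
                    image_sets=tuple(sorted(sets, key=lambda s: s.set_index)),
                    expert_call=expert_by_case.get(cid),
                )
            )
        except ValidationError as exc:
            problems.append(str(exc))
    if problems:
        raise ValidationError("invalid input tables:\n  " + "\n  ".join(problems))
    if not cases:
        raise ValidationError("input tables yield no cases")
    return cases


def load_cases(score_path: PathLike, case_path: PathLike) -> List[CaseRecord]:
    """Read both tables and assemble validated case records."""
    return cases_from_tables(read_score_table(score_path), read_case_table(case_path))


def cases_to_tables(cases: Iterable[CaseRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten case records back into (score table, case table) frames."""
    score_rows, case_rows = [], []
    for case in cases:
        case_rows.append(
            {
                "case_id": case.case_id,
                "ground_truth": case.ground_truth.value,
                "expert_call": case.expert_call.value if case.expert_call else "",
            }
        )
        for s in case.image_sets:
            score_rows.append(
                {
                    "case_id": s.case_id,
                    "cohort": case.cohort,
                    "scanner": case.scanner,
                    "set_index": s.set_index,
                    "dsa_score": s.dsa_score,
                    "pathologist_score": s.pathologist_score,
                    "causes": ";".join(sorted(c.value for c in s.cause_annotations)),
                }
            )
    return pd.DataFrame(score_rows), pd.DataFrame(case_rows)


def write_cohort(
    cases: Iterable[CaseRecord], score_path: PathLike, case_path: PathLike
) -> None:
    """Write score and case tables as CSV."""
    scores, case_table = cases_to_tables(cases)
    # %.17g keeps scores bit-exact across a write/read round trip
    scores.to_csv(score_path, index=False, float_format="%.17g")
    case_table.to_csv(case_path, index=False)


def load_image(path: PathLike) -> np.ndarray:
    """Read one 8-bit RGB tile, erroring with the offending file name."""
    import imageio.v3 as iio

    try:
        image = iio.imread(path)
    except Exception as exc:
        raise ValidationError(f"cannot read image {path}: {exc}") from exc
    image = np.asarray(image)
    if image.ndim == 3 and image.shape[2] == 4:  # drop alpha if present
        image = image[:, :, :3]
    if image.ndim != 3 or image.shape[2] != 3 or image.dtype != np.uint8:
        raise ValidationError(
            f"image {path} is not 8-bit RGB (shape {image.shape}, dtype {image.dtype})"
        )
    return image
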