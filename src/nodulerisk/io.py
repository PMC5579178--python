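"""CSV/TSV reading and writing of cohorts.

Two layouts are supported:

* single-file: one nodule per row, participant covariates repeated on
  every row of that participant;
* two-file: a nodule table plus a separate participant table.

Files are comma-separated UTF-8 with "." as decimal separator; pass
``dialect="tsv"`` for tab separation.  Booleans are written as
``true``/``false``.  Column order on output is fixed so that repeated
writes of the same cohort are byte-identical.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .records import (
    Calcification,
    Cohort,
    NoduleRecord,
    NoduleType,
    ParticipantRecord,
    SchemaError,
    Sex,
    ValidationError,
    build_cohort,
)

NODULE_COLUMNS = [
    "nodule_id",
    "participant_id",
    "type",
    "is_pfn",
    "calcification",
    "spiculated",
    "upper_lobe",
    "d_longest_axial",
    "d_perp_axial",
    "volume",
    "d_mean3d",
    "d_longest_axial_solid",
    "d_perp_axial_solid",
    "d_mean3d_solid",
    "malignant",
]

PARTICIPANT_COLUMNS = [
    "participant_id",
    "age",
    "sex",
    "family_history_lung_cancer",
    "emphysema",
    "nodule_count_additional",
    "has_cancer",
]

_REQUIRED_NODULE = [
    "nodule_id",
    "participant_id",
    "type",
    "is_pfn",
    "calcification",
    "spiculated",
    "upper_lobe",
    "d_longest_axial",
    "d_perp_axial",
    "malignant",
]

_REQUIRED_PARTICIPANT = [
    "participant_id",
    "age",
    "sex",
    "family_history_lung_cancer",
    "emphysema",
]

_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f"}


def _sep(dialect: str) -> str:
    if dialect == "csv":
        return ","
    if dialect == "tsv":
        return "\t"
    raise ValueError(f"dialect must be 'csv' or 'tsv', got {dialect!r}")


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return isinstance(value, str) and value.strip() == ""


def _parse_bool(value, context: str) -> bool:
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValidationError(f"{context}: cannot parse boolean from {value!r}")


def _parse_float(value, context: str) -> Optional[float]:
    if _is_missing(value):
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ValidationError(f"{context}: cannot parse number from {value!r}")


def _parse_enum(enum_cls, value, context: str):
    try:
        return enum_cls(str(value).strip().lower())
    except ValueError:
        allowed = ", ".join(e.value for e in enum_cls)
        raise ValidationError(
            f"{context}: {value!r} is not one of {allowed}"
        )


def _check_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{what} table is missing required column(s): "
            + ", ".join(missing)
        )


def _nodule_from_row(row: dict) -> NoduleRecord:
    ctx = f"nodule {row.get('nodule_id')!r}"
    return NoduleRecord(
        nodule_id=str(row["nodule_id"]),
        participant_id=str(row["participant_id"]),
        type=_parse_enum(NoduleType, row["type"], ctx),
        is_pfn=_parse_bool(row["is_pfn"], ctx),
        calcification=_parse_enum(Calcification, row["calcification"], ctx),
        spiculated=_parse_bool(row["spiculated"], ctx),
        upper_lobe=_parse_bool(row["upper_lobe"], ctx),
        d_longest_axial=_parse_float(row["d_longest_axial"], ctx),
        d_perp_axial=_parse_float(row["d_perp_axial"], ctx),
        volume=_parse_float(row.get("volume"), ctx),
        d_mean3d=_parse_float(row.get("d_mean3d"), ctx),
        d_longest_axial_solid=_parse_float(
            row.get("d_longest_axial_solid"), ctx
        ),
        d_perp_axial_solid=_parse_float(row.get("d_perp_axial_solid"), ctx),
        d_mean3d_solid=_parse_float(row.get("d_mean3d_solid"), ctx),
        malignant=_parse_bool(row["malignant"], ctx),
    )


def _participant_from_row(row: dict) -> tuple[ParticipantRecord, bool, bool]:
    """Build a participant; returns (record, count_missing, cancer_missing)."""
    ctx = f"participant {row.get('participant_id')!r}"
    count = row.get("nodule_count_additional")
    count_missing = _is_missing(count)
    cancer = row.get("has_cancer")
    cancer_missing = _is_missing(cancer)
    record = ParticipantRecord(
        participant_id=str(row["participant_id"]),
        age=_parse_float(row["age"], ctx),
        sex=_parse_enum(Sex, row["sex"], ctx),
        family_history_lung_cancer=_parse_bool(
            row["family_history_lung_cancer"], ctx
        ),
        emphysema=_parse_bool(row["emphysema"], ctx),
        nodule_count_additional=0 if count_missing else int(float(count)),
        has_cancer=False if cancer_missing else _parse_bool(cancer, ctx),
    )
    return record, count_missing, cancer_missing


def read_cohort(
    path: Union[str, Path],
    dialect: str = "csv",
    participants_path: Optional[Union[str, Path]] = None,
) -> Cohort:
    """Read a cohort from CSV/TSV.

    With ``participants_path`` the two-file layout is used; otherwise
    the participant covariate columns must be present (repeated) in the
    nodule file.  Missing ``nodule_count_additional`` is derived as the
    number of linked nodules minus one, missing ``has_cancer`` from the
    nodule malignancy labels.
    """
    sep = _sep(dialect)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    _check_columns(df, _REQUIRED_NODULE, "nodule")

    if participants_path is not None:
        pdf = pd.read_csv(
            participants_path, sep=sep, dtype=str, keep_default_na=False
        )
    else:
        covariate_cols = [c for c in PARTICIPANT_COLUMNS if c in df.columns]
        _check_columns(df, _REQUIRED_PARTICIPANT, "participant (inline)")
        pdf = df[covariate_cols].drop_duplicates()
        dup = pdf["participant_id"][pdf["participant_id"].duplicated()]
        if len(dup):
            raise ValidationError(
                "inconsistent repeated participant covariates for: "
                + ", ".join(sorted(set(dup)))
            )
    _check_columns(pdf, _REQUIRED_PARTICIPANT, "participant")

    nodules = [_nodule_from_row(row) for row in df.to_dict("records")]
    participants = []
    any_count_missing = False
    any_cancer_missing = False
    for row in pdf.to_dict("records"):
        rec, count_missing, cancer_missing = _participant_from_row(row)
        participants.append(rec)
        any_count_missing = any_count_missing or count_missing
        any_cancer_missing = any_cancer_missing or cancer_missing
    return build_cohort(
        participants,
        nodules,
        derive_counts=any_count_missing,
        derive_cancer=any_cancer_missing,
    )


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (NoduleType, Calcification, Sex)):
        return value.value
    return repr(value) if isinstance(value, float) else str(value)


def _nodule_row(n: NoduleRecord) -> dict:
    return {
        "nodule_id": n.nodule_id,
        "participant_id": n.participant_id,
        "type": _fmt(n.type),
        "is_pfn": _fmt(n.is_pfn),
        "calcification": _fmt(n.calcification),
        "spiculated": _fmt(n.spiculated),
        "upper_lobe": _fmt(n.upper_lobe),
        "d_longest_axial": _fmt(n.d_longest_axial),
        "d_perp_axial": _fmt(n.d_perp_axial),
        "volume": _fmt(n.volume),
        "d_mean3d": _fmt(n.d_mean3d),
        "d_longest_axial_solid": _fmt(n.d_longest_axial_solid),
        "d_perp_axial_solid": _fmt(n.d_perp_axial_solid),
        "d_mean3d_solid": _fmt(n.d_mean3d_solid),
        "malignant": _fmt(n.malignant),
    }


def _participant_row(p: ParticipantRecord) -> dict:
    return {
        "participant_id": p.participant_id,
        "age": _fmt(p.age),
        "sex": _fmt(p.sex),
        "family_history_lung_cancer": _fmt(p.family_history_lung_cancer),
        "emphysema": _fmt(p.emphysema),
        "nodule_count_additional": str(p.nodule_count_additional),
        "has_cancer": _fmt(p.has_cancer),
    }


def write_cohort(
    cohort: Cohort,
    path: Union[str, Path],
    dialect: str = "csv",
    participants_path: Optional[Union[str, Path]] = None,
) -> None:
    """Write a cohort to CSV/TSV; inverse of :func:`read_cohort`.

    Without ``participants_path`` the single-file layout is written with
    participant covariates repeated per nodule row.
    """
    sep = _sep(dialect)
    nodule_rows = [_nodule_row(n) for n in cohort.nodules]
    if participants_path is not None:
        pd.DataFrame(nodule_rows, columns=NODULE_COLUMNS).to_csv(
            path, sep=sep, index=False
        )
        participant_rows = [_participant_row(p) for p in cohort.participants]
        pd.DataFrame(participant_rows, columns=PARTICIPANT_COLUMNS).to_csv(
            participants_path, sep=sep, index=False
        )
        return
    linked = {n.participant_id for n in cohort.nodules}
    orphans = [
        p.participant_id for p in cohort.participants
        if p.participant_id not in linked
    ]
    if orphans:
        raise ValidationError(
            "single-file layout cannot represent participants without "
            "nodules (" + ", ".join(orphans) + "); use participants_path"
        )
    by_id = {p.participant_id: _participant_row(p) for p in cohort.participants}
    combined_cols = NODULE_COLUMNS + [
        c for c in PARTICIPANT_COLUMNS if c != "participant_id"
    ]
    rows = []
    for nrow, nodule in zip(nodule_rows, cohort.nodules):
        row = dict(nrow)
        prow = by_id[nodule.participant_id]
        row.update({k: v for k, v in prow.items() if k != "participant_id"})
        rows.append(row)
    pd.DataFrame(rows, columns=combined_cols).to_csv(path, sep=sep, index=False)
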