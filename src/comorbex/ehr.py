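"""De-identified hospital-stay extract: data model and delimited-file I/O.

A cohort is four flat files keyed by ``stay_id`` — stays, billing codes,
prescriptions and laboratory results — mirroring how clinical data
warehouses export structured EHR content. The stay is the unit of
detection and of every denominator downstream; patient_id is retained only
so reviewers can look across a patient's stays.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path

import pandas as pd

from .errors import CohortValidationError, ComorbexError
from .icd10 import normalize_codes

__all__ = [
    "Prescription",
    "LabResult",
    "Stay",
    "Cohort",
    "DEFAULT_CANONICAL_UNITS",
    "read_cohort",
    "write_cohort",
    "write_suggestions",
]

logger = logging.getLogger(__name__)

#: Canonical measurement unit per analyte; lab rows in any other unit are
#: rejected rather than silently mixed.
DEFAULT_CANONICAL_UNITS = {"potassium": "mmol/L"}


@dataclass(frozen=True)
class Prescription:
    cud: str
    start: date
    end: date | None = None

    def __post_init__(self) -> None:
        if self.end is not None and self.end < self.start:
            raise CohortValidationError(f"prescription {self.cud}: end {self.end} before start {self.start}")


@dataclass(frozen=True)
class LabResult:
    analyte: str
    value: float
    unit: str
    observed: datetime

    def __post_init__(self) -> None:
        if not self.unit:
            raise CohortValidationError(f"lab result {self.analyte}: empty unit")
        v = float(self.value)
        if v != v or v in (float("inf"), float("-inf")):
            raise CohortValidationError(f"lab result {self.analyte}: non-finite value {self.value}")


@dataclass(frozen=True)
class Stay:
    """One hospital stay with billing codes, prescriptions and labs."""

    stay_id: str
    patient_id: str
    admit: date
    discharge: date
    billing_codes: frozenset[str] = frozenset()
    prescriptions: tuple[Prescription, ...] = ()
    labs: tuple[LabResult, ...] = ()
    ward: str = ""

    def __post_init__(self) -> None:
        if self.discharge < self.admit:
            raise CohortValidationError(f"stay {self.stay_id}: discharge before admission")
        object.__setattr__(self, "billing_codes", normalize_codes(self.billing_codes))
        object.__setattr__(self, "prescriptions", tuple(self.prescriptions))
        object.__setattr__(self, "labs", tuple(self.labs))

    @property
    def prescribed_cuds(self) -> frozenset[str]:
        return frozenset(p.cud for p in self.prescriptions)


@dataclass(frozen=True)
class Cohort:
    stays: tuple[Stay, ...]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "stays", tuple(self.stays))
        ids = [s.stay_id for s in self.stays]
        if len(ids) != len(set(ids)):
            raise CohortValidationError("duplicate stay_id in cohort")

    def __len__(self) -> int:
        return len(self.stays)

    def __iter__(self):
        return iter(self.stays)


def _parse_date(value: str, where: str) -> date:
    try:
        return date.fromisoformat(str(value).strip()[:10])
    except ValueError as exc:
        raise CohortValidationError(f"malformed date {value!r} in {where}") from exc


def _parse_datetime(value: str, where: str) -> datetime:
    try:
        return datetime.fromisoformat(str(value).strip())
    except ValueError as exc:
        raise CohortValidationError(f"malformed datetime {value!r} in {where}") from exc


def _read(path, cols: set[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except OSError as exc:
        raise ComorbexError(f"cannot read {path}: {exc}") from exc
    missing = cols - set(df.columns)
    if missing:
        raise ComorbexError(f"{path} lacks columns: {sorted(missing)}")
    return df


def read_cohort(
    stays_path,
    codes_path,
    rx_path,
    labs_path,
    orphan_tolerance: int = 0,
    canonical_units: dict[str, str] | None = None,
    metadata: dict | None = None,
) -> Cohort:
    """Assemble a Cohort from the four extract files.

    Rows in codes/rx/labs whose stay_id has no stay row are orphans; more
    than ``orphan_tolerance`` of them is an error (default 0). Lab rows
    whose unit differs from the canonical unit for their analyte are
    rejected the same way — silent unit mixing is the classic failure mode
    for threshold rules.
    """
    units = DEFAULT_CANONICAL_UNITS if canonical_units is None else canonical_units
    stays_df = _read(stays_path, {"stay_id", "patient_id", "admit", "discharge"})
    codes_df = _read(codes_path, {"stay_id", "icd10"})
    rx_df = _read(rx_path, {"stay_id", "cud", "start"})
    labs_df = _read(labs_path, {"stay_id", "analyte", "value", "unit", "observed"})

    known = set(stays_df["stay_id"])
    rejects: list[str] = []

    codes_by_stay: dict[str, set[str]] = {}
    for row in codes_df.itertuples(index=False):
        if row.stay_id not in known:
            rejects.append(f"codes: orphan stay_id {row.stay_id!r}")
            continue
        codes_by_stay.setdefault(row.stay_id, set()).add(row.icd10)

    rx_by_stay: dict[str, list[Prescription]] = {}
    for row in rx_df.itertuples(index=False):
        if row.stay_id not in known:
            rejects.append(f"rx: orphan stay_id {row.stay_id!r}")
            continue
        end_raw = getattr(row, "end", "")
        rx_by_stay.setdefault(row.stay_id, []).append(
            Prescription(
                cud=row.cud,
                start=_parse_date(row.start, f"rx row for stay {row.stay_id}"),
                end=_parse_date(end_raw, f"rx row for stay {row.stay_id}") if str(end_raw).strip() else None,
            )
        )

    labs_by_stay: dict[str, list[LabResult]] = {}
    for row in labs_df.itertuples(index=False):
        if row.stay_id not in known:
            rejects.append(f"labs: orphan stay_id {row.stay_id!r}")
            continue
        canon = units.get(row.analyte)
        if canon is not None and row.unit != canon:
            rejects.append(
                f"labs: stay {row.stay_id} analyte {row.analyte!r} unit {row.unit!r} != canonical {canon!r}"
            )
            continue
        labs_by_stay.setdefault(row.stay_id, []).append(
            LabResult(
                analyte=row.analyte,
                value=float(row.value),
                unit=row.unit,
                observed=_parse_datetime(row.observed, f"lab row for stay {row.stay_id}"),
            )
        )

    if len(rejects) > orphan_tolerance:
        preview = "; ".join(rejects[:10])
        raise CohortValidationError(f"{len(rejects)} rejected rows (tolerance {orphan_tolerance}): {preview}")
    if rejects:
        logger.warning("rejected %d rows: %s", len(rejects), rejects)

    stays = []
    for row in stays_df.itertuples(index=False):
        sid = row.stay_id
        stays.append(
            Stay(
                stay_id=sid,
                patient_id=row.patient_id,
                admit=_parse_date(row.admit, f"stay {sid}"),
                discharge=_parse_date(row.discharge, f"stay {sid}"),
                billing_codes=frozenset(codes_by_stay.get(sid, set())),
                prescriptions=tuple(rx_by_stay.get(sid, [])),
                labs=tuple(labs_by_stay.get(sid, [])),
                ward=str(getattr(row, "ward", "")),
            )
        )
    logger.info(
        "read cohort: %d stays, %d code rows, %d rx rows, %d lab rows",
        len(stays), len(codes_df), len(rx_df), len(labs_df),
    )
    return Cohort(stays=tuple(stays), metadata=metadata or {"source": str(stays_path)})


def read_cohort_dir(directory, **kwargs) -> Cohort:
    """read_cohort over the conventional file names in *directory*."""
    d = Path(directory)
    return read_cohort(d / "stays.csv", d / "codes.csv", d / "rx.csv", d / "labs.csv", **kwargs)


def write_cohort(cohort: Cohort, directory) -> None:
    """Write the four extract files (stays/codes/rx/labs) for *cohort*.

    Output is deterministically sorted so identical cohorts produce
    byte-identical files.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    stays_rows, code_rows, rx_rows, lab_rows = [], [], [], []
    for s in sorted(cohort.stays, key=lambda s: s.stay_id):
        stays_rows.append(
            {
                "stay_id": s.stay_id,
                "patient_id": s.patient_id,
                "admit": s.admit.isoformat(),
                "discharge": s.discharge.isoformat(),
                "ward": s.ward,
            }
        )
        for c in sorted(s.billing_codes):
            code_rows.append({"stay_id": s.stay_id, "icd10": c})
        for p in sorted(s.prescriptions, key=lambda p: (p.cud, p.start)):
            rx_rows.append(
                {
                    "stay_id": s.stay_id,
                    "cud": p.cud,
                    "start": p.start.isoformat(),
                    "end": p.end.isoformat() if p.end else "",
                }
            )
        for lab in sorted(s.labs, key=lambda x: (x.analyte, x.observed)):
            lab_rows.append(
                {
                    "stay_id": s.stay_id,
                    "analyte": lab.analyte,
                    "value": repr(lab.value),
                    "unit": lab.unit,
                    "observed": lab.observed.isoformat(),
                }
            )
    pd.DataFrame(stays_rows, columns=["stay_id", "patient_id", "admit", "discharge", "ward"]).to_csv(
        d / "stays.csv", index=False
    )
    pd.DataFrame(code_rows, columns=["stay_id", "icd10"]).to_csv(d / "codes.csv", index=False)
    pd.DataFrame(rx_rows, columns=["stay_id", "cud", "start", "end"]).to_csv(d / "rx.csv", index=False)
    pd.DataFrame(lab_rows, columns=["stay_id", "analyte", "value", "unit", "observed"]).to_csv(
        d / "labs.csv", index=False
    )


def write_suggestions(suggestions, path) -> None:
    """Write suggestions as CSV, one row per (stay, drug, candidate code).

    Rows are sorted by (stay_id, cud, code) so the output is byte-identical
    across runs regardless of input order.
    """
    rows = []
    for s in suggestions:
        for code in sorted(s.candidate_codes):
            rows.append(
                {
                    "stay_id": s.stay_id,
                    "cud": s.cud,
                    "code": code,
                    "source": s.source,
                    "evidence": s.evidence,
                }
            )
    rows.sort(key=lambda r: (r["stay_id"], r["cud"], r["code"]))
    pd.DataFrame(rows, columns=["stay_id", "cud", "code", "source", "evidence"]).to_csv(path, index=False)
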