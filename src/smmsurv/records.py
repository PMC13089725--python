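"""Data model and delimited-text I/O for both hospitalization schema pairs.

The public dialect mirrors the Brazilian SIH/SUS distribution: a "reduced"
admissions table (one row per admission form, with 14 diagnosis fields, an
ICU-days counter and linkage keys) plus a "professional services" table of
procedure acts linked by admission-form number.  The private dialect mirrors
the ANS hospital-procedures release: a "consolidated" admissions table (a
type-of-hospitalization field and four ICD fields) plus a "detailed"
procedures table linked by event key.

Column names, date formats and discharge-reason code maps are configuration
(`ColumnMap`, `*_DISCHARGE_MAP`): the shipped defaults describe the synthetic
dialect (ISO-8601 dates); real distributions are accommodated by remapping.
Loading conserves rows: every input row becomes either a record or a flagged
entry in the `LoadReport`.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .codebook import SIGTAP, TUSS, IcdCode, ProcedureCode

__all__ = [
    "PUBLIC",
    "PRIVATE",
    "PUBLIC_DIAG_FIELDS",
    "PRIVATE_DIAG_FIELDS",
    "DischargeOutcome",
    "AdmissionRecord",
    "ColumnMap",
    "LoadReport",
    "RecordsError",
    "read_public_pair",
    "read_private_pair",
    "write_cohort",
    "write_public_pair",
    "write_private_pair",
]

PUBLIC = "PUBLIC"
PRIVATE = "PRIVATE"

PUBLIC_DIAG_FIELDS = (
    "principal",
    *(f"secondary_{i}" for i in range(1, 10)),
    "icd_notification",
    "icd_death",
    "icd_associated",
)
PRIVATE_DIAG_FIELDS = tuple(f"icd_{i}" for i in range(1, 5))


class RecordsError(ValueError):
    """Raised for structural problems (e.g. a missing linkage column)."""


class DischargeOutcome(enum.Enum):
    DISCHARGE_ALIVE = "DISCHARGE_ALIVE"
    DEATH = "DEATH"
    STAY = "STAY"
    TRANSFER = "TRANSFER"
    UNKNOWN = "UNKNOWN"

    @property
    def known(self) -> bool:
        """Known survival outcome: live discharge or in-hospital death."""
        return self in (DischargeOutcome.DISCHARGE_ALIVE, DischargeOutcome.DEATH)


# Synthetic-dialect discharge-reason code maps (raw code -> outcome).  The
# private schema's historical code list is noisier in real data (long-disused
# codes occur); unmapped codes load as UNKNOWN rather than failing.
PUBLIC_DISCHARGE_MAP: dict[str, DischargeOutcome] = {
    "1": DischargeOutcome.DISCHARGE_ALIVE,
    "2": DischargeOutcome.TRANSFER,
    "3": DischargeOutcome.STAY,
    "4": DischargeOutcome.DEATH,
}
PRIVATE_DISCHARGE_MAP: dict[str, DischargeOutcome] = {
    "1": DischargeOutcome.DISCHARGE_ALIVE,
    "2": DischargeOutcome.TRANSFER,
    "3": DischargeOutcome.STAY,       # hospital permanence
    "4": DischargeOutcome.DEATH,
    "5": DischargeOutcome.STAY,       # administrative discharge
}


@dataclass(frozen=True)
class AdmissionRecord:
    """One admission form (public) or hospitalization event (private)."""

    schema: str
    form_id: str
    admission_date: date
    discharge_date: date
    discharge_reason: DischargeOutcome
    person_key: str | None = None
    hospital_key: str | None = None
    type_of_hospitalization: str | None = None
    icu_days: int = 0
    diagnoses: tuple[tuple[str, IcdCode], ...] = ()
    procedures: tuple[ProcedureCode, ...] = ()
    # provenance only (the as-recorded discharge code); not identity
    raw_discharge_code: str | None = field(default=None, compare=False)

    def diagnosis_codes(self) -> list[str]:
        """Valid normalized ICD codes, any field, in field order."""
        return [c.normalized for _, c in self.diagnoses if c.valid]

    def procedure_codes(self) -> list[str]:
        return [p.normalized for p in self.procedures if p.valid]

    @property
    def terminology(self) -> str:
        return SIGTAP if self.schema == PUBLIC else TUSS


@dataclass(frozen=True)
class ColumnMap:
    """Column dictionary for one schema pair (synthetic-dialect defaults)."""

    form_id: str = "FORM_ID"
    person_key: str = "PERSON_KEY"
    hospital_key: str = "HOSPITAL_KEY"
    admission_date: str = "ADMISSION_DATE"
    discharge_date: str = "DISCHARGE_DATE"
    discharge_reason: str = "DISCHARGE_REASON"
    icu_days: str = "ICU_DAYS"
    type_of_hospitalization: str = "TYPE_OF_HOSPITALIZATION"
    procedure_code: str = "PROCEDURE_CODE"
    diagnosis_columns: Mapping[str, str] = field(default_factory=dict)
    date_format: str = "%Y-%m-%d"

    @staticmethod
    def public_default() -> "ColumnMap":
        cols = {"principal": "DIAG_PRINCIPAL"}
        cols.update({f"secondary_{i}": f"DIAG_SECONDARY_{i}" for i in range(1, 10)})
        cols.update({"icd_notification": "ICD_NOTIFICATION",
                     "icd_death": "ICD_DEATH",
                     "icd_associated": "ICD_ASSOCIATED"})
        return ColumnMap(diagnosis_columns=cols)

    @staticmethod
    def private_default() -> "ColumnMap":
        return ColumnMap(
            form_id="EVENT_ID",
            diagnosis_columns={f: f.upper() for f in PRIVATE_DIAG_FIELDS},
        )


@dataclass
class LoadReport:
    """Load accounting: rows in = records out + flagged rows."""

    rows_read: int = 0
    records_loaded: int = 0
    flagged: list[tuple[str, str]] = field(default_factory=list)
    orphan_service_rows: int = 0
    invalid_icd_values: int = 0
    invalid_procedure_values: int = 0
    unmapped_discharge_codes: int = 0

    def conserved(self) -> bool:
        return self.rows_read == self.records_loaded + len(self.flagged)

    def summary(self) -> str:
        return (
            f"rows={self.rows_read} loaded={self.records_loaded} "
            f"flagged={len(self.flagged)} orphans={self.orphan_service_rows} "
            f"invalid_icd={self.invalid_icd_values} "
            f"invalid_proc={self.invalid_procedure_values} "
            f"unmapped_discharge={self.unmapped_discharge_codes}"
        )


def _read_csv(path, delimiter: str, encoding: str) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=delimiter, encoding=encoding, dtype=str,
                           keep_default_na=False)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


def _parse_date(value: str, fmt: str) -> date | None:
    try:
        return datetime.strptime(value.strip(), fmt).date()
    except (ValueError, AttributeError):
        return None


def _procedure_lookup(
    frame: pd.DataFrame, key_col: str, proc_col: str, terminology: str,
    known_keys: set[str], report: LoadReport,
) -> dict[str, list[ProcedureCode]]:
    if key_col not in frame.columns:
        raise RecordsError(f"services table lacks linkage column {key_col!r}")
    if proc_col not in frame.columns:
        raise RecordsError(f"services table lacks procedure column {proc_col!r}")
    lookup: dict[str, list[ProcedureCode]] = {}
    for key, raw in zip(frame[key_col], frame[proc_col]):
        if key not in known_keys:
            report.orphan_service_rows += 1
            continue
        code = ProcedureCode.parse(raw, terminology)
        if not code.valid:
            report.invalid_procedure_values += 1
        lookup.setdefault(key, []).append(code)
    return lookup


def _diagnoses(row, colmap: ColumnMap, fields: Sequence[str],
               report: LoadReport) -> tuple[tuple[str, IcdCode], ...]:
    out = []
    for fname in fields:
        col = colmap.diagnosis_columns[fname]
        raw = row.get(col, "")
        if raw is None or not str(raw).strip():
            continue
        code = IcdCode.parse(str(raw).strip())
        if not code.valid:
            report.invalid_icd_values += 1
        out.append((fname, code))
    return tuple(out)


def _outcome(raw: str, mapping: Mapping[str, DischargeOutcome],
             report: LoadReport) -> DischargeOutcome:
    raw = (raw or "").strip()
    if raw in mapping:
        return mapping[raw]
    if raw:
        report.unmapped_discharge_codes += 1
    return DischargeOutcome.UNKNOWN


def read_public_pair(
    reduced_path,
    services_path,
    column_map: ColumnMap | None = None,
    discharge_map: Mapping[str, DischargeOutcome] | None = None,
    delimiter: str = ",",
    encoding: str = "utf-8",
) -> tuple[list[AdmissionRecord], LoadReport]:
    """Load the public-schema pair, joining procedure acts by form number."""
    colmap = column_map or ColumnMap.public_default()
    dmap = discharge_map or PUBLIC_DISCHARGE_MAP
    report = LoadReport()
    reduced = _read_csv(reduced_path, delimiter, encoding)
    if colmap.form_id not in reduced.columns:
        raise RecordsError(f"reduced table lacks linkage column {colmap.form_id!r}")
    report.rows_read = len(reduced)
    services = _read_csv(services_path, delimiter, encoding)
    if services.empty and colmap.form_id not in services.columns:
        procs: dict[str, list[ProcedureCode]] = {}
    else:
        procs = _procedure_lookup(
            services, colmap.form_id, colmap.procedure_code, SIGTAP,
            set(reduced[colmap.form_id]), report)

    records: list[AdmissionRecord] = []
    for row in reduced.to_dict("records"):
        form_id = str(row[colmap.form_id])
        adm = _parse_date(row.get(colmap.admission_date, ""), colmap.date_format)
        dis = _parse_date(row.get(colmap.discharge_date, ""), colmap.date_format)
        if adm is None or dis is None:
            report.flagged.append((form_id, "unparseable date"))
            continue
        if dis < adm:
            report.flagged.append((form_id, "discharge before admission"))
            continue
        try:
            icu = int(str(row.get(colmap.icu_days, "0")).strip() or 0)
        except ValueError:
            icu = -1
        if icu < 0:
            report.flagged.append((form_id, "invalid ICU-days counter"))
            continue
        records.append(AdmissionRecord(
            schema=PUBLIC,
            form_id=form_id,
            person_key=str(row.get(colmap.person_key, "")).strip() or None,
            hospital_key=str(row.get(colmap.hospital_key, "")).strip() or None,
            admission_date=adm,
            discharge_date=dis,
            icu_days=icu,
            diagnoses=_diagnoses(row, colmap, PUBLIC_DIAG_FIELDS, report),
            procedures=tuple(procs.get(form_id, ())),
            discharge_reason=_outcome(row.get(colmap.discharge_reason, ""),
                                      dmap, report),
            raw_discharge_code=str(row.get(colmap.discharge_reason, "")).strip()
            or None,
        ))
    report.records_loaded = len(records)
    return records, report


def read_private_pair(
    consolidated_path,
    detailed_path,
    column_map: ColumnMap | None = None,
    discharge_map: Mapping[str, DischargeOutcome] | None = None,
    delimiter: str = ",",
    encoding: str = "utf-8",
) -> tuple[list[AdmissionRecord], LoadReport]:
    """Load the private-schema pair, joining procedures by event key."""
    colmap = column_map or ColumnMap.private_default()
    dmap = discharge_map or PRIVATE_DISCHARGE_MAP
    report = LoadReport()
    consolidated = _read_csv(consolidated_path, delimiter, encoding)
    if colmap.form_id not in consolidated.columns:
        raise RecordsError(
            f"consolidated table lacks linkage column {colmap.form_id!r}")
    report.rows_read = len(consolidated)
    detailed = _read_csv(detailed_path, delimiter, encoding)
    if detailed.empty and colmap.form_id not in detailed.columns:
        procs: dict[str, list[ProcedureCode]] = {}
    else:
        procs = _procedure_lookup(
            detailed, colmap.form_id, colmap.procedure_code, TUSS,
            set(consolidated[colmap.form_id]), report)

    records: list[AdmissionRecord] = []
    for row in consolidated.to_dict("records"):
        event_id = str(row[colmap.form_id])
        adm = _parse_date(row.get(colmap.admission_date, ""), colmap.date_format)
        dis = _parse_date(row.get(colmap.discharge_date, ""), colmap.date_format)
        if adm is None or dis is None:
            report.flagged.append((event_id, "unparseable date"))
            continue
        if dis < adm:
            report.flagged.append((event_id, "discharge before admission"))
            continue
        records.append(AdmissionRecord(
            schema=PRIVATE,
            form_id=event_id,
            admission_date=adm,
            discharge_date=dis,
            type_of_hospitalization=str(
                row.get(colmap.type_of_hospitalization, "")).strip() or None,
            diagnoses=_diagnoses(row, colmap, PRIVATE_DIAG_FIELDS, report),
            procedures=tuple(procs.get(event_id, ())),
            discharge_reason=_outcome(row.get(colmap.discharge_reason, ""),
                                      dmap, report),
            raw_discharge_code=str(row.get(colmap.discharge_reason, "")).strip()
            or None,
        ))
    report.records_loaded = len(records)
    return records, report


# ---------------------------------------------------------------------------
# writers (synthetic dialect; round-trips with the readers above)
# ---------------------------------------------------------------------------

_REVERSE_PUBLIC = {v: k for k, v in PUBLIC_DISCHARGE_MAP.items()}
_REVERSE_PRIVATE = {v: k for k, v in PRIVATE_DISCHARGE_MAP.items()
                    if k != "5"}  # prefer the canonical STAY code


def _discharge_code(rec: AdmissionRecord, reverse: Mapping) -> str:
    if rec.raw_discharge_code is not None:
        return rec.raw_discharge_code
    return reverse.get(rec.discharge_reason, "9")


def write_public_pair(records: Iterable[AdmissionRecord],
                      reduced_path, services_path) -> None:
    colmap = ColumnMap.public_default()
    rows, svc_rows = [], []
    for rec in records:
        if rec.schema != PUBLIC:
            raise RecordsError("write_public_pair got a non-public record")
        row = {
            colmap.form_id: rec.form_id,
            colmap.person_key: rec.person_key or "",
            colmap.hospital_key: rec.hospital_key or "",
            colmap.admission_date: rec.admission_date.isoformat(),
            colmap.discharge_date: rec.discharge_date.isoformat(),
            colmap.icu_days: str(rec.icu_days),
            colmap.discharge_reason: _discharge_code(rec, _REVERSE_PUBLIC),
        }
        diag = dict.fromkeys(colmap.diagnosis_columns.values(), "")
        for fname, code in rec.diagnoses:
            diag[colmap.diagnosis_columns[fname]] = code.raw
        row.update(diag)
        rows.append(row)
        svc_rows.extend(
            {colmap.form_id: rec.form_id, colmap.procedure_code: p.raw}
            for p in rec.procedures)
    header = [colmap.form_id, colmap.person_key, colmap.hospital_key,
              colmap.admission_date, colmap.discharge_date,
              *colmap.diagnosis_columns.values(),
              colmap.icu_days, colmap.discharge_reason]
    pd.DataFrame(rows, columns=header).to_csv(reduced_path, index=False)
    pd.DataFrame(svc_rows, columns=[colmap.form_id, colmap.procedure_code]) \
        .to_csv(services_path, index=False)


def write_private_pair(records: Iterable[AdmissionRecord],
                       consolidated_path, detailed_path) -> None:
    colmap = ColumnMap.private_default()
    rows, det_rows = [], []
    for rec in records:
        if rec.schema != PRIVATE:
            raise RecordsError("write_private_pair got a non-private record")
        row = {
            colmap.form_id: rec.form_id,
            colmap.type_of_hospitalization: rec.type_of_hospitalization or "",
            colmap.admission_date: rec.admission_date.isoformat(),
            colmap.discharge_date: rec.discharge_date.isoformat(),
            colmap.discharge_reason: _discharge_code(rec, _REVERSE_PRIVATE),
        }
        diag = dict.fromkeys(colmap.diagnosis_columns.values(), "")
        for fname, code in rec.diagnoses:
            diag[colmap.diagnosis_columns[fname]] = code.raw
        row.update(diag)
        rows.append(row)
        det_rows.extend(
            {colmap.form_id: rec.form_id, colmap.procedure_code: p.raw}
            for p in rec.procedures)
    header = [colmap.form_id, colmap.type_of_hospitalization,
              colmap.admission_date, colmap.discharge_date,
              *colmap.diagnosis_columns.values(), colmap.discharge_reason]
    pd.DataFrame(rows, columns=header).to_csv(consolidated_path, index=False)
    pd.DataFrame(det_rows, columns=[colmap.form_id, colmap.procedure_code]) \
        .to_csv(detailed_path, index=False)


def write_cohort(records: Sequence[AdmissionRecord], directory) -> dict[str, Path]:
    """Write a mixed cohort as schema pairs under ``directory``.

    Returns the mapping of logical file names to paths.  Reading the pairs
    back yields the same records (round-trip identity).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "public_reduced": directory / "public_reduced.csv",
        "public_services": directory / "public_services.csv",
        "private_consolidated": directory / "private_consolidated.csv",
        "private_detailed": directory / "private_detailed.csv",
    }
    write_public_pair([r for r in records if r.schema == PUBLIC],
                      paths["public_reduced"], paths["public_services"])
    write_private_pair([r for r in records if r.schema == PRIVATE],
                       paths["private_consolidated"], paths["private_detailed"])
    return paths
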