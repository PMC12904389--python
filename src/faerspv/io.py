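"""Reader, writer and case deduplication for FAERS-style quarterly ASCII tables.

The public quarterly files are plain text: one header line naming the
columns, ``$`` as the field delimiter, one record per line.  This module
parses the four tables a disproportionality analysis needs (DEMO, DRUG,
REAC, OUTC) into typed records, normalising the closed vocabularies
(sex, reporter occupation, drug role, outcome code) and FAERS numeric
dates.  Partial dates (year-only or year-month) are kept verbatim but
treated as unknown for any interval arithmetic.
"""

from __future__ import annotations

import csv
import datetime as _dt
import io as _io
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Optional, Sequence, TextIO, Union


class TableKind(str, Enum):
    DEMO = "DEMO"
    DRUG = "DRUG"
    REAC = "REAC"
    OUTC = "OUTC"


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Occupation(str, Enum):
    CONSUMER = "consumer"
    PHYSICIAN = "physician"
    PHARMACIST = "pharmacist"
    OTHER_HEALTH_PROFESSIONAL = "other health-professional"
    UNKNOWN = "unknown"


class DrugRole(str, Enum):
    PRIMARY_SUSPECT = "primary suspect"
    SECONDARY_SUSPECT = "secondary suspect"
    CONCOMITANT = "concomitant"
    INTERACTING = "interacting"


#: FAERS outcome codes: death, life-threatening, hospitalization,
#: disability, congenital anomaly, required intervention, other serious.
OUTCOME_CODES = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")


class ParseError(ValueError):
    """A line of an ASCII table could not be parsed."""


_SEX_MAP = {"M": Sex.MALE, "F": Sex.FEMALE}
_OCCP_MAP = {
    "CN": Occupation.CONSUMER,
    "MD": Occupation.PHYSICIAN,
    "PH": Occupation.PHARMACIST,
    "OT": Occupation.OTHER_HEALTH_PROFESSIONAL,
    "HP": Occupation.OTHER_HEALTH_PROFESSIONAL,
}
_ROLE_MAP = {
    "PS": DrugRole.PRIMARY_SUSPECT,
    "SS": DrugRole.SECONDARY_SUSPECT,
    "C": DrugRole.CONCOMITANT,
    "I": DrugRole.INTERACTING,
}
_ROLE_CODE = {v: k for k, v in _ROLE_MAP.items()}
_SEX_CODE = {Sex.MALE: "M", Sex.FEMALE: "F", Sex.UNKNOWN: ""}
_OCCP_CODE = {
    Occupation.CONSUMER: "CN",
    Occupation.PHYSICIAN: "MD",
    Occupation.PHARMACIST: "PH",
    Occupation.OTHER_HEALTH_PROFESSIONAL: "OT",
    Occupation.UNKNOWN: "",
}

# Older quarters use different header spellings (ISR-era files).
_HEADER_SYNONYMS = {
    "isr": "primaryid",
    "case": "caseid",
    "case_id": "caseid",
    "case_version": "caseversion",
    "gndr_cod": "sex",
    "occr_country": "reporter_country",
    "pt_term": "pt",
    "outc_code": "outc_cod",
}


@dataclass(frozen=True)
class DemoRecord:
    report_id: str
    case_id: str
    case_version: int
    received_date: Optional[_dt.date]
    event_date: Optional[_dt.date]
    received_raw: str
    event_raw: str
    age_value: Optional[float]
    age_unit: Optional[str]
    sex: Sex
    occupation: Occupation
    country: Optional[str]


@dataclass(frozen=True)
class DrugRecord:
    report_id: str
    drug_seq: int
    role: DrugRole
    verbatim_name: str
    active_ingredient: Optional[str]
    therapy_start_date: Optional[_dt.date]
    therapy_start_raw: str = ""


@dataclass(frozen=True)
class ReacRecord:
    report_id: str
    pt: str


@dataclass(frozen=True)
class OutcRecord:
    report_id: str
    outcome_code: str


FaersRecord = Union[DemoRecord, DrugRecord, ReacRecord, OutcRecord]


def parse_faers_date(raw: str) -> Optional[_dt.date]:
    """Parse a FAERS yyyymmdd date; partial or malformed dates become None."""
    raw = raw.strip()
    if len(raw) != 8 or not raw.isdigit():
        return None
    try:
        return _dt.date(int(raw[:4]), int(raw[4:6]), int(raw[6:8]))
    except ValueError:
        return None


def _date_str(d: Optional[_dt.date], raw: str = "") -> str:
    if d is not None:
        return f"{d.year:04d}{d.month:02d}{d.day:02d}"
    return raw


def _parse_int(raw: str, default: int = 0) -> int:
    raw = raw.strip()
    try:
        return int(raw)
    except ValueError:
        return default


def _parse_float(raw: str) -> Optional[float]:
    raw = raw.strip()
    if not raw:
        return None
    try:
        return float(raw)
    except ValueError:
        return None


def _split_lines(stream: Union[str, TextIO]) -> Iterable[str]:
    if isinstance(stream, str):
        stream = _io.StringIO(stream)
    return stream


def _demo_from_row(row: dict) -> DemoRecord:
    report_id = row.get("primaryid", "").strip()
    received_raw = row.get("fda_dt", "").strip()
    event_raw = row.get("event_dt", "").strip()
    sex = _SEX_MAP.get(row.get("sex", "").strip().upper(), Sex.UNKNOWN)
    occp = _OCCP_MAP.get(row.get("occp_cod", "").strip().upper(), Occupation.UNKNOWN)
    country = row.get("reporter_country", "").strip() or None
    return DemoRecord(
        report_id=report_id,
        case_id=row.get("caseid", "").strip() or report_id,
        case_version=_parse_int(row.get("caseversion", ""), 0),
        received_date=parse_faers_date(received_raw),
        event_date=parse_faers_date(event_raw),
        received_raw=received_raw,
        event_raw=event_raw,
        age_value=_parse_float(row.get("age", "")),
        age_unit=row.get("age_cod", "").strip().upper() or None,
        sex=sex,
        occupation=occp,
        country=country,
    )


def _drug_from_row(row: dict) -> DrugRecord:
    start_raw = row.get("start_dt", "").strip()
    role = _ROLE_MAP.get(row.get("role_cod", "").strip().upper(), DrugRole.CONCOMITANT)
    return DrugRecord(
        report_id=row.get("primaryid", "").strip(),
        drug_seq=_parse_int(row.get("drug_seq", ""), 1),
        role=role,
        verbatim_name=row.get("drugname", "").strip(),
        active_ingredient=row.get("prod_ai", "").strip() or None,
        therapy_start_date=parse_faers_date(start_raw),
        therapy_start_raw=start_raw,
    )


def _reac_from_row(row: dict) -> ReacRecord:
    pt = row.get("pt", "").strip()
    return ReacRecord(report_id=row.get("primaryid", "").strip(), pt=pt)


def _outc_from_row(row: dict) -> OutcRecord:
    code = row.get("outc_cod", "").strip().upper()
    if code not in OUTCOME_CODES:
        code = "OT"
    return OutcRecord(report_id=row.get("primaryid", "").strip(), outcome_code=code)


_ROW_PARSERS = {
    TableKind.DEMO: _demo_from_row,
    TableKind.DRUG: _drug_from_row,
    TableKind.REAC: _reac_from_row,
    TableKind.OUTC: _outc_from_row,
}

#: Canonical column order used when writing each table.
TABLE_COLUMNS = {
    TableKind.DEMO: [
        "primaryid", "caseid", "caseversion", "fda_dt", "event_dt",
        "age", "age_cod", "sex", "occp_cod", "reporter_country",
    ],
    TableKind.DRUG: [
        "primaryid", "drug_seq", "role_cod", "drugname", "prod_ai", "start_dt",
    ],
    TableKind.REAC: ["primaryid", "pt"],
    TableKind.OUTC: ["primaryid", "outc_cod"],
}


def parse_ascii_table(stream: Union[str, TextIO], table_kind: Union[TableKind, str]) -> list:
    """Parse one ``$``-delimited table into a list of typed records.

    Parameters
    ----------
    stream
        Text stream or string whose first line is the header.
    table_kind
        Which of the four tables the stream contains.

    Raises
    ------
    ParseError
        If a data line has a different number of fields than the header.
    ValueError
        If ``table_kind`` is not one of the four known tables.
    """
    try:
        kind = table_kind if isinstance(table_kind, TableKind) \
            else TableKind(str(table_kind).upper())
    except ValueError:
        raise ValueError(f"unknown table kind: {table_kind!r}") from None
    make = _ROW_PARSERS[kind]

    reader = csv.reader(_split_lines(stream), delimiter="$")
    try:
        header = next(reader)
    except StopIteration:
        raise ParseError(f"{kind.value}: empty stream, no header line") from None
    names = [_HEADER_SYNONYMS.get(h.strip().lower(), h.strip().lower()) for h in header]

    records = []
    for lineno, fields in enumerate(reader, start=2):
        if not fields:
            continue  # blank trailing line
        if len(fields) != len(names):
            raise ParseError(
                f"{kind.value} line {lineno}: expected {len(names)} fields, got {len(fields)}"
            )
        records.append(make(dict(zip(names, fields))))
    return records


def _demo_to_row(r: DemoRecord) -> list:
    return [
        r.report_id, r.case_id, str(r.case_version),
        _date_str(r.received_date, r.received_raw),
        _date_str(r.event_date, r.event_raw),
        "" if r.age_value is None else f"{r.age_value:g}",
        r.age_unit or "", _SEX_CODE[r.sex], _OCCP_CODE[r.occupation],
        r.country or "",
    ]


def _drug_to_row(r: DrugRecord) -> list:
    return [
        r.report_id, str(r.drug_seq), _ROLE_CODE[r.role], r.verbatim_name,
        r.active_ingredient or "",
        _date_str(r.therapy_start_date, r.therapy_start_raw),
    ]


_ROW_WRITERS = {
    TableKind.DEMO: _demo_to_row,
    TableKind.DRUG: _drug_to_row,
    TableKind.REAC: lambda r: [r.report_id, r.pt],
    TableKind.OUTC: lambda r: [r.report_id, r.outcome_code],
}


def write_ascii_table(records: Sequence[FaersRecord], table_kind: Union[TableKind, str]) -> str:
    """Serialize records back to the ``$``-delimited dialect (with header)."""
    kind = table_kind if isinstance(table_kind, TableKind) \
        else TableKind(str(table_kind).upper())
    to_row = _ROW_WRITERS[kind]
    lines = ["$".join(TABLE_COLUMNS[kind])]
    lines.extend("$".join(to_row(r)) for r in records)
    return "\n".join(lines) + "\n"


def deduplicate_cases(demo: Sequence[DemoRecord]) -> list[DemoRecord]:
    """Keep one report per case.

    Among records sharing a ``case_id`` the survivor is the highest
    ``case_version``; ties go to the latest ``received_date``, then to the
    lexicographically largest ``report_id``.  The result is sorted by
    ``case_id`` so the output order is deterministic.
    """
    best: dict[str, DemoRecord] = {}
    for rec in demo:
        key = (
            rec.case_version,
            rec.received_date or _dt.date.min,
            rec.report_id,
        )
        cur = best.get(rec.case_id)
        if cur is None:
            best[rec.case_id] = rec
            continue
        cur_key = (cur.case_version, cur.received_date or _dt.date.min, cur.report_id)
        if key > cur_key:
            best[rec.case_id] = rec
    return sorted(best.values(), key=lambda r: r.case_id)
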