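"""Reader/writer for the cohort JSON dialect.

A cohort is a JSON array of patients; each patient is an array of visits;
each visit is an array of token strings.  The gender token canonically sits
first in the first visit, but the reader tolerates (and reports) any
placement, since the cleaning cascade targets exactly such noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .codebook import CodeBook
from .records import Gender, PatientRecord, RawRecord, RawVisit, Visit


class CohortParseError(ValueError):
    """Malformed JSON; carries the byte offset of the failure."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (byte offset {offset})")
        self.offset = offset


class CohortDialectError(ValueError):
    """Well-formed JSON that is not an array-of-patients cohort."""


class SerializationError(ValueError):
    """A record holds a token the code book does not know."""


@dataclass
class ParseReport:
    """Per-record anomalies noticed while reading or extracting."""

    entries: list[tuple[int, str, str]] = field(default_factory=list)

    def add(self, record_index: int, kind: str, detail: str = "") -> None:
        self.entries.append((record_index, kind, detail))

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, kind, _ in self.entries:
            out[kind] = out.get(kind, 0) + 1
        return out

    def to_tsv(self) -> str:
        lines = ["record_index\tanomaly\tdetail"]
        lines += [f"{i}\t{k}\t{d}" for i, k, d in self.entries]
        return "\n".join(lines) + "\n"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_tsv(), encoding="utf-8")


def parse_cohort(
    text: str, codebook: CodeBook
) -> tuple[list[RawRecord], ParseReport]:
    """Parse a cohort document, preserving token order exactly.

    Unknown tokens are retained in the records and flagged in the report.
    """
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise CohortParseError(exc.msg, exc.pos) from exc
    if not isinstance(data, list):
        raise CohortDialectError(
            f"top level must be a JSON array of patients, got {type(data).__name__}")
    report = ParseReport()
    records: list[RawRecord] = []
    for i, patient in enumerate(data):
        if not isinstance(patient, list):
            raise CohortDialectError(f"patient {i} is not an array of visits")
        visits = []
        for j, visit in enumerate(patient):
            if not isinstance(visit, list):
                raise CohortDialectError(
                    f"patient {i} visit {j} is not an array of tokens")
            tokens = [str(t) for t in visit]
            for tok in tokens:
                if codebook.classify(tok) == "unknown":
                    report.add(i, "unknown_token", tok)
            visits.append(RawVisit(tokens))
        records.append(RawRecord(visits))
    return records, report


def extract_patient(
    raw: RawRecord,
    codebook: CodeBook,
    patient_id: int = 0,
    report: ParseReport | None = None,
) -> PatientRecord:
    """Pull gender tokens out of the visits and classify the record's gender.

    Exactly one distinct gender token anywhere in the record gives that
    gender; none gives MISSING; both give CONFLICTING.  Gender tokens found
    outside the first visit are extracted all the same, with a placement
    anomaly logged.  Remaining tokens stay in order, age labels unresolved.
    """
    found: set[str] = set()
    visits: list[Visit] = []
    for j, visit in enumerate(raw.visits):
        kept = []
        for tok in visit.tokens:
            if codebook.is_gender(tok):
                found.add(tok)
                if j != 0 and report is not None:
                    report.add(patient_id, "gender_misplaced", f"visit {j + 1}")
            else:
                kept.append(tok)
        visits.append(Visit(age_label=None, codes=kept))
    if len(found) == 1:
        gender = Gender(codebook.gender_of(found.pop()))
    elif not found:
        gender = Gender.MISSING
    else:
        gender = Gender.CONFLICTING
    return PatientRecord(patient_id=patient_id, gender=gender, visits=visits)


def _visit_tokens(visit: Visit, codebook: CodeBook) -> list[str]:
    tokens = ([visit.age_label] if visit.age_label is not None else []) + list(visit.codes)
    for tok in tokens:
        if codebook.classify(tok) in ("unknown", "gender"):
            raise SerializationError(f"unknown or misplaced token {tok!r}")
    return tokens


def serialize_cohort(patients: list[PatientRecord], codebook: CodeBook) -> str:
    """Write patients back to the JSON dialect, gender first in visit 1."""
    out = []
    for p in patients:
        if p.gender in (Gender.MALE, Gender.FEMALE):
            gender_token = [codebook.gender_codes[p.gender.value]]
        elif p.gender is Gender.MISSING:
            gender_token = []
        else:
            raise SerializationError(
                f"patient {p.patient_id}: conflicting gender is not serializable")
        visits = [_visit_tokens(v, codebook) for v in p.visits]
        if visits:
            visits[0] = gender_token + visits[0]
        elif gender_token:
            visits = [gender_token]
        out.append(visits)
    return json.dumps(out, separators=(",", ":"))


def serialize_raw_cohort(records: list[RawRecord]) -> str:
    """Write raw records (token lists as-is) to the JSON dialect."""
    return json.dumps(
        [[v.tokens for v in r.visits] for r in records], separators=(",", ":"))


def read_cohort(path: str | Path, codebook: CodeBook) -> tuple[list[RawRecord], ParseReport]:
    return parse_cohort(Path(path).read_text(encoding="utf-8"), codebook)


def write_cohort(path: str | Path, patients: list[PatientRecord], codebook: CodeBook) -> None:
    Path(path).write_text(serialize_cohort(patients, codebook), encoding="utf-8")
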