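"""Cleaning cascade: raw trajectories -> canonical diabetes-anchored records.

Rule order (record-level filters, then per-visit normalization, then the
sequence-level passes) follows the source data's documented conventions:

1. drop empty records, records with missing/conflicting gender, gender-only
   records, and records without the diabetes code;
2. null out empty and age-label-only visits, move the age label first and
   sort codes ascending within each visit;
3. compact null visits and keep only the first appearance of each chronic
   code (iterated to a fixpoint, since deduplication can empty a visit);
4. impute missing age labels from the next later visit (the previous one at
   the tail), dropping records with no age label at all;
5. drop records whose first complication-endpoint occurrence precedes the
   first diabetes visit, then drop all pre-diabetes visits and re-compact.

Deduplicating *before* pre-diabetes visits are dropped means a chronic code
seen both before and after diabetes onset disappears entirely: its first
(pre-diabetes) appearance is the one kept, and it leaves with its visit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .codebook import CodeBook
from .records import (Gender, PatientRecord, PreprocessedRecord, RawRecord,
                      Visit)

log = logging.getLogger(__name__)

REMOVAL_RULES = (
    "empty",
    "gender_missing",
    "gender_conflicting",
    "gender_only",
    "no_diabetes",
    "all_ages_missing",
    "endpoint_before_diabetes",
)


@dataclass
class CleanReport:
    """Audit of the cascade: per-rule removal counts and edit counts."""

    records_in: int = 0
    records_out: int = 0
    removed: dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in REMOVAL_RULES})
    visits_nulled: int = 0
    visits_removed: int = 0
    extra_age_labels_dropped: int = 0
    ages_imputed_from_next: int = 0
    ages_imputed_from_prev: int = 0

    def check_conservation(self) -> None:
        total = self.records_out + sum(self.removed.values())
        if total != self.records_in:
            raise AssertionError(
                f"record conservation violated: {self.records_in} in, "
                f"{self.records_out} out + {sum(self.removed.values())} removed")

    def to_tsv(self) -> str:
        lines = ["rule\tcount"]
        lines.append(f"records_in\t{self.records_in}")
        lines.append(f"records_out\t{self.records_out}")
        for rule in REMOVAL_RULES:
            lines.append(f"removed_{rule}\t{self.removed[rule]}")
        lines.append(f"visits_nulled\t{self.visits_nulled}")
        lines.append(f"visits_removed\t{self.visits_removed}")
        lines.append(f"extra_age_labels_dropped\t{self.extra_age_labels_dropped}")
        lines.append(f"ages_imputed_from_next\t{self.ages_imputed_from_next}")
        lines.append(f"ages_imputed_from_prev\t{self.ages_imputed_from_prev}")
        return "\n".join(lines) + "\n"


def clean_record_level(
    patients: list[PatientRecord], codebook: CodeBook,
    report: CleanReport | None = None,
) -> tuple[list[PatientRecord], CleanReport]:
    """Record-level filters, applied in order.

    A record is *empty* when it holds no tokens at all, *gender-only* when
    its only content was the gender token, and *no-diabetes* when the
    diabetes code never appears.
    """
    report = report or CleanReport(records_in=len(patients))
    kept: list[PatientRecord] = []
    for p in patients:
        has_tokens = any(v.codes or v.age_label for v in p.visits)
        if not p.visits and p.gender is Gender.MISSING:
            report.removed["empty"] += 1
            continue
        if p.gender is Gender.MISSING:
            report.removed["gender_missing"] += 1
            continue
        if p.gender is Gender.CONFLICTING:
            report.removed["gender_conflicting"] += 1
            continue
        if not has_tokens:
            report.removed["gender_only"] += 1
            continue
        if not any(codebook.diabetes_code in v.codes for v in p.visits):
            report.removed["no_diabetes"] += 1
            continue
        kept.append(p)
    return kept, report


def normalize_visit(
    visit: Visit, codebook: CodeBook, report: CleanReport | None = None
) -> Visit | None:
    """Resolve a visit's age label and sort its codes; None marks a null visit.

    Empty visits and visits holding only an age label are nulled.  The first
    age token found anywhere becomes the visit's label (extra age labels are
    dropped with a warning); the remaining tokens are sorted ascending by
    integer value.
    """
    tokens = ([visit.age_label] if visit.age_label else []) + list(visit.codes)
    age_label: str | None = None
    codes: list[str] = []
    for tok in tokens:
        if codebook.is_age(tok):
            if age_label is None:
                age_label = tok
            else:
                if report is not None:
                    report.extra_age_labels_dropped += 1
                log.warning("extra age label %s dropped", tok)
        else:
            codes.append(tok)
    if not codes:
        if report is not None:
            report.visits_nulled += 1
        return None
    codes.sort(key=int)
    return Visit(age_label=age_label, codes=codes)


def compact_and_dedup(
    visits: list[Visit | None], report: CleanReport | None = None
) -> list[Visit]:
    """Drop null visits, keep each code's first appearance, iterate to fixpoint.

    Visits emptied by deduplication become null and are compacted in the next
    pass; indices are implicitly reassigned by list position.
    """
    current = list(visits)
    while True:
        compacted = [v for v in current if v is not None]
        if report is not None:
            report.visits_removed += len(current) - len(compacted)
        seen: set[str] = set()
        deduped: list[Visit | None] = []
        changed = False
        for v in compacted:
            codes = [c for c in v.codes if c not in seen]
            seen.update(codes)
            if codes != v.codes:
                changed = True
            deduped.append(Visit(v.age_label, codes) if codes else None)
            if not codes:
                changed = True
        if not changed:
            return [v for v in deduped if v is not None]
        current = deduped


def impute_age_labels(
    visits: list[Visit], report: CleanReport | None = None
) -> list[Visit] | None:
    """Fill missing age labels from the next later visit, or the previous one
    at the tail; None when every label is missing (record removal)."""
    labels = [v.age_label for v in visits]
    if all(lab is None for lab in labels):
        return None
    out = [v.copy() for v in visits]
    # backward pass: take the next available later label
    next_label: str | None = None
    for i in range(len(out) - 1, -1, -1):
        if out[i].age_label is None and next_label is not None:
            out[i].age_label = next_label
            if report is not None:
                report.ages_imputed_from_next += 1
        elif out[i].age_label is not None:
            next_label = out[i].age_label
    # forward pass: a missing tail takes the previous label
    prev_label: str | None = None
    for v in out:
        if v.age_label is None and prev_label is not None:
            v.age_label = prev_label
            if report is not None:
                report.ages_imputed_from_prev += 1
        elif v.age_label is not None:
            prev_label = v.age_label
    return out


def anchor_to_diabetes(
    visits: list[Visit], codebook: CodeBook
) -> list[Visit] | None:
    """Drop pre-diabetes visits; None when an endpoint precedes diabetes.

    The diabetes visit becomes visit 1.  A record whose first occurrence of
    any complication endpoint lies strictly before the first diabetes visit
    is excluded outright (the complication predates the disease).
    """
    dia = next(
        (i for i, v in enumerate(visits) if codebook.diabetes_code in v.codes), None)
    if dia is None:
        raise ValueError("record reached anchoring without a diabetes code")
    for ep in codebook.endpoint_codes:
        first = next((i for i, v in enumerate(visits) if ep in v.codes), None)
        if first is not None and first < dia:
            return None
    return visits[dia:]


def preprocess_cohort(
    cohort: list[RawRecord] | list[PatientRecord],
    codebook: CodeBook,
    strict: bool = False,
) -> tuple[list[PreprocessedRecord], CleanReport]:
    """Run the full cascade; returns cleaned records plus the audit report.

    Accepts either raw records (gender extraction is performed here) or
    already-extracted patient records.  With ``strict`` every output record
    is validated against the cleaned-record invariants.
    """
    from .io import extract_patient

    if cohort and isinstance(cohort[0], RawRecord):
        patients = [extract_patient(r, codebook, patient_id=i)
                    for i, r in enumerate(cohort)]
    else:
        patients = list(cohort)  # type: ignore[arg-type]

    report = CleanReport(records_in=len(patients))
    kept, report = clean_record_level(patients, codebook, report)

    out: list[PreprocessedRecord] = []
    for p in kept:
        normalized = [normalize_visit(v, codebook, report) for v in p.visits]
        visits = compact_and_dedup(normalized, report)
        imputed = impute_age_labels(visits, report)
        if imputed is None:
            report.removed["all_ages_missing"] += 1
            continue
        anchored = anchor_to_diabetes(imputed, codebook)
        if anchored is None:
            report.removed["endpoint_before_diabetes"] += 1
            continue
        report.visits_removed += len(imputed) - len(anchored)
        final = compact_and_dedup(anchored, report)
        rec = PreprocessedRecord(p.patient_id, p.gender, final)
        if strict:
            rec.validate(codebook)
        out.append(rec)
    report.records_out = len(out)
    report.check_conservation()
    return out, report
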