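"""In-memory containers for raw and cleaned patient visit trajectories."""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .codebook import CodeBook


class Gender(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    MISSING = "missing"
    CONFLICTING = "conflicting"


@dataclass
class RawVisit:
    """One visit exactly as parsed: an ordered token list, possibly empty."""

    tokens: list[str] = field(default_factory=list)


@dataclass
class RawRecord:
    """One patient's visits in input order, before any interpretation."""

    visits: list[RawVisit] = field(default_factory=list)

    def all_tokens(self) -> list[str]:
        return [t for v in self.visits for t in v.tokens]


@dataclass
class Visit:
    """A visit after gender extraction: an optional age label plus codes.

    Before per-visit normalization ``age_label`` is None and ``codes`` holds
    the remaining tokens in original order (age labels may still be mixed in).
    After normalization ``codes`` contains only diagnosis tokens, sorted
    ascending by integer value.
    """

    age_label: str | None = None
    codes: list[str] = field(default_factory=list)

    def copy(self) -> "Visit":
        return Visit(self.age_label, list(self.codes))


@dataclass
class PatientRecord:
    """Record-level gender plus the ordered visit sequence."""

    patient_id: int
    gender: Gender
    visits: list[Visit] = field(default_factory=list)


class InvariantError(AssertionError):
    """A cleaned record violates one of its structural invariants."""


@dataclass
class PreprocessedRecord:
    """A fully cleaned trajectory, anchored so the diabetes visit is visit 1.

    Every visit carries a resolved age label and a non-empty ascending code
    list; each chronic code appears in exactly one visit; age labels are
    non-decreasing along the sequence.
    """

    patient_id: int
    gender: Gender
    visits: list[Visit] = field(default_factory=list)

    def validate(self, codebook: CodeBook) -> None:
        """Assert every structural invariant; raise InvariantError otherwise."""
        if self.gender not in (Gender.MALE, Gender.FEMALE):
            raise InvariantError(f"patient {self.patient_id}: gender {self.gender}")
        if not self.visits:
            raise InvariantError(f"patient {self.patient_id}: no visits")
        seen: set[str] = set()
        prev_age = None
        for i, visit in enumerate(self.visits):
            if visit.age_label not in codebook.age_labels:
                raise InvariantError(
                    f"patient {self.patient_id} visit {i + 1}: bad age label")
            if not visit.codes:
                raise InvariantError(
                    f"patient {self.patient_id} visit {i + 1}: empty code list")
            ints = [int(c) for c in visit.codes]
            if ints != sorted(ints):
                raise InvariantError(
                    f"patient {self.patient_id} visit {i + 1}: codes not ascending")
            for code in visit.codes:
                if code in seen:
                    raise InvariantError(
                        f"patient {self.patient_id}: code {code} repeated")
                seen.add(code)
            if codebook.diabetes_code in visit.codes and i != 0:
                raise InvariantError(
                    f"patient {self.patient_id}: diabetes code after visit 1")
            if prev_age is not None and int(visit.age_label) < prev_age:
                raise InvariantError(
                    f"patient {self.patient_id}: age labels decrease at visit {i + 1}")
            prev_age = int(visit.age_label)
        if codebook.diabetes_code not in self.visits[0].codes:
            raise InvariantError(
                f"patient {self.patient_id}: visit 1 lacks the diabetes code")

    def pairs(self) -> list[tuple[str, str]]:
        """All (age label, code) pairs of the trajectory, in visit order."""
        return [(v.age_label, c) for v in self.visits for c in v.codes]
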