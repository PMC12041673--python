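"""Token code book for the coded visit-trajectory dialect.

Cohorts are sequences of integer-coded string tokens: a gender token in the
first visit ("1111" male / "2222" female), a decade-of-life age-range label
per visit ("1000" = <10 through "1090" = >90), and one or more chronic
ICD-9-derived diagnosis codes per visit.  Diabetes is "401"; the four
complication endpoints are retinopathy "703", chronic kidney disease "1401",
ischemic heart disease "910" and amputation "1999".
"""

from __future__ import annotations

from dataclasses import dataclass, field

MALE_TOKEN = "1111"
FEMALE_TOKEN = "2222"
DIABETES_CODE = "401"
ENDPOINT_CODES = ("703", "910", "1401", "1999")

AGE_LABELS = tuple(str(1000 + 10 * i) for i in range(10))

AGE_RANGE_NAMES = {
    "1000": "<10", "1010": "10-20", "1020": "20-30", "1030": "30-40",
    "1040": "40-50", "1050": "50-60", "1060": "60-70", "1070": "70-80",
    "1080": "80-90", "1090": ">90",
}

# Codes with a published clinical meaning; the rest of the default 83-code
# vocabulary is synthetic filler standing in for the unnamed chronic codes.
NAMED_CODES = {
    "401": "Diabetes",
    "402": "Hyperlipidaemia",
    "503": "Tobacco dependence",
    "507": "Anxiety disorder",
    "604": "Motor disorders with no CVA",
    "703": "Retinopathy",
    "906": "Extremity arteriopathy diseases",
    "910": "Ischemic heart disease",
    "913": "Hypertension",
    "914": "Heart failure",
    "1302": "Arthrosis/spondylosis",
    "1401": "Chronic kidney disease",
    "1999": "Amputation",
}


class CodeBookError(ValueError):
    """Raised when a code book violates its structural invariants."""


@dataclass(frozen=True)
class CodeBook:
    """Declares which tokens are genders, age labels and diagnosis codes.

    The three token classes must be pairwise disjoint, the age vocabulary
    must hold exactly ten strictly increasing labels, and the diabetes and
    endpoint codes must be members of ``diagnosis_codes``.
    """

    gender_codes: dict[str, str] = field(
        default_factory=lambda: {"male": MALE_TOKEN, "female": FEMALE_TOKEN})
    age_labels: tuple[str, ...] = AGE_LABELS
    diabetes_code: str = DIABETES_CODE
    endpoint_codes: tuple[str, ...] = ENDPOINT_CODES
    diagnosis_codes: frozenset[str] = frozenset()
    display_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.age_labels) != 10:
            raise CodeBookError("age_labels must have exactly 10 entries")
        ints = [int(a) for a in self.age_labels]
        if ints != sorted(ints) or len(set(ints)) != 10:
            raise CodeBookError("age_labels must be strictly increasing")
        genders = set(self.gender_codes.values())
        ages = set(self.age_labels)
        diags = set(self.diagnosis_codes)
        if genders & ages or genders & diags or ages & diags:
            raise CodeBookError("gender, age and diagnosis tokens must be disjoint")
        missing = ({self.diabetes_code} | set(self.endpoint_codes)) - diags
        if missing:
            raise CodeBookError(f"codes {sorted(missing)} absent from diagnosis_codes")

    # --- token classification -------------------------------------------------

    def is_gender(self, token: str) -> bool:
        return token in self.gender_codes.values()

    def is_age(self, token: str) -> bool:
        return token in self.age_labels

    def is_diagnosis(self, token: str) -> bool:
        return token in self.diagnosis_codes

    def classify(self, token: str) -> str:
        """Return one of 'gender', 'age', 'diagnosis', 'unknown'."""
        if self.is_gender(token):
            return "gender"
        if self.is_age(token):
            return "age"
        if self.is_diagnosis(token):
            return "diagnosis"
        return "unknown"

    def gender_of(self, token: str) -> str:
        for name, tok in self.gender_codes.items():
            if tok == token:
                return name
        raise KeyError(token)

    def display_name(self, code: str) -> str:
        return self.display_names.get(code, code)

    def age_range_name(self, label: str) -> str:
        return AGE_RANGE_NAMES.get(label, label)


def _filler_codes(needed: int, taken: set[str]) -> list[str]:
    """Deterministic synthetic chronic-code tokens avoiding reserved ranges."""
    out: list[str] = []
    for base in (400, 500, 600, 900, 1300, 1400):
        for v in range(base, base + 100):
            tok = str(v)
            if tok in taken or tok in out:
                continue
            out.append(tok)
            if len(out) == needed:
                return out
    raise RuntimeError("ran out of filler code space")  # pragma: no cover


def default_codebook(n_codes: int = 83) -> CodeBook:
    """Default 83-code chronic-disease vocabulary.

    The named codes (diabetes, the four endpoints, and the comorbidities with
    published meanings) are included verbatim; synthetic filler codes pad the
    vocabulary to ``n_codes`` distinct diagnosis tokens.
    """
    named = list(NAMED_CODES)
    if n_codes < len(named):
        raise CodeBookError(f"n_codes must be >= {len(named)}")
    reserved = set(AGE_LABELS) | {MALE_TOKEN, FEMALE_TOKEN} | set(named)
    codes = named + _filler_codes(n_codes - len(named), reserved)
    return CodeBook(
        diagnosis_codes=frozenset(codes),
        display_names=dict(NAMED_CODES),
    )
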