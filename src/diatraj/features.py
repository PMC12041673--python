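"""Visit-order-weighted pair encoding, Bag-of-Features baseline, DF tables.

The proposed encoding maps each instance window to a (k + 2)-vector: one
slot per distinct (age label, code) pair observed in the dataset, holding
the 1-based index of the visit where the pair occurs (0 when absent) so
later visits get larger raw weights, plus two gender indicator slots.
Raw weights are min-max scaled per column to [0, 1] on designated fit rows
only; columns constant on fit rows map to 0 and applied values are clipped.

The Bag-of-Features baseline drops the age pairing and the temporal weight:
individual codes, age labels and gender become independent count features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codebook import CodeBook
from .endpoints import EndpointDataset, LabeledInstance
from .records import Gender

Pair = tuple[str, str]


class VocabularyError(KeyError):
    """An instance holds a pair absent from the fitted vocabulary."""


@dataclass
class FeatureVocabulary:
    """Ordered pair vocabulary plus the two gender slots (dim = k + 2)."""

    pairs: list[Pair]
    index: dict[Pair, int] = field(init=False)

    def __post_init__(self) -> None:
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("vocabulary pairs must be unique")
        self.index = {p: i for i, p in enumerate(self.pairs)}

    @property
    def k(self) -> int:
        return len(self.pairs)

    @property
    def total_dim(self) -> int:
        return self.k + 2

    def column_names(self) -> list[str]:
        return [f"{a}:{c}" for a, c in self.pairs] + ["gender:male", "gender:female"]

    @classmethod
    def from_dataset(cls, dataset: EndpointDataset) -> "FeatureVocabulary":
        pairs = {p for inst in dataset.instances for p in inst.pairs()}
        return cls(sorted(pairs, key=lambda p: (int(p[0]), int(p[1]))))


def vectorize_instance(
    instance: LabeledInstance, vocab: FeatureVocabulary
) -> np.ndarray:
    """Raw weight vector: pair slot = 1-based visit index, gender one-hot.

    Codes are deduplicated upstream, so each pair occurs in at most one
    visit and the slot value is well defined.
    """
    vec = np.zeros(vocab.total_dim)
    for visit_idx, visit in enumerate(instance.input_visits, start=1):
        for code in visit.codes:
            pair = (visit.age_label, code)
            try:
                vec[vocab.index[pair]] = visit_idx
            except KeyError:
                raise VocabularyError(
                    f"pair {pair} not in vocabulary") from None
    vec[vocab.k + (0 if instance.gender is Gender.MALE else 1)] = 1.0
    return vec


def vectorize_dataset(
    dataset: EndpointDataset, vocab: FeatureVocabulary
) -> np.ndarray:
    return np.vstack([vectorize_instance(i, vocab) for i in dataset.instances])


@dataclass
class MinMaxNormalizer:
    """Per-column min-max scaling fitted on an explicit row subset."""

    col_min: np.ndarray | None = None
    col_max: np.ndarray | None = None
    fit_row_ids: np.ndarray | None = None

    def fit(self, X: np.ndarray, fit_rows: np.ndarray) -> "MinMaxNormalizer":
        rows = np.asarray(fit_rows)
        if rows.size == 0:
            raise ValueError("fit rows must be non-empty")
        sub = X[rows]
        self.col_min = sub.min(axis=0)
        self.col_max = sub.max(axis=0)
        self.fit_row_ids = rows.copy()
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.col_min is None:
            raise RuntimeError("normalizer not fitted")
        span = self.col_max - self.col_min
        out = np.zeros_like(X, dtype=float)
        nz = span > 0
        out[:, nz] = (X[:, nz] - self.col_min[nz]) / span[nz]
        return np.clip(out, 0.0, 1.0)


@dataclass
class FeatureMatrix:
    """Normalized instance-by-feature matrix with its fit provenance."""

    values: np.ndarray
    columns: list[str]
    row_ids: list[int]
    normalizer: MinMaxNormalizer

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.columns, index=self.row_ids)

    def to_tsv(self) -> str:
        return self.to_frame().to_csv(sep="\t", index_label="instance",
                                      float_format="%.6f")


def fit_apply_minmax(
    X: np.ndarray,
    fit_rows: np.ndarray,
    columns: list[str] | None = None,
    row_ids: list[int] | None = None,
) -> FeatureMatrix:
    """Fit min-max on ``fit_rows`` and apply to all rows of ``X``."""
    norm = MinMaxNormalizer().fit(X, fit_rows)
    values = norm.transform(X)
    n, d = X.shape
    return FeatureMatrix(
        values=values,
        columns=columns or [f"f{i}" for i in range(d)],
        row_ids=row_ids or list(range(n)),
        normalizer=norm,
    )


# --- Bag-of-Features baseline -------------------------------------------------


@dataclass
class BofVocabulary:
    """Individual codes, individual age labels, plus the two gender slots."""

    codes: list[str]
    age_labels: list[str]

    @property
    def total_dim(self) -> int:
        return len(self.codes) + len(self.age_labels) + 2

    def column_names(self) -> list[str]:
        return ([f"code:{c}" for c in self.codes]
                + [f"age:{a}" for a in self.age_labels]
                + ["gender:male", "gender:female"])

    @classmethod
    def from_dataset(cls, dataset: EndpointDataset) -> "BofVocabulary":
        codes: set[str] = set()
        ages: set[str] = set()
        for inst in dataset.instances:
            for v in inst.input_visits:
                ages.add(v.age_label)
                codes.update(v.codes)
        return cls(sorted(codes, key=int), sorted(ages, key=int))


def encode_bof(instance: LabeledInstance, vocab: BofVocabulary) -> np.ndarray:
    """Occurrence counts: age labels once per visit bearing them, codes at
    most once (deduplicated upstream), gender as indicators."""
    vec = np.zeros(vocab.total_dim)
    code_idx = {c: i for i, c in enumerate(vocab.codes)}
    age_idx = {a: len(vocab.codes) + i for i, a in enumerate(vocab.age_labels)}
    for visit in instance.input_visits:
        if visit.age_label in age_idx:
            vec[age_idx[visit.age_label]] += 1
        for code in visit.codes:
            if code in code_idx:
                vec[code_idx[code]] += 1
    base = len(vocab.codes) + len(vocab.age_labels)
    vec[base + (0 if instance.gender is Gender.MALE else 1)] = 1.0
    return vec


def encode_bof_dataset(dataset: EndpointDataset, vocab: BofVocabulary) -> np.ndarray:
    return np.vstack([encode_bof(i, vocab) for i in dataset.instances])


# --- document frequency -------------------------------------------------------


def document_frequency(
    dataset: EndpointDataset,
    codebook: CodeBook,
    top_n: int = 10,
) -> pd.DataFrame:
    """Top pairs by positive-class document frequency.

    DF% of a pair = share of positive instances whose window contains it.
    Diabetes-code pairs are excluded (the code is present in every record by
    construction).  Ties break by (age label, code) numeric order.
    """
    positives = [i for i in dataset.instances if i.label == 1]
    if not positives:
        raise ValueError("dataset has no positive instances")
    counts: dict[Pair, int] = {}
    for inst in positives:
        for pair in set(inst.pairs()):
            if pair[1] == codebook.diabetes_code:
                continue
            counts[pair] = counts.get(pair, 0) + 1
    rows = sorted(
        ((a, c, 100.0 * n / len(positives)) for (a, c), n in counts.items()),
        key=lambda r: (-r[2], int(r[0]), int(r[1])),
    )[:top_n]
    return pd.DataFrame(rows, columns=["age_range", "code", "df_pct"])
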