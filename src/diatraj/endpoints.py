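"""Per-endpoint balanced binary datasets with leakage-avoiding windowing.

For each complication endpoint, a cleaned trajectory becomes a labeled
instance: positives keep the visits strictly before the endpoint's visit
(the whole endpoint-bearing visit is future information and is dropped);
negatives keep all visits except the last, so both classes end one visit
short of the information that decided their label.  Endpoints at the first
visit, and negatives with a single visit, are excluded.  Class balance is
restored by seeded uniform downsampling of negatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codebook import CodeBook
from .records import Gender, PreprocessedRecord, Visit
from .simulate import summary_stats


@dataclass
class LabeledInstance:
    patient_id: int
    gender: Gender
    input_visits: list[Visit]
    label: int  # 1 positive, 0 negative
    endpoint: str

    def pairs(self) -> list[tuple[str, str]]:
        return [(v.age_label, c) for v in self.input_visits for c in v.codes]


@dataclass
class Exclusion:
    patient_id: int
    reason: str  # endpoint_at_first_visit | window_too_short


@dataclass
class EndpointDataset:
    endpoint: str
    instances: list[LabeledInstance]
    balance_seed: int
    eligible_positives: int
    eligible_negatives: int
    sampled_negatives: int

    @property
    def n_positive(self) -> int:
        return sum(i.label == 1 for i in self.instances)

    @property
    def n_negative(self) -> int:
        return sum(i.label == 0 for i in self.instances)

    def labels(self) -> np.ndarray:
        return np.asarray([i.label for i in self.instances], dtype=int)


def label_for_endpoint(
    record: PreprocessedRecord, endpoint: str, min_gap_visits: int = 1
) -> LabeledInstance | Exclusion:
    """Window one record for one endpoint.

    Positive: endpoint first occurs at visit e >= 2, window = visits 1..e-1,
    requiring at least ``min_gap_visits`` visits between diabetes onset and
    the complication.  Negative: endpoint absent, window = all visits but the
    last, excluded when only one visit exists.
    """
    first = next(
        (i for i, v in enumerate(record.visits) if endpoint in v.codes), None)
    if first is not None:
        if first == 0:
            return Exclusion(record.patient_id, "endpoint_at_first_visit")
        window = record.visits[:first]
        if len(window) < min_gap_visits:
            return Exclusion(record.patient_id, "window_too_short")
        return LabeledInstance(record.patient_id, record.gender,
                               [v.copy() for v in window], 1, endpoint)
    window = record.visits[:-1]
    if len(window) < max(1, min_gap_visits):
        return Exclusion(record.patient_id, "window_too_short")
    return LabeledInstance(record.patient_id, record.gender,
                           [v.copy() for v in window], 0, endpoint)


def balance_downsample(
    instances: list[LabeledInstance], seed: int, endpoint: str | None = None
) -> EndpointDataset:
    """Keep all positives; sample an equal number of negatives without
    replacement; shuffle deterministically under ``seed``."""
    positives = [i for i in instances if i.label == 1]
    negatives = [i for i in instances if i.label == 0]
    if not positives:
        raise ValueError("cannot balance a dataset with zero positives")
    if len(negatives) < len(positives):
        raise ValueError(
            f"fewer negatives ({len(negatives)}) than positives ({len(positives)})")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(negatives), size=len(positives), replace=False)
    sampled = [negatives[i] for i in sorted(idx)]
    combined = positives + sampled
    order = rng.permutation(len(combined))
    ep = endpoint or positives[0].endpoint
    return EndpointDataset(
        endpoint=ep,
        instances=[combined[i] for i in order],
        balance_seed=seed,
        eligible_positives=len(positives),
        eligible_negatives=len(negatives),
        sampled_negatives=len(sampled),
    )


def build_endpoint_dataset(
    records: list[PreprocessedRecord],
    endpoint: str,
    seed: int,
    min_gap_visits: int = 1,
) -> tuple[EndpointDataset, list[Exclusion]]:
    """Label every record for ``endpoint`` and balance by downsampling."""
    instances: list[LabeledInstance] = []
    exclusions: list[Exclusion] = []
    for rec in records:
        out = label_for_endpoint(rec, endpoint, min_gap_visits)
        if isinstance(out, Exclusion):
            exclusions.append(out)
        else:
            instances.append(out)
    return balance_downsample(instances, seed, endpoint), exclusions


def endpoint_stats(
    groups: dict[str, list[PreprocessedRecord] | list[LabeledInstance]],
) -> pd.DataFrame:
    """Per-group trajectory statistics in the cohort-table layout.

    Each column is one group (e.g. one endpoint's positive class); rows are
    patient counts, visits-per-patient moments, unique code and pair counts,
    and the per-patient maximum of distinct pairs.
    """
    table: dict[str, dict[str, float]] = {}
    for name, items in groups.items():
        visit_lists = [
            getattr(it, "input_visits", None) or getattr(it, "visits")
            for it in items
        ]
        counts = [len(vs) for vs in visit_lists]
        stats = summary_stats(counts) if counts else {}
        codes: set[str] = set()
        pairs: set[tuple[str, str]] = set()
        max_pairs = 0
        for vs in visit_lists:
            ppairs = {(v.age_label, c) for v in vs for c in v.codes}
            pairs |= ppairs
            codes |= {c for _, c in ppairs}
            max_pairs = max(max_pairs, len(ppairs))
        col = {"n_patients": float(len(items))}
        col.update({f"visits_{k}": v for k, v in stats.items()})
        col.update({
            "unique_codes": float(len(codes)),
            "unique_pairs": float(len(pairs)),
            "max_pairs_per_patient": float(max_pairs),
        })
        table[name] = col
    return pd.DataFrame(table)


def serialize_dataset(dataset: EndpointDataset) -> dict:
    """JSON-ready form of a balanced dataset (windows, labels, provenance)."""
    return {
        "endpoint": dataset.endpoint,
        "balance_seed": dataset.balance_seed,
        "eligible_positives": dataset.eligible_positives,
        "eligible_negatives": dataset.eligible_negatives,
        "sampled_negatives": dataset.sampled_negatives,
        "instances": [
            {
                "patient_id": i.patient_id,
                "gender": i.gender.value,
                "label": i.label,
                "visits": [[v.age_label] + v.codes for v in i.input_visits],
            }
            for i in dataset.instances
        ],
    }


def deserialize_dataset(data: dict, codebook: CodeBook) -> EndpointDataset:
    instances = [
        LabeledInstance(
            patient_id=d["patient_id"],
            gender=Gender(d["gender"]),
            input_visits=[Visit(v[0], list(v[1:])) for v in d["visits"]],
            label=int(d["label"]),
            endpoint=data["endpoint"],
        )
        for d in data["instances"]
    ]
    return EndpointDataset(
        endpoint=data["endpoint"],
        instances=instances,
        balance_seed=data["balance_seed"],
        eligible_positives=data["eligible_positives"],
        eligible_negatives=data["eligible_negatives"],
        sampled_negatives=data["sampled_negatives"],
    )
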