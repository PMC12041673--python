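"""Synthetic cohort generator with planted (age, code) -> endpoint risk.

Emulates the coded visit-trajectory dialect: per patient a gender token in
the first visit, a decade age label per visit, chronic diagnosis codes
sampled from an age-dependent prevalence table, diabetes ("401") at the
onset visit, and complication endpoints emitted by a per-visit logistic
hazard on the set of (age label, code) pairs accumulated in *prior* visits.
Pairs are therefore the Bayes-relevant predictors by construction, which is
what makes downstream feature-recovery tests meaningful.

Structural noise (the anomalies the cleaning cascade targets) is injected
after clean generation and recorded per patient in the ground truth, so the
cleaning report can be audited exactly.  Record-removing anomalies are
mutually exclusive per patient; benign anomalies are drawn independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import kurtosis, skew

from .codebook import CodeBook, default_codebook
from .records import RawRecord, RawVisit

REMOVAL_NOISE = (
    "gender_missing",
    "gender_conflicting",
    "gender_only_record",
    "no_diabetes_record",
    "endpoint_before_diabetes",
)
BENIGN_NOISE = (
    "pre_diabetes_visits",
    "empty_visit",
    "age_only_visit",
    "missing_age_label",
    "misplaced_age_label",
    "duplicate_chronic_code",
)
NOISE_KINDS = REMOVAL_NOISE + BENIGN_NOISE

Pair = tuple[str, str]


@dataclass
class EndpointHazard:
    """Per-visit log-odds model: intercept + sum of coefficients over the
    accumulated (age label, code) exposure pairs present in prior visits."""

    intercept: float
    coefficients: dict[Pair, float] = field(default_factory=dict)


@dataclass
class SimConfig:
    n_patients: int = 1000
    seed: int = 0
    gender_mix: float = 0.5  # probability of male
    max_visits: int = 11
    visit_count_law: dict[int, float] | None = None
    start_age_law: dict[str, float] | None = None
    age_advance_prob: float = 0.35
    code_prevalence: dict[Pair, float] | None = None
    endpoint_hazard: dict[str, EndpointHazard] | None = None
    noise_rates: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0.0 <= self.gender_mix <= 1.0:
            raise ValueError("gender_mix must be a probability")
        for kind, rate in self.noise_rates.items():
            if kind not in NOISE_KINDS:
                raise ValueError(f"unknown noise kind {kind!r}")
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"noise rate for {kind} must be in [0,1]")
        if sum(self.noise_rates.get(k, 0.0) for k in REMOVAL_NOISE) > 1.0:
            raise ValueError("removal-class noise rates must sum to <= 1")
        if self.endpoint_hazard:
            for ep, hz in self.endpoint_hazard.items():
                if not np.isfinite(list(hz.coefficients.values()) or [0.0]).all():
                    raise ValueError(f"non-finite coefficient for endpoint {ep}")


@dataclass
class GroundTruth:
    """What the generator planted: risk structure, outcomes and anomalies."""

    risk_pairs: dict[str, dict[Pair, float]] = field(default_factory=dict)
    endpoint_visit: dict[int, dict[str, int]] = field(default_factory=dict)
    anomalies: dict[str, list[int]] = field(default_factory=dict)

    def anomaly_counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.anomalies.items()}


# --- defaults ----------------------------------------------------------------

# Chronic-disease archetypes whose prevalence rises with age; the named ones
# mirror the comorbidities most often co-reported with diabetes complications
# (hypertension, hyperlipidaemia, heart failure, arthrosis, ...).
ARCHETYPE_CODES = ("400", "402", "403", "503", "507", "604", "906", "913", "914", "1302")


def default_visit_count_law(max_visits: int = 11) -> dict[int, float]:
    """Truncated geometric-like visit-count law, mean about 3 visits."""
    p = 0.33
    weights = {k: p * (1 - p) ** (k - 1) for k in range(1, max_visits + 1)}
    total = sum(weights.values())
    return {k: w / total for k, w in weights.items()}


def default_start_age_law(codebook: CodeBook) -> dict[str, float]:
    """Onset-age law concentrated in the 40-80 decades."""
    weights = [0.5, 0.5, 1, 2, 6, 12, 14, 10, 4, 1]
    total = sum(weights)
    return {a: w / total for a, w in zip(codebook.age_labels, weights)}


def default_code_prevalence(codebook: CodeBook) -> dict[Pair, float]:
    """Per-visit inclusion probability for each (age label, code) pair.

    Archetype chronic codes climb with age; the remaining filler codes keep a
    small flat background rate so the full 83-code vocabulary is exercised.
    """
    prevalence: dict[Pair, float] = {}
    excluded = {codebook.diabetes_code} | set(codebook.endpoint_codes)
    for code in sorted(codebook.diagnosis_codes, key=int):
        if code in excluded:
            continue
        base = 0.07 if code in ARCHETYPE_CODES else 0.008
        for idx, age in enumerate(codebook.age_labels):
            p = base * (1 + 0.35 * idx) if code in ARCHETYPE_CODES else base
            prevalence[(age, code)] = min(p, 0.5)
    return prevalence


def default_endpoint_hazard(codebook: CodeBook) -> dict[str, EndpointHazard]:
    """Ten planted risk pairs per endpoint on late-decade archetype pairs."""
    risk_codes = {
        "910": ("913", "402", "1302", "914"),
        "1401": ("913", "914", "507", "402"),
        "703": ("402", "507", "913", "1302"),
        "1999": ("604", "906", "503", "913"),
    }
    ages = ("1050", "1060", "1070")
    hazards: dict[str, EndpointHazard] = {}
    for ep in codebook.endpoint_codes:
        codes = risk_codes[ep]
        pairs: dict[Pair, float] = {}
        for age in ages:
            for code in codes:
                if len(pairs) >= 10:
                    break
                pairs[(age, code)] = 2.0
        hazards[ep] = EndpointHazard(intercept=-5.0, coefficients=pairs)
    return hazards


# --- generation ---------------------------------------------------------------


def _sample_law(rng: np.random.Generator, law: dict, n: int) -> list:
    keys = list(law)
    probs = np.asarray([law[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    idx = rng.choice(len(keys), size=n, p=probs)
    return [keys[i] for i in idx]


def generate_cohort(
    config: SimConfig, codebook: CodeBook | None = None
) -> tuple[list[RawRecord], GroundTruth]:
    """Generate a cohort in the raw JSON dialect plus its ground truth.

    Deterministic given ``config.seed``: the same configuration produces a
    byte-identical serialized cohort on every run.
    """
    config.validate()
    cb = codebook or default_codebook()
    rng = np.random.default_rng(config.seed)

    visit_law = config.visit_count_law or default_visit_count_law(config.max_visits)
    if max(visit_law) > config.max_visits:
        raise ValueError("visit_count_law exceeds max_visits")
    age_law = config.start_age_law or default_start_age_law(cb)
    prevalence = (config.code_prevalence if config.code_prevalence is not None
                  else default_code_prevalence(cb))
    hazards = (config.endpoint_hazard if config.endpoint_hazard is not None
               else default_endpoint_hazard(cb))

    sampled_codes = sorted(
        {c for (_, c) in prevalence}, key=int)
    prev_by_age = {
        age: np.asarray([prevalence.get((age, c), 0.0) for c in sampled_codes])
        for age in cb.age_labels
    }
    endpoints = sorted(hazards, key=int)

    truth = GroundTruth(
        risk_pairs={ep: dict(hazards[ep].coefficients) for ep in endpoints},
        anomalies={k: [] for k in NOISE_KINDS},
    )

    records: list[RawRecord] = []
    for pid in range(config.n_patients):
        male = rng.random() < config.gender_mix
        gender_token = cb.gender_codes["male" if male else "female"]
        n_visits = _sample_law(rng, visit_law, 1)[0]
        start_age = _sample_law(rng, age_law, 1)[0]

        # age path: non-decreasing decade labels
        ages = []
        age_idx = cb.age_labels.index(start_age)
        for _ in range(n_visits):
            ages.append(cb.age_labels[age_idx])
            if age_idx < 9 and rng.random() < config.age_advance_prob:
                age_idx += 1

        # chronic codes per visit
        visit_codes: list[list[str]] = []
        for v in range(n_visits):
            probs = prev_by_age[ages[v]]
            mask = rng.random(len(sampled_codes)) < probs
            codes = [c for c, m in zip(sampled_codes, mask) if m]
            if not codes and probs.sum() > 0:
                codes = [sampled_codes[rng.choice(len(sampled_codes),
                                                  p=probs / probs.sum())]]
            visit_codes.append(codes)
        visit_codes[0].append(cb.diabetes_code)

        # endpoint hazard draws from visit 2 on, exposure = prior visits' pairs
        occurred: dict[str, int] = {}
        exposure: set[Pair] = set()
        for v in range(1, n_visits):
            exposure.update((ages[v - 1], c) for c in visit_codes[v - 1])
            for ep in endpoints:
                if ep in occurred:
                    continue
                hz = hazards[ep]
                logit = hz.intercept + sum(
                    coef for pair, coef in hz.coefficients.items() if pair in exposure)
                if rng.random() < expit(logit):
                    visit_codes[v].append(ep)
                    occurred[ep] = v + 1  # 1-based visit index
        if occurred:
            truth.endpoint_visit[pid] = occurred

        visits = [[ages[v]] + sorted(visit_codes[v], key=int) for v in range(n_visits)]
        visits[0] = [gender_token] + visits[0]

        visits = _inject_noise(rng, visits, pid, config, cb, truth, gender_token,
                               ages, prev_by_age, sampled_codes)
        records.append(RawRecord([RawVisit(t) for t in visits]))

    truth.anomalies = {k: v for k, v in truth.anomalies.items() if v}
    return records, truth


def _inject_noise(rng, visits, pid, config, cb, truth, gender_token,
                  ages, prev_by_age, sampled_codes):
    rates = config.noise_rates
    if not rates:
        return visits

    other_gender = (cb.gender_codes["female"] if gender_token == cb.gender_codes["male"]
                    else cb.gender_codes["male"])

    # at most one record-removing anomaly per patient (categorical draw)
    u = rng.random()
    cum = 0.0
    removal = None
    for kind in REMOVAL_NOISE:
        cum += rates.get(kind, 0.0)
        if u < cum:
            removal = kind
            break

    if removal == "gender_missing":
        visits[0] = [t for t in visits[0] if t != gender_token]
    elif removal == "gender_conflicting":
        visits[0] = visits[0][:1] + [other_gender] + visits[0][1:]
    elif removal == "gender_only_record":
        visits = [[gender_token]]
    elif removal == "no_diabetes_record":
        visits[0] = [t for t in visits[0] if t != cb.diabetes_code]
    elif removal == "endpoint_before_diabetes":
        ep = cb.endpoint_codes[rng.choice(len(cb.endpoint_codes))]
        visits[0] = [t for t in visits[0] if t != gender_token]
        visits = [[gender_token, ages[0], ep]] + visits
    if removal is not None:
        truth.anomalies[removal].append(pid)
        return visits

    # benign structural noise, independent draws
    def sample_code(age):
        probs = prev_by_age[age]
        if probs.sum() == 0:
            return None
        return sampled_codes[rng.choice(len(sampled_codes), p=probs / probs.sum())]

    if rng.random() < rates.get("pre_diabetes_visits", 0.0):
        k = 1 + int(rng.random() < 0.5)
        pre = []
        for _ in range(k):
            code = sample_code(ages[0])
            pre.append([ages[0]] + ([code] if code else []))
        visits[0] = [t for t in visits[0] if t != gender_token]
        visits = [[gender_token] + pre[0]] + pre[1:] + visits
        truth.anomalies["pre_diabetes_visits"].append(pid)

    if rng.random() < rates.get("empty_visit", 0.0):
        pos = int(rng.integers(1, len(visits) + 1))
        visits = visits[:pos] + [[]] + visits[pos:]
        truth.anomalies["empty_visit"].append(pid)

    if rng.random() < rates.get("age_only_visit", 0.0):
        pos = int(rng.integers(1, len(visits) + 1))
        prev_age = next((t for t in reversed(visits[pos - 1]) if cb.is_age(t)),
                        ages[0])
        visits = visits[:pos] + [[prev_age]] + visits[pos:]
        truth.anomalies["age_only_visit"].append(pid)

    if rng.random() < rates.get("missing_age_label", 0.0):
        # only strip an age from visits that survive cleaning: a visit
        # survives iff it has an age token and at least one novel code
        # (deduplication empties visits whose codes all appeared earlier)
        seen_codes: set[str] = set()
        aged = []
        for i, v in enumerate(visits):
            novel = [t for t in v if cb.is_diagnosis(t) and t not in seen_codes]
            seen_codes.update(novel)
            if novel and any(cb.is_age(t) for t in v):
                aged.append(i)
        if len(aged) >= 2:
            i = aged[rng.choice(len(aged))]
            seen = False
            kept = []
            for t in visits[i]:
                if cb.is_age(t) and not seen:
                    seen = True
                    continue
                kept.append(t)
            visits[i] = kept
            truth.anomalies["missing_age_label"].append(pid)

    if rng.random() < rates.get("misplaced_age_label", 0.0):
        cands = [i for i, v in enumerate(visits)
                 if any(cb.is_age(t) for t in v) and len(v) >= 2]
        if cands:
            i = cands[rng.choice(len(cands))]
            age = next(t for t in visits[i] if cb.is_age(t))
            rest = [t for t in visits[i] if not (cb.is_age(t) and t == age)]
            visits[i] = rest + [age]
            truth.anomalies["misplaced_age_label"].append(pid)

    if rng.random() < rates.get("duplicate_chronic_code", 0.0) and len(visits) >= 2:
        skip = {cb.diabetes_code} | set(cb.endpoint_codes)
        early = [t for t in visits[0] if cb.is_diagnosis(t) and t not in skip]
        if early:
            code = early[rng.choice(len(early))]
            if code not in visits[-1]:
                visits[-1] = visits[-1] + [code]
                truth.anomalies["duplicate_chronic_code"].append(pid)

    return visits


# --- summary statistics -------------------------------------------------------


def summary_stats(values: list[int] | np.ndarray) -> dict[str, float]:
    """Spreadsheet-convention moments of a count sample.

    Sample std/variance (ddof=1); bias-corrected skewness and excess
    kurtosis.  Degenerate samples (too few points or zero spread) report NaN
    for the undefined moments.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    out = {
        "max": float(x.max()) if n else float("nan"),
        "mean": float(x.mean()) if n else float("nan"),
        "median": float(np.median(x)) if n else float("nan"),
        "std": float(x.std(ddof=1)) if n > 1 else float("nan"),
        "variance": float(x.var(ddof=1)) if n > 1 else float("nan"),
    }
    spread = n > 2 and x.std(ddof=1) > 0
    out["skewness"] = float(skew(x, bias=False)) if spread else float("nan")
    out["kurtosis"] = (float(kurtosis(x, fisher=True, bias=False))
                       if spread and n > 3 else float("nan"))
    return out


def cohort_summary(cohort: list[RawRecord], codebook: CodeBook) -> pd.DataFrame:
    """Visit-count moments plus code/pair diversity of a raw cohort.

    Pairs use each visit's first age token; codes in ageless visits count
    toward code diversity but not pair diversity.
    """
    if not cohort:
        import warnings

        warnings.warn("empty cohort: summary is empty", stacklevel=2)
        return pd.DataFrame(columns=["statistic", "value"])
    counts = [len(r.visits) for r in cohort]
    stats = summary_stats(counts)
    codes: set[str] = set()
    pairs: set[Pair] = set()
    max_pairs = 0
    for r in cohort:
        patient_pairs: set[Pair] = set()
        for v in r.visits:
            age = next((t for t in v.tokens if codebook.is_age(t)), None)
            for t in v.tokens:
                if codebook.is_diagnosis(t):
                    codes.add(t)
                    if age is not None:
                        patient_pairs.add((age, t))
        pairs |= patient_pairs
        max_pairs = max(max_pairs, len(patient_pairs))
    rows = [("n_patients", float(len(cohort)))]
    rows += [(f"visits_{k}", v) for k, v in stats.items()]
    rows += [
        ("unique_codes", float(len(codes))),
        ("unique_pairs", float(len(pairs))),
        ("max_pairs_per_patient", float(max_pairs)),
    ]
    return pd.DataFrame(rows, columns=["statistic", "value"])
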