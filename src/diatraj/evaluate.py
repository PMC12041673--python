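"""Validation protocols: Monte-Carlo cross-validation and partitioned
validation, with leakage-safe per-split fitting.

Within every split, the min-max normalizer, the feature ranking and the
classifiers are fitted on training rows only; the pair vocabulary is fixed
dataset-wide (it enumerates observed pairs, not label information).

Seeding: the master seed fans out through a ``numpy.random.SeedSequence``
counter scheme — one child per run, from which the split seed, the ranking
seed and one model seed per classifier family are drawn — so any single run
is reproducible in isolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedShuffleSplit

from .codebook import CodeBook
from .endpoints import EndpointDataset
from .features import (BofVocabulary, FeatureVocabulary, MinMaxNormalizer,
                       encode_bof_dataset, vectorize_dataset)
from .metrics import compute_metrics
from .models import ModelSpec, RankedFeatures, rank_features_xgb, train_model

METRIC_COLUMNS = ("accuracy", "sensitivity", "specificity",
                  "f_measure", "precision", "auc")


@dataclass
class EvalConfig:
    protocol: str = "mccv"
    k_repeats: int = 10
    train_fraction: float = 0.9
    n_validation_subsets: int = 5
    validation_fraction: float = 0.05
    feature_subset_sizes: tuple = (25, 50, 100, 150, 200, "all")
    repetitions: int = 6
    seed: int = 0
    threshold: float = 0.5

    def validate(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0,1)")
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must be in (0,1)")
        if self.n_validation_subsets * self.validation_fraction >= 1:
            raise ValueError("validation subsets must cover less than the dataset")


@dataclass
class EvalReport:
    """Per-run metric rows plus provenance; means via :meth:`summary`."""

    protocol: str
    endpoint: str
    runs: pd.DataFrame
    config: EvalConfig

    def summary(self) -> pd.DataFrame:
        keys = [k for k in ("family", "subset_size", "subset") if k in self.runs]
        return (self.runs.groupby(keys, sort=False)[list(METRIC_COLUMNS)]
                .mean().reset_index())


def _seed_ints(seq: np.random.SeedSequence, n: int) -> list[int]:
    return [int(s) % (2**31 - 1) for s in seq.generate_state(n)]


def _encode(dataset: EndpointDataset, encoding: str):
    if encoding == "pairs":
        vocab = FeatureVocabulary.from_dataset(dataset)
        return vocab, vectorize_dataset(dataset, vocab)
    if encoding == "bof":
        vocab = BofVocabulary.from_dataset(dataset)
        return vocab, encode_bof_dataset(dataset, vocab)
    raise ValueError(f"unknown encoding {encoding!r}")


def _effective_size(requested, dim: int):
    if requested == "all":
        return "all", dim
    k = int(requested)
    if k >= dim:
        warnings.warn(
            f"subset size {k} capped at feature dimension {dim}", stacklevel=3)
        return requested, dim
    return requested, k


def run_mccv(
    dataset: EndpointDataset,
    specs: list[ModelSpec],
    config: EvalConfig,
    encoding: str = "pairs",
) -> EvalReport:
    """Repeated stratified train/test splits with per-split fitting.

    Each of ``k_repeats × repetitions`` runs re-randomizes the split; for
    every requested feature-subset size the top-ranked training-set features
    feed each classifier family, and test-set metrics are recorded per run.
    """
    config.validate()
    _, X = _encode(dataset, encoding)
    y = dataset.labels()
    dim = X.shape[1]
    n_runs = config.k_repeats * config.repetitions
    children = np.random.SeedSequence(config.seed).spawn(n_runs)
    needs_ranking = any(s != "all" for s in config.feature_subset_sizes)

    rows = []
    for run, child in enumerate(children):
        seeds = _seed_ints(child, 2 + len(specs))
        split_seed, rank_seed, *model_seeds = seeds
        splitter = StratifiedShuffleSplit(
            n_splits=1, train_size=config.train_fraction, random_state=split_seed)
        train_idx, test_idx = next(splitter.split(X, y))

        norm = MinMaxNormalizer().fit(X, train_idx)
        Xn = norm.transform(X)
        ranking: RankedFeatures | None = None
        if needs_ranking:
            ranking = rank_features_xgb(Xn[train_idx], y[train_idx], seed=rank_seed)

        for requested in config.feature_subset_sizes:
            label, k = _effective_size(requested, dim)
            cols = (np.arange(dim) if label == "all" or ranking is None
                    else ranking.top(k))
            for spec, mseed in zip(specs, model_seeds):
                run_spec = ModelSpec(spec.family, seed=mseed,
                                     hyperparameters=spec.hyperparameters)
                fitted = train_model(run_spec, Xn[np.ix_(train_idx, cols)],
                                     y[train_idx])
                scores = fitted.scores(Xn[np.ix_(test_idx, cols)])
                m = compute_metrics(scores, y[test_idx], config.threshold)
                rows.append({
                    "run": run, "family": spec.family, "subset_size": label,
                    "n_features": len(cols), "split_seed": split_seed,
                    "model_seed": mseed, **m.as_dict(),
                })
    return EvalReport("mccv", dataset.endpoint, pd.DataFrame(rows), config)


def stratified_partition(
    labels: np.ndarray,
    train_fraction: float = 0.75,
    n_subsets: int = 5,
    subset_fraction: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Disjoint stratified validation subsets plus the training remainder.

    Each subset holds floor(subset_fraction × N) rows with per-class counts
    proportional to the class distribution (largest-remainder rounding).
    The training set is everything not allocated to a subset.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if not 0 < subset_fraction < 1 or n_subsets * subset_fraction >= 1:
        raise ValueError("invalid subset fractions")
    if train_fraction + n_subsets * subset_fraction > 1 + 1e-9:
        raise ValueError("training and validation fractions exceed the dataset")
    subset_size = int(np.floor(subset_fraction * n))
    if subset_size == 0:
        raise ValueError("subset size is zero for this dataset")

    classes, counts = np.unique(labels, return_counts=True)
    frac = subset_size * counts / n
    base = np.floor(frac).astype(int)
    short = subset_size - base.sum()
    order = np.argsort(-(frac - base))  # classes most short-changed first
    per_class = base.copy()
    per_class[order[:short]] += 1

    rng = np.random.default_rng(seed)
    subsets: list[list[int]] = [[] for _ in range(n_subsets)]
    train: list[int] = []
    for cls, take in zip(classes, per_class):
        idx = np.flatnonzero(labels == cls)
        idx = idx[rng.permutation(len(idx))]
        pos = 0
        for s in range(n_subsets):
            subsets[s].extend(idx[pos:pos + take])
            pos += take
        train.extend(idx[pos:])
    return (np.array(sorted(train)),
            [np.array(sorted(s)) for s in subsets])


def run_partitioned_validation(
    dataset: EndpointDataset,
    specs: list[ModelSpec],
    config: EvalConfig,
    subset_size: int | str = "all",
    encoding: str = "pairs",
) -> EvalReport:
    """Train once on the stratified 75% allocation, evaluate on each of the
    five disjoint validation subsets independently (rows v1..v5)."""
    config.validate()
    _, X = _encode(dataset, encoding)
    y = dataset.labels()
    dim = X.shape[1]
    seeds = _seed_ints(np.random.SeedSequence(config.seed), 2 + len(specs))
    part_seed, rank_seed, *model_seeds = seeds
    train_idx, val_subsets = stratified_partition(
        y,
        1 - config.n_validation_subsets * config.validation_fraction,
        config.n_validation_subsets, config.validation_fraction, part_seed)

    norm = MinMaxNormalizer().fit(X, train_idx)
    Xn = norm.transform(X)
    label, k = _effective_size(subset_size, dim)
    if label == "all":
        cols = np.arange(dim)
    else:
        ranking = rank_features_xgb(Xn[train_idx], y[train_idx], seed=rank_seed)
        cols = ranking.top(k)

    rows = []
    for spec, mseed in zip(specs, model_seeds):
        run_spec = ModelSpec(spec.family, seed=mseed,
                             hyperparameters=spec.hyperparameters)
        fitted = train_model(run_spec, Xn[np.ix_(train_idx, cols)], y[train_idx])
        for s, val_idx in enumerate(val_subsets, start=1):
            scores = fitted.scores(Xn[np.ix_(val_idx, cols)])
            m = compute_metrics(scores, y[val_idx], config.threshold)
            rows.append({
                "family": spec.family, "subset": f"v{s}",
                "subset_size": label, "n_features": len(cols),
                "n_rows": len(val_idx), **m.as_dict(),
            })
    return EvalReport("partitioned", dataset.endpoint, pd.DataFrame(rows), config)


def compare_encodings(
    dataset: EndpointDataset,
    config: EvalConfig,
    spec: ModelSpec | None = None,
    fs_size: int = 100,
) -> pd.DataFrame:
    """Three-regime comparison: Bag-of-Features with all features, the pair
    encoding with all features, and the pair encoding with top-``fs_size``
    selected features — one summary row per regime."""
    spec = spec or ModelSpec("xgboost")
    regimes = [
        ("BoF (all features)", "bof", ("all",)),
        ("Proposed (all features)", "pairs", ("all",)),
        ("Proposed + XGB FS", "pairs", (fs_size,)),
    ]
    rows = []
    for name, encoding, sizes in regimes:
        cfg = EvalConfig(
            protocol="mccv", k_repeats=config.k_repeats,
            train_fraction=config.train_fraction,
            feature_subset_sizes=sizes, repetitions=config.repetitions,
            seed=config.seed, threshold=config.threshold)
        report = run_mccv(dataset, [spec], cfg, encoding=encoding)
        mean = report.runs[list(METRIC_COLUMNS)].mean()
        rows.append({
            "endpoint": dataset.endpoint,
            "fs_model": name,
            "n_features": int(report.runs["n_features"].iloc[0]),
            **{m: float(mean[m]) for m in METRIC_COLUMNS},
        })
    return pd.DataFrame(rows)


def default_model_specs(seed: int = 0) -> list[ModelSpec]:
    from .models import MODEL_FAMILIES

    return [ModelSpec(f, seed=seed) for f in MODEL_FAMILIES]
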