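"""Deterministic TSV renderings of the analysis tables.

All writers format floats with fixed precision so regenerating a report
from the same seeded run reproduces it byte for byte.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .codebook import CodeBook
from .evaluate import METRIC_COLUMNS, EvalReport
from .features import FeatureVocabulary
from .models import RankedFeatures

_METRIC_HEADER = {
    "accuracy": "Accuracy", "sensitivity": "Sensitivity",
    "specificity": "Specificity", "f_measure": "F-measure",
    "precision": "Precision", "auc": "AUC",
}


def _pct(x: float) -> str:
    return "NA" if pd.isna(x) else f"{100 * x:.1f}%"


def render_df_table(df_table: pd.DataFrame) -> str:
    """Document-frequency table: one (age range, code, DF%) row, sorted."""
    lines = ["age_range\tcode\tdf_pct"]
    for _, row in df_table.iterrows():
        lines.append(f"{row['age_range']}\t{row['code']}\t{row['df_pct']:.2f}")
    return "\n".join(lines) + "\n"


def render_mccv_report(report: EvalReport) -> str:
    """Mean MCCV metric panel per (subset size, model family)."""
    summary = report.summary()
    lines = ["Endpoint\tSubset\tn_features\tML Model\t"
             + "\t".join(_METRIC_HEADER[m] for m in METRIC_COLUMNS)]
    nfeat = (report.runs.groupby(["family", "subset_size"], sort=False)
             ["n_features"].first())
    for _, row in summary.iterrows():
        k = nfeat[(row["family"], row["subset_size"])]
        cells = [report.endpoint, str(row["subset_size"]), str(int(k)),
                 row["family"]]
        cells += [_pct(row[m]) for m in METRIC_COLUMNS]
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"


def render_partitioned_report(report: EvalReport) -> str:
    """One metric row per validation subset v1..v5 per model family."""
    lines = ["Endpoint\tML Model\tValidation Subset\t"
             + "\t".join(_METRIC_HEADER[m] for m in METRIC_COLUMNS)]
    for _, row in report.runs.iterrows():
        cells = [report.endpoint, row["family"], row["subset"]]
        cells += [_pct(row[m]) for m in METRIC_COLUMNS]
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"


def render_top_predictors(
    ranking: RankedFeatures,
    vocab: FeatureVocabulary,
    codebook: CodeBook,
    top_n: int = 25,
) -> str:
    """Ranked predictor table: rank, age range, diagnosed disease."""
    names = vocab.column_names()
    lines = ["Rank\tAge Range\tDiagnosed Disease"]
    rank = 0
    for idx in ranking.order:
        if rank >= top_n:
            break
        name = names[idx]
        if name.startswith("gender:"):
            age, disease = "-", name.split(":", 1)[1]
        else:
            age, code = name.split(":", 1)
            age = codebook.age_range_name(age)
            disease = codebook.display_name(code)
        rank += 1
        lines.append(f"{rank}\t{age}\t{disease}")
    return "\n".join(lines) + "\n"


def render_comparison(table: pd.DataFrame) -> str:
    """Encoding-comparison table (baseline vs proposed vs proposed+FS)."""
    lines = ["Endpoint\tFS Model\tn_features\t"
             + "\t".join(_METRIC_HEADER[m] for m in METRIC_COLUMNS)]
    for _, row in table.iterrows():
        cells = [str(row["endpoint"]), row["fs_model"], str(int(row["n_features"]))]
        cells += [_pct(row[m]) for m in METRIC_COLUMNS]
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"


def write_text(path: str | Path, text: str) -> None:
    Path(path).write_text(text, encoding="utf-8")
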