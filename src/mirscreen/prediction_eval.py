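"""Precision benchmarking of miRNA target-prediction programs.

Precision here is experimental: the percentage of predicted miRNA-mRNA
pairs that, when assayed in the reporter screen, were called positive,
among the predicted pairs actually tested. Per-gene precisions are pooled
per program into a total precision (pooled counts, not a mean of
percentages), and the per-program totals are averaged (unweighted) across
programs. A co-prediction precision restricts the tested set to the
per-gene intersection of several programs' tested sets.

The module works on two levels: identity-level ``PredictionTable`` records
(sets of miRNA ids per program x gene) and count-level tables, since the
published benchmark is available as counts. Bundled under
``mirscreen/data`` are the published benchmark count tables this package
reproduces in its tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .errors import InputError
from .hit_stats import round_half_up


@dataclass(frozen=True)
class PredictionTable:
    """One program's predictions for one gene, at miRNA-identity level."""

    program: str
    gene: str
    predicted: frozenset
    tested: frozenset
    validated_positive: frozenset

    def __post_init__(self):
        if not self.tested <= self.predicted:
            raise InputError(
                f"{self.program}/{self.gene}: tested set not within predicted set"
            )
        if not self.validated_positive <= self.tested:
            raise InputError(
                f"{self.program}/{self.gene}: positives not within tested set"
            )


def precision(table: PredictionTable) -> float:
    """Per-gene precision of one program, percent to one decimal.

    Zero tested miRNAs is reported as 0.0 (the benchmark-table convention
    for untestable cells).
    """
    return precision_from_counts(len(table.validated_positive), len(table.tested))


def precision_from_counts(positive: int, tested: int) -> float:
    if tested == 0:
        return 0.0
    if positive > tested:
        raise InputError(f"positive count {positive} exceeds tested count {tested}")
    return round_half_up(100.0 * positive / tested, 1)


def total_precision(tables: list[PredictionTable]) -> float:
    """One program's precision pooled over genes: 100 * sum(pos) / sum(tested).

    Pooling counts — not averaging per-gene percentages — weights each gene
    by how many of its predictions were tested.
    """
    tested = sum(len(t.tested) for t in tables)
    positive = sum(len(t.validated_positive) for t in tables)
    if tested == 0:
        raise InputError("total_precision undefined: no tested predictions pooled")
    return round_half_up(100.0 * positive / tested, 1)


def average_precision(program_totals) -> float:
    """Unweighted arithmetic mean of per-program total precisions."""
    totals = list(program_totals)
    if not totals:
        raise InputError("average_precision of an empty list")
    return round_half_up(sum(totals) / len(totals), 1)


def co_prediction_precision(tables_by_program: dict[str, list[PredictionTable]]) -> float:
    """Precision of the miRNAs tested by every program in a combination.

    For each gene the tested set is the intersection of the programs'
    tested sets; validated labels are program-independent so the positive
    count within the intersection is unambiguous. Counts are pooled across
    genes as in ``total_precision``.
    """
    if len(tables_by_program) < 2:
        raise InputError("co-prediction needs >= 2 programs")
    genes = set.intersection(
        *(set(t.gene for t in tabs) for tabs in tables_by_program.values())
    )
    tested_total = 0
    positive_total = 0
    for gene in genes:
        per_program = [
            next(t for t in tabs if t.gene == gene)
            for tabs in tables_by_program.values()
        ]
        common = frozenset.intersection(*(t.tested for t in per_program))
        positives = set.union(*(set(t.validated_positive) for t in per_program))
        tested_total += len(common)
        positive_total += len(common & positives)
    if tested_total == 0:
        raise InputError("co-prediction undefined: tested intersection is empty")
    return round_half_up(100.0 * positive_total / tested_total, 1)


def check_label_consistency(tables: list[PredictionTable]) -> None:
    """Validated labels must not depend on the predicting program.

    For every (gene, miRNA) pair tested by several programs, the
    positive/negative label must agree across them.
    """
    labels: dict[tuple[str, str], bool] = {}
    for t in tables:
        for m in t.tested:
            key = (t.gene, m)
            lab = m in t.validated_positive
            if key in labels and labels[key] != lab:
                raise InputError(
                    f"inconsistent validation label for miRNA {m!r} on gene {t.gene!r}"
                )
            labels[key] = lab


def summarize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Benchmark report matrix from a count table.

    Input columns: gene, program, predicted, tested, positive. Output has
    one row per gene per program plus a ``Summary`` gene block whose counts
    are column sums and whose precision is computed from the pooled counts.
    """
    required = {"gene", "program", "predicted", "tested", "positive"}
    missing = required - set(counts.columns)
    if missing:
        raise InputError(f"count table missing columns: {sorted(missing)}")
    if counts.empty:
        return counts.assign(precision=[])
    bad = counts[counts["positive"] > counts["tested"]]
    if not bad.empty:
        raise InputError("positive count exceeds tested count in count table")

    per_cell = counts.copy()
    per_cell["precision"] = [
        precision_from_counts(p, t)
        for p, t in zip(per_cell["positive"], per_cell["tested"])
    ]
    summary = (
        counts.groupby("program", sort=False)[["predicted", "tested", "positive"]]
        .sum()
        .reset_index()
    )
    summary.insert(0, "gene", "Summary")
    summary["precision"] = [
        precision_from_counts(p, t)
        for p, t in zip(summary["positive"], summary["tested"])
    ]
    return pd.concat([per_cell, summary], ignore_index=True)


def tables_to_counts(tables: list[PredictionTable]) -> pd.DataFrame:
    """Collapse identity-level tables into the count-table schema."""
    check_label_consistency(tables)
    return pd.DataFrame(
        {
            "gene": [t.gene for t in tables],
            "program": [t.program for t in tables],
            "predicted": [len(t.predicted) for t in tables],
            "tested": [len(t.tested) for t in tables],
            "positive": [len(t.validated_positive) for t in tables],
        }
    )


def _load_bundled(name: str) -> pd.DataFrame:
    ref = resources.files("mirscreen.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def load_benchmark_counts() -> pd.DataFrame:
    """Published 9-program x 7-gene benchmark counts (predicted/tested/positive)."""
    return _load_bundled("benchmark_counts.tsv")


def load_gene_positive_counts() -> pd.DataFrame:
    """Published per-gene counts of distinct positive miRNAs (union over programs)."""
    return _load_bundled("gene_positive_counts.tsv")


def load_genome_screen_counts() -> pd.DataFrame:
    """Published genome-wide screen positives/tested per subset."""
    return _load_bundled("genome_screen_counts.tsv")
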