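"""Per-pathogen precision/recall/F1 with micro and macro averaging.

Evaluation granularity is the citation level: a (pmid, pathogen) pair
counts once regardless of how many mentions occur in the citation,
because the gold signal (MeSH indexing) is per citation.  Counts follow
the usual contingency layout: TP, gold positives, and predicted
positives (FP + TP).  Precision = TP / (FP + TP); recall = TP /
positives; F1 is their harmonic mean.  Any metric with a zero
denominator is 0 by convention.  Reported values are rounded
half-away-from-zero at 4 decimals; full precision is kept internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence


@dataclass(frozen=True)
class EvalCounts:
    tp: int
    gold_positives: int
    predicted_positives: int

    def __post_init__(self) -> None:
        if min(self.tp, self.gold_positives, self.predicted_positives) < 0:
            raise ValueError("counts must be non-negative")
        if self.tp > min(self.gold_positives, self.predicted_positives):
            raise ValueError(
                "tp cannot exceed gold_positives or predicted_positives"
            )


@dataclass(frozen=True)
class Metrics:
    precision: float
    recall: float
    f1: float

    def rounded(self) -> "Metrics":
        return Metrics(
            round4(self.precision), round4(self.recall), round4(self.f1)
        )


def round4(x: float) -> float:
    """Round half away from zero at 4 decimals."""
    import math

    scaled = x * 10_000
    return math.copysign(math.floor(abs(scaled) + 0.5), scaled) / 10_000


def compute_metrics(counts: EvalCounts) -> Metrics:
    precision = (
        counts.tp / counts.predicted_positives if counts.predicted_positives else 0.0
    )
    recall = counts.tp / counts.gold_positives if counts.gold_positives else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return Metrics(precision, recall, f1)


def micro_average(counts_list: Sequence[EvalCounts]) -> Metrics:
    """Sum counts over pathogens, then compute metrics once."""
    if not counts_list:
        raise ValueError("micro_average requires a non-empty list")
    total = EvalCounts(
        tp=sum(c.tp for c in counts_list),
        gold_positives=sum(c.gold_positives for c in counts_list),
        predicted_positives=sum(c.predicted_positives for c in counts_list),
    )
    return compute_metrics(total)


def macro_average(counts_list: Sequence[EvalCounts]) -> Metrics:
    """Per-pathogen metrics first, then the arithmetic mean of each."""
    if not counts_list:
        raise ValueError("macro_average requires a non-empty list")
    per = [compute_metrics(c) for c in counts_list]
    n = len(per)
    return Metrics(
        precision=sum(m.precision for m in per) / n,
        recall=sum(m.recall for m in per) / n,
        f1=sum(m.f1 for m in per) / n,
    )


def count_predictions(
    predicted: Iterable[tuple[str, str]],
    gold: Iterable[tuple[str, str]],
    pathogen_id: str,
) -> EvalCounts:
    """Contingency counts for one pathogen over (pmid, pathogen) pair sets."""
    pred = {p for p in predicted if p[1] == pathogen_id}
    gld = {g for g in gold if g[1] == pathogen_id}
    return EvalCounts(
        tp=len(pred & gld),
        gold_positives=len(gld),
        predicted_positives=len(pred),
    )


def evaluate_pairs(
    predicted: Iterable[tuple[str, str]],
    gold: Iterable[tuple[str, str]],
    pathogen_ids: Iterable[str] | None = None,
) -> dict[str, EvalCounts]:
    """Per-pathogen counts over every pathogen present in either set."""
    predicted = set(predicted)
    gold = set(gold)
    if pathogen_ids is None:
        pathogen_ids = sorted({p for _, p in predicted} | {p for _, p in gold})
    return {
        pid: count_predictions(predicted, gold, pid) for pid in pathogen_ids
    }


def write_report_tsv(
    per_pathogen: dict[str, EvalCounts], path: str | Path
) -> None:
    """TSV report: term, TP, Positives, FP+TP, Precision, Recall, F1,
    with trailing micro- and macro-average rows."""
    rows = []
    for pid in sorted(per_pathogen):
        c = per_pathogen[pid]
        m = compute_metrics(c).rounded()
        rows.append(
            f"{pid}\t{c.tp}\t{c.gold_positives}\t{c.predicted_positives}"
            f"\t{m.precision:.4f}\t{m.recall:.4f}\t{m.f1:.4f}"
        )
    counts_list = [per_pathogen[p] for p in sorted(per_pathogen)]
    micro = micro_average(counts_list).rounded()
    macro = macro_average(counts_list).rounded()
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("term\tTP\tPositives\tFP+TP\tPrecision\tRecall\tF1\n")
        for row in rows:
            fh.write(row + "\n")
        fh.write(
            f"micro-average\t\t\t\t{micro.precision:.4f}\t{micro.recall:.4f}"
            f"\t{micro.f1:.4f}\n"
        )
        fh.write(
            f"macro-average\t\t\t\t{macro.precision:.4f}\t{macro.recall:.4f}"
            f"\t{macro.f1:.4f}\n"
        )
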