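"""Length-based benchmarking of prophage predictions against a gold standard.

Performance is measured in base pairs, not in prophage counts: TP is the
total length of the intersection between the (disjoint unions of the)
predictions and the gold standard, FP the predicted length outside the
gold standard, FN the gold length missed. Sensitivity = TP/(TP+FN) and
PPV = TP/(TP+FP); when a denominator is zero (no gold, or no predictions)
the ratio is reported as undefined (None), never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .intervals import Interval, intersect, merge_intervals, subtract, total_length


@dataclass(frozen=True)
class EvaluationResult:
    """TP/FP/FN overlap lengths and the derived rates for one comparison."""

    tp_len: int
    fp_len: int
    fn_len: int
    sensitivity: Optional[float]
    ppv: Optional[float]


def evaluate(
    predictions: Sequence[Interval], gold: Sequence[Interval]
) -> EvaluationResult:
    """Compare predicted and gold intervals by overlap length.

    Both sets are reduced to their disjoint unions per contig first, so no
    base is counted twice. Intervals on contigs absent from the other set
    count fully as FP or FN.
    """
    tp = total_length(intersect(predictions, gold))
    fp = total_length(subtract(predictions, gold))
    fn = total_length(subtract(gold, predictions))
    sens = tp / (tp + fn) if (tp + fn) > 0 else None
    ppv = tp / (tp + fp) if (tp + fp) > 0 else None
    return EvaluationResult(tp, fp, fn, sens, ppv)


def evaluate_per_genome(
    predictions: Sequence[Interval], gold: Sequence[Interval]
) -> dict[str, EvaluationResult]:
    """One evaluation per contig/genome id (a contig stands for a genome
    when many genomes are pooled in one file)."""
    contigs = sorted(
        {iv.contig_id for iv in predictions} | {iv.contig_id for iv in gold}
    )
    return {
        c: evaluate(
            [iv for iv in predictions if iv.contig_id == c],
            [iv for iv in gold if iv.contig_id == c],
        )
        for c in contigs
    }


def compare_tools(
    prediction_sets: Mapping[str, Sequence[Interval]],
    gold: Sequence[Interval],
    mode: str = "pooled",
) -> pd.DataFrame:
    """Evaluate several tools' predictions against one gold standard.

    ``mode='pooled'`` measures each tool over all contigs at once;
    ``mode='per-genome'`` averages sensitivity and PPV over contigs,
    ignoring contigs where the ratio is undefined (the TP/FP/FN columns
    stay pooled sums either way). Rows are ordered by tool name.
    """
    if mode not in ("pooled", "per-genome"):
        raise ValueError(f"unknown mode {mode!r}")
    rows = []
    for tool in sorted(prediction_sets):
        preds = prediction_sets[tool]
        pooled = evaluate(preds, gold)
        if mode == "pooled":
            sens, ppv = pooled.sensitivity, pooled.ppv
        else:
            per = evaluate_per_genome(preds, gold).values()
            sens_vals = [r.sensitivity for r in per if r.sensitivity is not None]
            ppv_vals = [r.ppv for r in per if r.ppv is not None]
            sens = sum(sens_vals) / len(sens_vals) if sens_vals else None
            ppv = sum(ppv_vals) / len(ppv_vals) if ppv_vals else None
        rows.append(
            {
                "tool": tool,
                "tp_len": pooled.tp_len,
                "fp_len": pooled.fp_len,
                "fn_len": pooled.fn_len,
                "sensitivity": sens,
                "ppv": ppv,
            }
        )
    return pd.DataFrame(rows, columns=["tool", "tp_len", "fp_len", "fn_len", "sensitivity", "ppv"])


def format_percent_table(table: pd.DataFrame) -> str:
    """Percent view of a comparison table, one decimal place, 'NA' for undefined."""
    out = table.copy()
    for col in ("sensitivity", "ppv"):
        out[col] = [
            "NA" if v is None or pd.isna(v) else f"{100 * v:.1f}" for v in out[col]
        ]
    return out.to_csv(sep="\t", index=False)
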