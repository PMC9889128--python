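"""Per-pathogen precision/recall/F1 with micro and macro averaging.

Counts are citation-level: a (pmid, pathogen) pair counts once however
many times the pathogen is mentioned.  Metrics are reported at 4
decimals, rounding half away from zero.
"""

from pathocite import EvalCounts, compute_metrics, macro_average, micro_average

rows = {
    "Sc (cat)": EvalCounts(tp=4, gold_positives=9, predicted_positives=6),
    "Sc (cattle)": EvalCounts(tp=145, gold_positives=457, predicted_positives=170),
    "Sc (deer)": EvalCounts(tp=29, gold_positives=46, predicted_positives=40),
    "Sc (goat)": EvalCounts(tp=31, gold_positives=68, predicted_positives=63),
}

print(f"{'term':<12} {'TP':>5} {'Pos':>5} {'FP+TP':>6} {'P':>7} {'R':>7} {'F1':>7}")
for term, counts in rows.items():
    m = compute_metrics(counts).rounded()
    print(
        f"{term:<12} {counts.tp:>5} {counts.gold_positives:>5} "
        f"{counts.predicted_positives:>6} {m.precision:>7.4f} "
        f"{m.recall:>7.4f} {m.f1:>7.4f}"
    )

micro = micro_average(list(rows.values())).rounded()
macro = macro_average(list(rows.values())).rounded()
print(f"{'micro':<12} {'':>26} {micro.precision:>7.4f} {micro.recall:>7.4f} {micro.f1:>7.4f}")
print(f"{'macro':<12} {'':>26} {macro.precision:>7.4f} {macro.recall:>7.4f} {macro.f1:>7.4f}")
# Micro averaging sums the counts first (large pathogens dominate);
# macro averages the per-pathogen metrics (every pathogen weighs the same).
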