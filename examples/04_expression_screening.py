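"""Screen temperature/photoperiod candidate genes from an FPKM matrix.

Simulates a six-checkpoint expression matrix, keeps genes whose profiles
vary at least four-fold (with a pseudocount), classifies toy annotations
by keyword, tallies the kept genes per homolog, and standardizes their
profiles for heatmap display.  The printed table is the per-homolog
bookkeeping of the screened candidates; the z-matrix rows have mean 0,
unit spread, clipped to ±3.
"""

from peonychill import (
    AnnotationRecord,
    ExpressionSimConfig,
    differential_screen,
    heatmap_normalize,
    keyword_classify,
    simulate_expression_pair,
    summarize_by_homolog,
)

pair = simulate_expression_pair(ExpressionSimConfig(n_genes=30, seed=11), 2, 3)
matrix = pair.matrix_a

varying = differential_screen(matrix, fold_threshold=4.0, min_peak=1.0, pseudocount=0.1)
print(f"{len(varying)} of {len(matrix)} genes pass the fold-change screen")

# toy annotations: seasonal genes cold-responsive, ramping genes light-related
annotations = {}
for gid, label in pair.truth.items():
    if label == "cr_congruent":
        annotations[gid] = AnnotationRecord(gid, "AT2G45660", "SOC1", "cold response flowering integrator")
    elif label == "late_photoperiod":
        annotations[gid] = AnnotationRecord(gid, "AT3G08940", "LHCB4.2", "light harvesting complex")
    else:
        annotations[gid] = AnnotationRecord(gid, "", "", "hypothetical protein")

kept = [g for g in varying if keyword_classify(annotations[g])[0] != "none"]
table, total = summarize_by_homolog(kept, annotations)
print(table.to_string(index=False))
print(f"total screened candidates: {total}")

z = heatmap_normalize(matrix.loc[kept])
print(f"heatmap matrix: {z.shape[0]} genes x {z.shape[1]} checkpoints, "
      f"range [{z.min().min():.2f}, {z.max().max():.2f}]")
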