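"""Quantify qPCR measurements with the 2^-dCt method.

Builds one record of 3 biological x 3 technical cycle-threshold readings
for a target gene and its in-sample reference, and aggregates them:
technical replicates average on the Ct scale, each biological replicate
yields one relative expression, and the mean ± sd across biological
replicates is reported.  One extra cycle relative to the reference
halves the expression.
"""

import numpy as np

from peonychill import QPCRRecord, aggregate_qpcr, relative_expression

print("one cycle later than the reference:", relative_expression(21.0, 20.0))

target = np.array(
    [
        [23.1, 23.0, 23.2],   # biological replicate 1
        [23.9, 24.0, 24.1],   # biological replicate 2
        [23.4, 23.5, 23.6],   # biological replicate 3
    ]
)
reference = np.full((3, 3), 20.0)

result = aggregate_qpcr(QPCRRecord("Unigene024925", "Jan 21", target, reference))
print(f"per-replicate 2^-dCt: {[round(r, 4) for r in result.per_replicate]}")
print(f"mean expression {result.mean_expression:.4f} ± {result.sd_expression:.4f}"
      f" (flagged replicates: {list(result.flagged_replicates)})")
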