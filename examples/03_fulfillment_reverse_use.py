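"""Reverse use of the chill model: when is the CR fulfilled each winter?

Loads the packaged six-checkpoint chilling-hour accumulations of the two
study winters (2012-13 and the warmer 2015-16) and finds, for the
672-CH optimal requirement, the first sampling date whose accumulated
chill reaches it.  The printed delay is how much later dormancy release
conditions were met in the warm winter — two weeks, one full sampling
interval.
"""

from peonychill import estimate_fulfillment, fulfillment_delay
from peonychill.datasets import load_checkpoint_series

CR = 672.0  # chilling hours

cp_cold = load_checkpoint_series("2012-2013")
cp_warm = load_checkpoint_series("2015-2016")

for label, cp in (("2012-2013", cp_cold), ("2015-2016", cp_warm)):
    date = estimate_fulfillment(cp, CR)
    print(f"{label}: checkpoints {cp.astype(int).tolist()} CH -> "
          f"CR of {CR:.0f} CH first met on {date:%b %d}")

days, weeks = fulfillment_delay(cp_cold, cp_warm, CR)
print(f"fulfillment delayed by {days} days = {weeks} weeks in the warmer winter")
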