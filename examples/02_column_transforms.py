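"""Bring columns on wildly different scales to a comparable range.

A matrix whose columns differ by orders of magnitude is useless under one
shared color scale: the widest column takes all the colors. Each per-column
transform fixes this differently — z-scores for roughly normal columns,
min-max for shape preservation, the empirical CDF for a probability
reading.
"""

import numpy as np

from interheat import (DataMatrix, normalize_columns, percentize_columns,
                       scale_columns)

rng = np.random.default_rng(0)
values = np.column_stack([
    rng.normal(0, 1, 8),          # unit scale
    rng.normal(500, 120, 8),      # hundreds
    rng.exponential(20000, 8),    # tens of thousands, right-tailed
])
m = DataMatrix(values, [f"s{i}" for i in range(8)], ["a", "b", "c"])

print("raw column ranges:")
for j, lab in enumerate(m.col_labels):
    print(f"  {lab}: [{values[:, j].min():10.2f}, {values[:, j].max():10.2f}]")

for name, fn in [("scale", scale_columns), ("normalize", normalize_columns),
                 ("percentize", percentize_columns)]:
    out = fn(m).values
    print(f"{name:>10}: ranges "
          + ", ".join(f"[{out[:, j].min():6.3f}, {out[:, j].max():6.3f}]"
                      for j in range(3)))
# After any of the three, all columns share one comparable range, so a
# single color scale shows within-column structure for every variable.
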