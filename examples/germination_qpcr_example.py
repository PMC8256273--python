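"""Germination summaries and qPCR relative expression.

Two dishes of 50 seeds at 12 degrees C: a fast, complete germinator (the
north-eastern pattern) and a slow, partial one (the eastern pattern); then
a 2^-ddCt calculation against a reference gene with the eastern sample as
calibrator.
"""

import pandas as pd

from feralscan.phenotype import (
    GerminationRecord,
    germination_ratio,
    mean_germination_time,
    relative_expression,
)

ne = GerminationRecord("NE-dish", "HLJ", 12.0, 50, (4, 6, 8), (10, 30, 10))
e = GerminationRecord("E-dish", "JS", 12.0, 50, (18, 25), (4, 2))

for rec in (ne, e):
    print(f"{rec.dish_id}: ratio {germination_ratio(rec):.2f}, "
          f"mean time {mean_germination_time(rec):.1f} d")

qpcr = pd.DataFrame(
    {
        "sample": ["JS_12d", "JS_12d", "HLJ_4d", "HLJ_4d"],
        "gene": ["OsMADS50-like", "UBQ5", "OsMADS50-like", "UBQ5"],
        "role": ["target", "reference", "target", "reference"],
        "Ct": [26.0, 21.0, 22.8, 21.0],
        "replicate": [1, 1, 1, 1],
    }
)
rel = relative_expression(qpcr, calibrator="JS_12d")
print("\n" + rel.to_string(index=False))
# ddCt of -3.2 cycles means the target is 2^3.2 ~ 9.2-fold more abundant in
# the north-eastern sample than in the calibrator, relative to UBQ5.
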