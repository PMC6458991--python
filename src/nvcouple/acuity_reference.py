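"""Reference visual-acuity group-comparison inputs.

Fourteen Mann–Whitney p-values from log(MAR) visual-acuity comparisons
between patients (n = 12) and controls (n = 10): one comparison per chart
contrast level (100, 25, 10, 5, 2.5, 1.25, 0.6 %) and eye.  These serve as
the worked input for the Holm–Bonferroni step-down demonstration; none of
the comparisons reaches its per-rank threshold.
"""

import pandas as pd

ACUITY_CONTRASTS = (100.0, 25.0, 10.0, 5.0, 2.5, 1.25, 0.6)

#: (eye, chart contrast %) -> two-tailed Mann–Whitney p-value
ACUITY_PVALUES = {
    ("left", 100.0): 0.63,
    ("left", 25.0): 0.92,
    ("left", 10.0): 0.58,
    ("left", 5.0): 0.38,
    ("left", 2.5): 0.85,
    ("left", 1.25): 0.42,
    ("left", 0.6): 0.58,
    ("right", 100.0): 0.20,
    ("right", 25.0): 0.23,
    ("right", 10.0): 0.50,
    ("right", 5.0): 0.35,
    ("right", 2.5): 0.14,
    ("right", 1.25): 0.47,
    ("right", 0.6): 0.72,
}


def acuity_table() -> pd.DataFrame:
    rows = [{"eye": eye, "chart_contrast": c, "p": p}
            for (eye, c), p in ACUITY_PVALUES.items()]
    return pd.DataFrame(rows)
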