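#!/usr/bin/env python
"""Per-subject neurovascular coupling fits from the raw-cohort tables.

Merges the gamma and hemodynamic response tables on (subject, eye,
contrast) — 10 points per subject — and fits the coupling line for each
hemodynamic measure.  Writes results/coupling_fits_raw.csv.
"""

from pathlib import Path

import pandas as pd

from nvcouple import couplingstats as cs
from nvcouple.pipeline import NAME_TO_CONTRAST

ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    gamma = pd.read_csv(ROOT / "meg_gamma.csv")
    hemo = pd.read_csv(ROOT / "hemodynamics.csv")
    hemo = hemo[hemo["contrast"] != "mean"].copy()
    hemo["contrast_fraction"] = hemo["contrast"].map(NAME_TO_CONTRAST)
    merged = gamma.merge(
        hemo, left_on=["subject", "eye", "contrast"],
        right_on=["subject", "eye", "contrast_fraction"],
        suffixes=("", "_hemo"))
    rows = []
    for subj, sub in merged.groupby("subject"):
        for measure in ("bold_pct", "cbf_pct", "cbf_quant"):
            fit = cs.fit_coupling(sub["gamma_pct"], sub[measure],
                                  measure=measure, subject=subj)
            rows.append({"subject": subj, "group": sub["group"].iloc[0],
                         "measure": measure, "gradient": fit.gradient,
                         "intercept": fit.intercept,
                         "n_points": fit.n_points,
                         "r_squared": fit.r_squared})
            if measure == "bold_pct":
                print(f"{subj}: BOLD coupling gradient {fit.gradient:.4f} "
                      f"%/%, R^2 {fit.r_squared:.2f} ({fit.n_points} points)")
    pd.DataFrame(rows).to_csv(ROOT / "coupling_fits_raw.csv", index=False)
    print(f"wrote {ROOT / 'coupling_fits_raw.csv'}")


if __name__ == "__main__":
    main()
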