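#!/usr/bin/env python
"""Behavioral statistics of the synthetic cohort and the model-vs-human
overlay.

Generates the 395-listener synthetic cohort, reports the age-score
correlation and the multiple regression WRS_65% ~ Age + PTA_St +
PTA_EHF, then places the NN2 accuracies per CND profile (from
04_cnd_experiment.py, if present) and the human word scores on a common
percent-synapse-survival axis via the age-survival map.
"""

from pathlib import Path

import pandas as pd

from cndspeech.behavior import (
    correlate_age_wrs,
    default_survival_map,
    fit_wrs_regression,
    overlay_model_vs_human,
    synth_cohort,
)
from cndspeech.decoder import EvalReport

RESULTS = Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)


def main():
    cohort = synth_cohort(395, seed=0)
    cohort.round(2).to_csv(RESULTS / "cohort.csv", index=False)
    r, p = correlate_age_wrs(cohort)
    res = fit_wrs_regression(cohort)
    print(f"age vs WRS65: r = {r:.2f} (p = {p:.2e})")
    print(f"regression adj R^2 = {res.adj_r2:.2f}, n = {res.n}")
    stats = pd.DataFrame({
        "coef": res.params, "p": res.pvalues,
        "std_beta": pd.concat([pd.Series({"const": float("nan")}), res.std_betas]),
    }).round(4)
    stats.to_csv(RESULTS / "behavior_regression.csv")
    print(stats.to_string())

    acc_path = RESULTS / "cnd_accuracy.csv"
    if acc_path.exists():
        import numpy as np

        table = pd.read_csv(acc_path)
        nn2 = table[table.arch == "nn2"]
        reports = {
            row["profile"]: EvalReport(accuracy=row["accuracy"],
                                       confusion=np.zeros((1, 1), dtype=int),
                                       per_snr_bin={"10..0": row["acc_10..0"]})
            for _, row in nn2.iterrows()
        }
        overlay = overlay_model_vs_human(reports, cohort, default_survival_map())
        overlay.round(2).to_csv(RESULTS / "overlay_model_vs_human.csv", index=False)
        print("\nmodel points on the survival axis:")
        print(overlay[overlay.source == "model"].to_string(index=False))
    else:
        print("\n(run 04_cnd_experiment.py first to add model points to the overlay)")


if __name__ == "__main__":
    main()
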