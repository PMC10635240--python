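"""Group comparisons, confounder ANCOVA, and the stage trend.

Compares each diagnostic group's patient-mean packing scaling against the
control group (Welch's t, Cohen's d, Holm-adjusted p-values), fits the
confounder model D ~ case + age + sex + smoker + drinker, and checks the
monotone increase of group means along the progression order.
"""

from pathlib import Path

import pandas as pd

from chromascan import ancova_d, compare_many, trend_across_stages

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    patients = pd.read_csv(OUT / "cohort.csv")

    groups = {
        g: sub["true_mean_d"].to_numpy()
        for g, sub in patients.groupby("group", sort=False)
    }
    comparisons = compare_many(groups, reference="Control")
    comparisons.to_csv(OUT / "group_comparisons.csv", index=False)
    print("group comparisons vs Control (Welch t, Cohen's d):")
    print(comparisons.to_string(index=False, float_format=lambda v: f"{v:.4g}"))

    ancova = ancova_d(patients, d_col="true_mean_d")
    ancova.table.to_csv(OUT / "ancova.csv")
    print(f"\nANCOVA (n={ancova.n}): age coefficient "
          f"{ancova.coef('age'):+.4f} per year (p={ancova.p('age'):.2g}); "
          f"sex p={ancova.p('female'):.2f}, smoker p={ancova.p('smoker'):.2f}, "
          f"drinker p={ancova.p('drinker'):.2f}")

    order = ["Control", "DA", "NDA", "AA", "HNPCC", "CRC"]
    trend = trend_across_stages(order, {g: float(v.mean()) for g, v in groups.items()})
    status = "monotone" if trend["monotone"] else f"{trend['n_violations']} violation(s)"
    print(f"stage trend {' < '.join(order)}: {status}")


if __name__ == "__main__":
    main()
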