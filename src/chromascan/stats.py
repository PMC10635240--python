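"""Group comparisons, confounder ANCOVA, demographics, and stage trends.

Two-sample comparisons use Welch's t-test with Cohen's d (pooled SD) as the
effect size; multi-group tables carry both unadjusted and Holm-adjusted
p-values. The confounder analysis regresses patient-mean D on case status
plus age, sex, smoking and drinking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupComparison",
    "AncovaResult",
    "compare_groups",
    "compare_many",
    "ancova_d",
    "demographic_table",
    "trend_across_stages",
    "cohens_d",
]


@dataclass(frozen=True)
class GroupComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    statistic: float
    p_value: float
    effect_size: float
    test: str = "welch_t"
    effect_size_kind: str = "cohens_d_pooled"

    def __post_init__(self) -> None:
        if self.n_a < 2 or self.n_b < 2:
            raise ValueError("need at least 2 observations per group")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


@dataclass
class AncovaResult:
    """Per-term coefficients from D ~ case + age + sex + smoker + drinker."""

    table: pd.DataFrame  # index: term; columns: coef, se, p
    n: int

    def coef(self, term: str) -> float:
        return float(self.table.loc[term, "coef"])

    def p(self, term: str) -> float:
        return float(self.table.loc[term, "p"])


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Standardized mean difference (b - a) / pooled SD."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = a.size, b.size
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var == 0:
        return 0.0
    return float((b.mean() - a.mean()) / np.sqrt(pooled_var))


def compare_groups(
    d_a: np.ndarray,
    d_b: np.ndarray,
    name_a: str = "a",
    name_b: str = "b",
) -> GroupComparison:
    """Welch two-sample comparison of packing scaling between two groups."""
    a = np.asarray(d_a, float)
    b = np.asarray(d_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            stat, p = 0.0, 1.0
        else:
            raise ValueError("zero variance in both groups with unequal means")
    else:
        stat, p = sps.ttest_ind(a, b, equal_var=False)
    return GroupComparison(
        group_a=name_a,
        group_b=name_b,
        n_a=int(a.size),
        n_b=int(b.size),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        statistic=float(stat),
        p_value=float(p),
        effect_size=cohens_d(a, b),
    )


def compare_many(
    groups: dict[str, np.ndarray], reference: str
) -> pd.DataFrame:
    """Each group vs the reference, with Holm-adjusted p-values appended."""
    rows = []
    for name, values in groups.items():
        if name == reference:
            continue
        cmp = compare_groups(groups[reference], values, reference, name)
        rows.append(
            {
                "group": name,
                "n": cmp.n_b,
                "mean_d": cmp.mean_b,
                "statistic": cmp.statistic,
                "p_value": cmp.p_value,
                "effect_size": cmp.effect_size,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_holm"] = multipletests(out["p_value"].to_numpy(), method="holm")[1]
    return out


def ancova_d(patients: pd.DataFrame, d_col: str = "mean_d") -> AncovaResult:
    """Linear-model confounder analysis of patient-mean D.

    Fits ``D ~ is_case + age + female + smoker + drinker`` where is_case is
    1 for any non-Control group. Raises on a rank-deficient design (e.g. a
    constant covariate).
    """
    df = patients.copy()
    required = {"group", "age", "sex", "smoker", "drinker", d_col}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    df["is_case"] = (df["group"] != "Control").astype(int)
    df["female"] = (df["sex"].astype(str).str.upper().str.startswith("F")).astype(int)
    df["smoker"] = df["smoker"].astype(int)
    df["drinker"] = df["drinker"].astype(int)
    df = df.rename(columns={d_col: "d_outcome"})
    model = smf.ols("d_outcome ~ is_case + age + female + smoker + drinker", data=df)
    exog = model.exog
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        raise ValueError("rank-deficient design (constant or collinear covariates)")
    fit = model.fit()
    table = pd.DataFrame(
        {"coef": fit.params, "se": fit.bse, "p": fit.pvalues}
    )
    return AncovaResult(table=table, n=int(fit.nobs))


def demographic_table(patients: pd.DataFrame) -> pd.DataFrame:
    """Per-group n, % female, % smoker, % drinker, mean age.

    Percentages for an empty group are NaN (undefined-marked).
    """
    if patients.empty:
        raise ValueError("empty cohort")
    rows = []
    for group, sub in patients.groupby("group", sort=False):
        n = len(sub)
        rows.append(
            {
                "group": group,
                "n": n,
                "pct_female": 100.0 * (sub["sex"].astype(str).str.upper().str.startswith("F")).mean()
                if n else float("nan"),
                "pct_smoker": 100.0 * sub["smoker"].astype(bool).mean() if n else float("nan"),
                "pct_drinker": 100.0 * sub["drinker"].astype(bool).mean() if n else float("nan"),
                "mean_age": float(sub["age"].mean()) if n else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def trend_across_stages(
    group_order: list[str], group_means: dict[str, float]
) -> dict:
    """Check weak monotone increase of group-mean D along the stage order."""
    if len(group_order) < 3:
        raise ValueError("need at least 3 ordered groups")
    means = [group_means[g] for g in group_order]
    violations = [
        {"from": group_order[i], "to": group_order[i + 1],
         "drop": means[i] - means[i + 1]}
        for i in range(len(means) - 1)
        if means[i + 1] < means[i]
    ]
    return {
        "order": list(group_order),
        "means": [float(m) for m in means],
        "monotone": not violations,
        "n_violations": len(violations),
        "violations": violations,
    }
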