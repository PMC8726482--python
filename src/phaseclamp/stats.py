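"""Group-comparison decision tree and mean ± SEM reporting.

The comparison scheme mirrors common practice in cellular electrophysiology
studies with one wild-type and two disease lines:

* two groups — unpaired two-sided Student's t-test;
* three groups — one-way ANOVA gate, Tukey HSD post hoc, and (only when the
  ANOVA null is rejected) pairwise t-tests;
* factorial designs (group × voltage or group × concentration) — two-way
  ANOVA with Sidak-adjusted per-level comparisons between the two groups.

Underlying test statistics are delegated to scipy/statsmodels; what is owned
here is the gating logic, the Sidak family definition, and the reporting
schema. Significance is called at α = 0.05 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.formula.api import ols
from statsmodels.stats.multicomp import pairwise_tukeyhsd

ALPHA = 0.05


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean: float
    sem: float


@dataclass(frozen=True)
class ComparisonResult:
    test_name: str
    groups: tuple
    statistic: float
    p_value: float
    adjusted: bool = False
    significant: bool = False


def summarize_group(label: str, values: Sequence[float]) -> GroupSummary:
    """Mean ± SEM (ddof = 1) of one group."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 1:
        raise ValueError("group is empty")
    sem = float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0
    return GroupSummary(label=label, n=int(x.size), mean=float(x.mean()), sem=sem)


def sidak_adjust(p: float, k: int) -> float:
    """Sidak family-wise adjustment of one of k p-values: 1 − (1 − p)^k."""
    if not 0 <= p <= 1 or k < 1:
        raise ValueError("p must lie in [0,1] and k be >= 1")
    return float(1.0 - (1.0 - p) ** k)


def compare_two_groups(
    a: Sequence[float], b: Sequence[float], labels=("a", "b")
) -> ComparisonResult:
    """Unpaired two-sided Student's t-test (pooled variance)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        # degenerate: no within-group variance
        equal = a.mean() == b.mean()
        return ComparisonResult(
            "t-test", tuple(labels), 0.0 if equal else np.inf,
            1.0 if equal else 0.0, significant=not equal,
        )
    t, p = sps.ttest_ind(a, b)
    return ComparisonResult(
        "t-test", tuple(labels), float(t), float(p), significant=bool(p < ALPHA)
    )


def compare_three_groups(groups: Dict[str, Sequence[float]]) -> dict:
    """One-way ANOVA gate → Tukey HSD → pairwise t-tests.

    Pairwise t-tests are run only when the ANOVA null is rejected at
    α = 0.05; the gate decision is always reported.

    Returns a dict with keys ``anova`` (ComparisonResult), ``tukey``
    (list of ComparisonResult) and ``pairwise`` (list, empty when the gate
    stays closed).
    """
    if len(groups) != 3:
        raise ValueError("the three-group driver needs exactly 3 groups")
    labels = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least 2 observations")

    if all(a.std(ddof=1) == 0 for a in arrays) and len({a.mean() for a in arrays}) == 1:
        f, p = 0.0, 1.0
    else:
        f, p = sps.f_oneway(*arrays)
    anova = ComparisonResult(
        "one-way ANOVA", tuple(labels), float(f), float(p),
        significant=bool(p < ALPHA),
    )

    tukey_results: List[ComparisonResult] = []
    pairwise: List[ComparisonResult] = []
    if anova.significant:
        values = np.concatenate(arrays)
        codes = np.concatenate([[k] * a.size for k, a in zip(labels, arrays)])
        tk = pairwise_tukeyhsd(values, codes, alpha=ALPHA)
        for (g1, g2), stat, padj in zip(
            combinations(sorted(labels), 2), tk.meandiffs, tk.pvalues
        ):
            tukey_results.append(
                ComparisonResult(
                    "Tukey HSD", (g1, g2), float(stat), float(padj),
                    adjusted=True, significant=bool(padj < ALPHA),
                )
            )
        for (l1, a1), (l2, a2) in combinations(zip(labels, arrays), 2):
            pairwise.append(compare_two_groups(a1, a2, labels=(l1, l2)))
    return {"anova": anova, "tukey": tukey_results, "pairwise": pairwise}


def compare_factorial(df: pd.DataFrame, value: str = "value",
                      group: str = "group", level: str = "level") -> dict:
    """Two-way ANOVA with Sidak-adjusted per-level group comparisons.

    ``df`` is a tidy table with one observation per row; ``group`` holds the
    two phase groups and ``level`` the crossed factor (voltage step or drug
    concentration). Every cell needs ≥ 2 observations. The Sidak family is
    the set of per-level two-group comparisons.

    Returns ``{"anova": DataFrame, "per_level": [ComparisonResult, ...]}``.
    """
    groups = sorted(df[group].unique())
    levels = sorted(df[level].unique())
    if len(groups) != 2:
        raise ValueError("factorial comparison expects exactly 2 groups")
    counts = df.groupby([group, level])[value].count()
    if len(counts) < len(groups) * len(levels) or (counts < 2).any():
        raise ValueError("every group x level cell needs at least 2 observations")

    data = df.rename(columns={value: "y", group: "g", level: "lv"})
    model = ols("y ~ C(g) * C(lv)", data=data).fit()
    anova = sm.stats.anova_lm(model, typ=2)

    k = len(levels)
    per_level = []
    for lv in levels:
        sub = data[data["lv"] == lv]
        a = sub.loc[sub["g"] == groups[0], "y"]
        b = sub.loc[sub["g"] == groups[1], "y"]
        raw = compare_two_groups(a, b, labels=(groups[0], groups[1]))
        padj = sidak_adjust(raw.p_value, k)
        per_level.append(
            ComparisonResult(
                f"t-test (Sidak, level={lv})", raw.groups, raw.statistic,
                padj, adjusted=True, significant=bool(padj < ALPHA),
            )
        )
    return {"anova": anova, "per_level": per_level}


def comparisons_to_frame(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    """Tidy table of comparison results."""
    return pd.DataFrame(
        [
            {
                "test": r.test_name,
                "groups": " vs ".join(map(str, r.groups)),
                "statistic": r.statistic,
                "p_value": r.p_value,
                "adjusted": r.adjusted,
                "significant": r.significant,
            }
            for r in results
        ]
    )
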