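"""Group statistics: ANOVA + Holm-Bonferroni post hoc t-tests, Cohen's d,
Pearson correlations, and Fisher r-to-z comparison of two correlations.

The multiple-comparison layer is the Holm step-down procedure: sort the m raw
p-values ascending, multiply p_(i) by (m - i), enforce monotonicity by running
maximum, cap at 1.  Effect sizes are pooled-SD Cohen's d by default (Glass's
delta, using the control group's SD alone, is selectable).  Two Pearson
coefficients are compared through the variance-stabilizing transform
z' = atanh(r), with z = (z1' - z2') / sqrt(1/(n1-3) + 1/(n2-3)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "EffectSize",
    "CorrelationComparison",
    "holm_bonferroni",
    "anova_with_posthoc",
    "cohens_d",
    "pearson_r",
    "compare_correlations",
]


@dataclass(frozen=True)
class EffectSize:
    d: float
    mean_diff: float
    sd_pooled: float
    n1: int
    n2: int
    variant: str = "pooled"  # pooled | glass


@dataclass(frozen=True)
class CorrelationComparison:
    r1: float
    r2: float
    n1: int
    n2: int
    z1p: float
    z2p: float
    z: float
    p: float


def holm_bonferroni(pvalues: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = p[order] * (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def cohens_d(x1, x2, variant: str = "pooled") -> EffectSize:
    """Standardized mean difference (group1 - group2).

    ``pooled``: SD = sqrt(((n1-1)s1^2 + (n2-1)s2^2)/(n1+n2-2)).
    ``glass``: the second (control) group's SD alone.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    n1, n2 = x1.size, x2.size
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two observations per group")
    if variant == "pooled":
        sd = np.sqrt(((n1 - 1) * x1.var(ddof=1) + (n2 - 1) * x2.var(ddof=1)) / (n1 + n2 - 2))
    elif variant == "glass":
        sd = x2.std(ddof=1)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    if sd == 0:
        raise ValueError("zero pooled variance; d undefined")
    diff = x1.mean() - x2.mean()
    return EffectSize(
        d=float(diff / sd), mean_diff=float(diff), sd_pooled=float(sd),
        n1=n1, n2=n2, variant=variant,
    )


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input; correlation undefined")
    return float(sps.pearsonr(x, y).statistic)


def compare_correlations(r1: float, n1: int, r2: float, n2: int) -> CorrelationComparison:
    """Fisher r-to-z comparison of two independent Pearson correlations."""
    for r in (r1, r2):
        if not -1.0 < r < 1.0:
            raise ValueError("|r| must be < 1 for Fisher's transformation")
    if n1 <= 3 or n2 <= 3:
        raise ValueError("need n > 3 in both samples")
    z1p = float(np.arctanh(r1))
    z2p = float(np.arctanh(r2))
    z = (z1p - z2p) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * sps.norm.sf(abs(z))
    return CorrelationComparison(
        r1=float(r1), r2=float(r2), n1=int(n1), n2=int(n2),
        z1p=z1p, z2p=z2p, z=float(z), p=float(p),
    )


def _select(table: pd.DataFrame, flt: Mapping) -> pd.DataFrame:
    sel = pd.Series(True, index=table.index)
    for col, val in flt.items():
        sel &= table[col] == val
    return table[sel]


def anova_with_posthoc(
    table: pd.DataFrame,
    comparisons: Sequence[tuple[Mapping, Mapping]],
    factors: Sequence[str] = ("group", "age"),
    value_col: str = "value",
    welch: bool = True,
    effect_variant: str = "pooled",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Omnibus ANOVA over the factors plus Holm-corrected planned t-tests.

    ``comparisons`` is a list of ``(filter1, filter2)`` row-filter pairs, e.g.
    ``({"group": "SOD1", "age": 120}, {"group": "WT", "age": 120})``.  Returns
    ``(anova_table, posthoc_table)``; post hoc tests are Welch by default.
    Degenerate comparisons (both groups constant and equal) get t = 0, p = 1.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    usable = [f for f in factors if table[f].nunique() >= 2]
    if usable:
        terms = " * ".join(f"C({f})" for f in usable)
        model = ols(f"{value_col} ~ {terms}", data=table).fit()
        anova_table = sm.stats.anova_lm(model, typ=2).reset_index(names="term")
    else:
        anova_table = pd.DataFrame(columns=["term", "sum_sq", "df", "F", "PR(>F)"])

    rows = []
    for flt1, flt2 in comparisons:
        x1 = _select(table, flt1)[value_col].to_numpy(dtype=float)
        x2 = _select(table, flt2)[value_col].to_numpy(dtype=float)
        if x1.size < 2 or x2.size < 2:
            raise ValueError(f"empty or singleton cell in comparison {flt1} vs {flt2}")
        if x1.var() == 0 and x2.var() == 0 and x1.mean() == x2.mean():
            t, p, d = 0.0, 1.0, 0.0
        else:
            res = sps.ttest_ind(x1, x2, equal_var=not welch)
            t, p = float(res.statistic), float(res.pvalue)
            d = cohens_d(x1, x2, variant=effect_variant).d
        rows.append(
            {
                "comparison": f"{dict(flt1)} vs {dict(flt2)}",
                "n1": x1.size, "n2": x2.size,
                "t": t, "p_raw": p, "cohens_d": d,
            }
        )
    posthoc = pd.DataFrame(rows)
    if not posthoc.empty:
        posthoc["p_holm"] = holm_bonferroni(posthoc["p_raw"].to_numpy())
    return anova_table, posthoc
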