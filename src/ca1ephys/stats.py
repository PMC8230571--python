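"""Per-feature, per-current statistical comparison between genotype groups.

Each (feature, current, age) cell of the comparison grid is tested with a
two-sided Student t-test when both samples pass a Shapiro-Wilk normality
check, and with a Mann-Whitney rank-sum test otherwise.  Ages are tested
independently and no multiple-comparison correction is applied, mirroring
the study's testing scheme; significance is declared at p <= 0.05.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["ComparisonResult", "compare_groups", "run_comparison_grid",
           "ALPHA", "NORMALITY_ALPHA"]

ALPHA = 0.05
NORMALITY_ALPHA = 0.05


@dataclass(frozen=True)
class ComparisonResult:
    feature: str
    current_pA: float | None
    age: str
    test: str              # "t" | "rank-sum" | "untestable"
    statistic: float
    p_value: float
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    normal_a: bool
    normal_b: bool

    @property
    def significant(self) -> bool:
        return np.isfinite(self.p_value) and self.p_value <= ALPHA


import warnings


def _is_normal(x: np.ndarray) -> bool:
    if x.size < 3 or np.allclose(x, x[0]):
        return True  # degenerate: Shapiro undefined; keep the t branch
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sps.shapiro(x).pvalue > NORMALITY_ALPHA


def compare_groups(values_a, values_b, feature: str = "",
                   current_pA: float | None = None, age: str = "",
                   equal_var: bool = True) -> ComparisonResult:
    """Two-sided comparison of one feature between two groups.

    Normality is checked per group (Shapiro-Wilk at alpha 0.05); the rank-sum
    test is used iff either group rejects normality.  Groups with fewer than
    3 finite values are marked untestable.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]

    def summ(x):
        return (float(np.mean(x)) if x.size else float("nan"),
                float(np.std(x, ddof=1)) if x.size > 1 else float("nan"))

    ma, sa = summ(a)
    mb, sb = summ(b)
    if a.size < 3 or b.size < 3:
        return ComparisonResult(feature, current_pA, age, "untestable",
                                float("nan"), float("nan"),
                                ma, sa, a.size, mb, sb, b.size, False, False)
    na, nb = _is_normal(a), _is_normal(b)
    if na and nb:
        if np.allclose(a, ma) and np.allclose(b, mb) and np.isclose(ma, mb):
            stat, p = 0.0, 1.0  # identical degenerate samples
        else:
            stat, p = sps.ttest_ind(a, b, equal_var=equal_var)
        test = "t"
    else:
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        test = "rank-sum"
    return ComparisonResult(feature, current_pA, age, test, float(stat),
                            float(p), ma, sa, a.size, mb, sb, b.size, na, nb)


_CUR_SUFFIX = re.compile(r"^(?P<base>.+?)_(?P<cur>-?\d+)$")


def _age_of(group_label: str) -> str:
    return group_label.split("-", 1)[1] if "-" in group_label else group_label


def _genotype_of(group_label: str) -> str:
    return group_label.split("-", 1)[0]


def run_comparison_grid(table: pd.DataFrame,
                        features: list[str] | None = None,
                        equal_var: bool = True) -> pd.DataFrame:
    """WT-vs-AD comparison for every (feature, current, age) cell.

    ``table`` is a feature table indexed by (cell_id, group_label).  Returns
    a tidy frame with one row per comparison and a ``significant`` marker
    column; an empty table yields an empty grid.
    """
    if table.empty:
        return pd.DataFrame(columns=[
            "feature", "current_pA", "age", "test", "statistic", "p_value",
            "mean_WT", "sd_WT", "n_WT", "mean_AD", "sd_AD", "n_AD",
            "significant"])
    cols = features if features is not None else list(table.columns)
    labels = table.index.get_level_values("group_label")
    ages = sorted({_age_of(g) for g in labels})
    rows = []
    for age in ages:
        wt = table[[_genotype_of(g) == "WT" and _age_of(g) == age
                    for g in labels]]
        ad = table[[_genotype_of(g) == "AD" and _age_of(g) == age
                    for g in labels]]
        if wt.empty or ad.empty:
            continue
        for col in cols:
            m = _CUR_SUFFIX.match(col)
            cur = float(m.group("cur")) if m else None
            base = m.group("base") if m else col
            r = compare_groups(wt[col].to_numpy(), ad[col].to_numpy(),
                               feature=base, current_pA=cur, age=age,
                               equal_var=equal_var)
            rows.append({"feature": r.feature, "current_pA": r.current_pA,
                         "age": r.age, "test": r.test,
                         "statistic": r.statistic, "p_value": r.p_value,
                         "mean_WT": r.mean_a, "sd_WT": r.sd_a, "n_WT": r.n_a,
                         "mean_AD": r.mean_b, "sd_AD": r.sd_b, "n_AD": r.n_b,
                         "significant": r.significant})
    return pd.DataFrame(rows)
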