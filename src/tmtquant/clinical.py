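"""Cohort characteristics table: group summaries and exact tests.

Reproduces the usual "Table 1" of a two-cohort clinical study: numeric
characteristics summarized as mean (SD), categorical ones as count
(percent), with Fisher's exact test on the 2x2 contingency tables and a
configurable two-sample test for continuous characteristics.

Fisher's two-sided p-value is computed by exhaustive enumeration of the
hypergeometric distribution over all tables sharing the observed margins,
summing the probabilities of tables no more likely than the observed one
(with a 1 + 1e-7 relative tolerance guarding floating-point equality at
symmetric tables).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ConfigurationError, DataError


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = cohorts (young, old), columns = trait
    (present, absent)."""

    a: int  # young, present
    b: int  # young, absent
    c: int  # old, present
    d: int  # old, absent

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise DataError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def fisher_exact_2x2(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher's exact p by hypergeometric enumeration.

    Fixing both margins, the first cell follows a hypergeometric
    distribution; the two-sided p sums the probabilities of all attainable
    tables whose probability does not exceed the observed table's
    (relative tolerance 1 + 1e-7).  Degenerate margins (an empty row or
    column) give p = 1.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.total
    row1, col1 = a + b, a + c
    if row1 == 0 or row1 == n or col1 == 0 or col1 == n:
        return 1.0
    k_min = max(0, row1 + col1 - n)
    k_max = min(row1, col1)
    support = np.arange(k_min, k_max + 1)
    pmf = stats.hypergeom.pmf(support, n, col1, row1)
    p_obs = pmf[support == a][0]
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum())
    return min(p, 1.0)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def format_percent(count: int, total: int) -> str:
    """``"3 (38%)"``-style cell with the percent rounded half-up."""
    if total == 0:
        return ""
    return f"{count} ({_round_half_up(100.0 * count / total)}%)"


def summarize_characteristics(
    patients: pd.DataFrame,
    numeric: list[str] | None = None,
    categorical: list[str] | None = None,
    group_col: str = "group",
) -> pd.DataFrame:
    """Group summary table: mean (SD, n-1 denominator) for numeric
    characteristics, count (percent) for categorical levels.

    ``patients`` has one row per patient with a cohort column.  Columns
    not listed are ignored.  Empty groups produce blank cells.
    """
    numeric = numeric or []
    categorical = categorical or []
    groups = list(dict.fromkeys(patients[group_col]))
    rows = []
    for col in numeric:
        row = {"characteristic": col, "type": "numeric"}
        for g in groups:
            vals = patients.loc[patients[group_col] == g, col].dropna()
            if vals.empty:
                row[g] = ""
            else:
                mean = float(vals.mean())
                sd = float(vals.std(ddof=1)) if len(vals) > 1 else float("nan")
                row[g] = f"{mean:.1f} ({sd:.1f})" if np.isfinite(sd) else f"{mean:.1f}"
        rows.append(row)
    for col in categorical:
        levels = list(dict.fromkeys(patients[col].dropna()))
        for level in levels:
            row = {"characteristic": f"{col}: {level}", "type": "categorical"}
            for g in groups:
                sub = patients.loc[patients[group_col] == g, col].dropna()
                row[g] = format_percent(int((sub == level).sum()), len(sub))
            rows.append(row)
    return pd.DataFrame(rows)


def continuous_group_test(
    young: np.ndarray, old: np.ndarray, method: str = "wilcoxon"
) -> float:
    """Two-sided two-sample test for a continuous characteristic.

    ``wilcoxon`` (rank-sum): exact enumeration when the combined sample
    size is at most 20 and there are no ties, otherwise the normal
    approximation with tie correction.  ``welch_t``: Welch's unequal-
    variance t-test.  Completely tied data give p = 1.
    """
    young = np.asarray(young, dtype=float)
    old = np.asarray(old, dtype=float)
    if len(young) < 2 or len(old) < 2:
        raise DataError("each group needs n >= 2")
    combined = np.concatenate([young, old])
    if np.all(combined == combined[0]):
        return 1.0
    if method == "wilcoxon":
        exact = len(combined) <= 20 and len(np.unique(combined)) == len(combined)
        res = stats.mannwhitneyu(
            young, old, alternative="two-sided",
            method="exact" if exact else "asymptotic",
        )
        return float(min(res.pvalue, 1.0))
    if method == "welch_t":
        res = stats.ttest_ind(young, old, equal_var=False)
        return float(res.pvalue)
    raise ConfigurationError(f"unknown method {method!r}")


def clinical_table(
    patients: pd.DataFrame,
    numeric: list[str] | None = None,
    categorical: list[str] | None = None,
    group_col: str = "group",
    continuous_method: str = "wilcoxon",
) -> pd.DataFrame:
    """Full characteristics table with per-row p-values.

    Categorical rows are tested with Fisher's exact test on the
    present/absent 2x2 table of each level; numeric rows with
    ``continuous_method``.  The test used is annotated per row.
    """
    groups = list(dict.fromkeys(patients[group_col]))
    if len(groups) != 2:
        raise DataError("clinical table requires exactly two cohorts")
    g1, g2 = groups
    summary = summarize_characteristics(patients, numeric, categorical, group_col)
    pvals, methods = [], []
    for _, row in summary.iterrows():
        if row["type"] == "numeric":
            col = row["characteristic"]
            p = continuous_group_test(
                patients.loc[patients[group_col] == g1, col].dropna(),
                patients.loc[patients[group_col] == g2, col].dropna(),
                method=continuous_method,
            )
            methods.append(continuous_method)
        else:
            col, level = row["characteristic"].split(": ", 1)
            sub1 = patients.loc[patients[group_col] == g1, col].dropna()
            sub2 = patients.loc[patients[group_col] == g2, col].dropna()
            a = int((sub1 == level).sum())
            c = int((sub2 == level).sum())
            p = fisher_exact_2x2(
                ContingencyTable2x2(a, len(sub1) - a, c, len(sub2) - c)
            )
            methods.append("fisher_exact")
        pvals.append(p)
    summary["p_value"] = pvals
    summary["test"] = methods
    return summary
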