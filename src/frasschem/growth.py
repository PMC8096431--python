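"""Fold-change statistics for the frass competition assay.

Each microbe's growth over the incubation is summarized as the fold
change of its CFU count from inoculation to day 7; treatments are
compared with a Welch t-test (two groups) or one-way ANOVA followed by
Tukey's HSD (three or more groups).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

CFU_COLUMNS = ["organism", "treatment", "replicate", "cfu_initial", "cfu_final"]


def fold_change(cfu_initial: float, cfu_final: float, row_id: str | None = None) -> float:
    """Final over initial CFU count; 0 for extinction, error for zero inoculum."""
    if cfu_initial <= 0:
        where = f" (row {row_id})" if row_id is not None else ""
        raise ValueError(f"initial CFU count must be > 0{where}")
    if cfu_final < 0:
        raise ValueError("final CFU count must be >= 0")
    return cfu_final / cfu_initial


def fold_changes(table: pd.DataFrame, log10: bool = False) -> pd.DataFrame:
    """Per-row fold changes of a CFU table, optionally log10-transformed.

    Counts recorded as 0 (below the plating detection limit) yield a fold
    change of 0 and are flagged in the ``below_detection`` column; in
    log10 mode those rows become -inf and should be handled by the
    caller.
    """
    missing = [c for c in CFU_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"CFU table missing columns: {missing}")
    out = table.copy()
    out["fold_change"] = [
        fold_change(i, f, row_id=str(idx))
        for idx, i, f in zip(table.index, table["cfu_initial"], table["cfu_final"])
    ]
    out["below_detection"] = table["cfu_final"] == 0
    if log10:
        with np.errstate(divide="ignore"):
            out["fold_change"] = np.log10(out["fold_change"])
    return out


def compare_two_groups(fc_a: list[float], fc_b: list[float]) -> tuple[float, float]:
    """Welch two-sided t-test on fold changes of two treatment groups."""
    a = np.asarray(fc_a, dtype=float)
    b = np.asarray(fc_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 replicates per group")
    if a.std() == 0.0 and b.std() == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def compare_many_groups(
    groups: dict[str, list[float]], alpha: float = 0.05
) -> tuple[float, float, pd.DataFrame]:
    """One-way ANOVA plus Tukey HSD over three or more treatment groups.

    Returns the ANOVA F statistic and p-value, and the pairwise Tukey
    table (columns: group1, group2, meandiff, p_adj, lower, upper,
    reject) with studentized-range adjusted p-values.
    """
    if len(groups) < 3:
        raise ValueError(
            "compare_many_groups needs >= 3 groups; use compare_two_groups"
        )
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 replicates")
    names = sorted(groups)
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    F, p = stats.f_oneway(*arrays)
    values = np.concatenate(arrays)
    labels = np.concatenate([[n] * len(groups[n]) for n in names])
    tk = pairwise_tukeyhsd(values, labels, alpha=alpha)
    table = pd.DataFrame(
        tk.summary().data[1:],
        columns=["group1", "group2", "meandiff", "p_adj", "lower", "upper", "reject"],
    )
    # the summary rounds heavily; replace with full-precision columns
    table["meandiff"] = tk.meandiffs
    table["p_adj"] = tk.pvalues
    table["lower"] = tk.confint[:, 0]
    table["upper"] = tk.confint[:, 1]
    table["reject"] = tk.reject
    return float(F), float(p), table
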