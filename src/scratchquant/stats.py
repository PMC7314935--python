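"""Group summaries and comparisons for assay endpoints.

Endpoints are tabulated as (condition, replicate, value) rows.  Summaries
are mean ± standard error per condition.  Comparisons follow the classic
scheme: one-way ANOVA with Tukey's HSD post-hoc test across multiple
groups, and a two-sample t-test (pooled-variance Student by default, Welch
optionally) when exactly two groups are compared; differences are flagged
significant at p <= alpha (default 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .io import ValidationError

__all__ = ["ComparisonResult", "summarize", "compare_groups"]

GROUP_COLUMNS = ("condition", "replicate", "value")


def _validate_table(table: pd.DataFrame, min_per_group: int = 1) -> pd.DataFrame:
    missing = [c for c in ("condition", "value") if c not in table.columns]
    if missing:
        raise ValidationError(f"group table missing columns {missing}")
    if len(table) == 0:
        raise ValidationError("group table is empty")
    bad = table.groupby("condition")["value"].count()
    small = bad[bad < min_per_group]
    if len(small):
        raise ValidationError(
            f"conditions with fewer than {min_per_group} values: {list(small.index)}"
        )
    return table


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Per-condition n, mean and standard error (sd/sqrt(n); 0 when n = 1)."""
    table = _validate_table(table)
    out = (
        table.groupby("condition")["value"]
        .agg(n="count", mean="mean", sd=lambda v: v.std(ddof=1))
        .reset_index()
    )
    out["sem"] = np.where(out["n"] > 1, out["sd"] / np.sqrt(out["n"]), 0.0)
    out.loc[out["n"] == 1, "sd"] = 0.0
    return out[["condition", "n", "mean", "sem"]]


@dataclass(frozen=True)
class ComparisonResult:
    """Omnibus and pairwise comparison of >= 2 conditions.

    ``pairwise`` has columns group1, group2, statistic, p_raw, p_adj,
    significant; for exactly two groups the row is the two-sample t-test
    (p_adj = p_raw), otherwise Tukey-HSD-adjusted p-values (statistic is
    the unadjusted pairwise pooled t).
    """

    anova_f: float
    anova_p: float
    pairwise: pd.DataFrame
    method: str
    alpha: float

    @property
    def significant(self) -> bool:
        return bool(self.anova_p <= self.alpha)


def _t_test(a: np.ndarray, b: np.ndarray, equal_var: bool) -> tuple[float, float]:
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    table: pd.DataFrame, alpha: float = 0.05, equal_var: bool = True
) -> ComparisonResult:
    """Compare conditions: ANOVA F/p plus pairwise (adjusted) p-values.

    With exactly two conditions the pairwise test is the two-sample t-test
    (Student pooled-variance when ``equal_var``, else Welch); with more,
    Tukey's HSD supplies the adjusted pairwise p-values.  Every condition
    needs n >= 2.
    """
    table = _validate_table(table, min_per_group=2)
    groups = {c: g["value"].to_numpy(float) for c, g in table.groupby("condition")}
    names = sorted(groups)
    if len(names) < 2:
        raise ValidationError("need at least 2 conditions to compare")

    f_stat, f_p = sps.f_oneway(*(groups[c] for c in names))

    rows = []
    if len(names) == 2:
        a, b = names
        t, p = _t_test(groups[a], groups[b], equal_var)
        rows.append((a, b, t, p, p, p <= alpha))
        method = "t-test (pooled)" if equal_var else "t-test (Welch)"
    else:
        tukey = pairwise_tukeyhsd(
            endog=table["value"].to_numpy(float),
            groups=table["condition"].to_numpy(),
            alpha=alpha,
        )
        adj = {
            (g1, g2): p
            for g1, g2, p in zip(
                tukey.groupsunique[tukey._multicomp.pairindices[0]],
                tukey.groupsunique[tukey._multicomp.pairindices[1]],
                tukey.pvalues,
            )
        }
        # unadjusted pairwise p from the pooled ANOVA residual (Fisher LSD),
        # the same error term Tukey studentizes — so p_adj >= p_raw holds
        n_total = sum(len(g) for g in groups.values())
        df_resid = n_total - len(names)
        mse = (
            sum(((g - g.mean()) ** 2).sum() for g in groups.values()) / df_resid
        )
        for a, b in combinations(names, 2):
            ga, gb = groups[a], groups[b]
            se = np.sqrt(mse * (1 / len(ga) + 1 / len(gb)))
            t = float((ga.mean() - gb.mean()) / se)
            p_raw = float(2 * sps.t.sf(abs(t), df_resid))
            p_adj = float(adj.get((a, b), adj.get((b, a))))
            rows.append((a, b, t, p_raw, p_adj, p_adj <= alpha))
        method = "ANOVA + Tukey HSD"

    pairwise = pd.DataFrame(
        rows, columns=["group1", "group2", "statistic", "p_raw", "p_adj", "significant"]
    )
    return ComparisonResult(
        anova_f=float(f_stat),
        anova_p=float(f_p),
        pairwise=pairwise,
        method=method,
        alpha=alpha,
    )
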