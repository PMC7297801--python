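"""Condition-level summaries and pairwise significance of binding data.

Box-plot style descriptive statistics per condition (median, quartiles by
linear interpolation, min/max whiskers) and a pairwise two-sided
Mann-Whitney U family with Holm adjustment (Welch's t available as an
alternative; the quartile dialect is recorded in the output metadata).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import QuantificationError

QUARTILE_DIALECT = "linear"   # numpy 'linear' interpolation between order stats
MIN_GROUP_SIZE = 3


@dataclass
class ConditionSummary:
    condition: str
    n_guvs: int
    median: float
    q25: float
    q75: float
    min: float
    max: float


def summarize_condition(values: Sequence[float],
                        condition: str = "") -> ConditionSummary:
    """Order statistics of one condition's binding efficiencies."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise QuantificationError("cannot summarize an empty condition")
    q25, med, q75 = np.percentile(values, [25, 50, 75], method=QUARTILE_DIALECT)
    return ConditionSummary(condition=condition, n_guvs=int(values.size),
                            median=float(med), q25=float(q25), q75=float(q75),
                            min=float(values.min()), max=float(values.max()))


def summary_table(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    rows = [summarize_condition(v, k).__dict__ for k, v in groups.items()]
    df = pd.DataFrame(rows)
    df.attrs["quartile_dialect"] = QUARTILE_DIALECT
    return df


def pairwise_significance(groups: Mapping[str, Sequence[float]],
                          test: str = "mannwhitney") -> pd.DataFrame:
    """All pairwise comparisons with Holm-adjusted two-sided p-values.

    Pairs involving a group with fewer than 3 values are kept in the table
    but flagged (``flag = "too_few"``) with NaN statistics rather than
    silently dropped.
    """
    if len(groups) < 2:
        raise QuantificationError("need at least 2 groups to compare")
    if test not in ("mannwhitney", "welch"):
        raise QuantificationError(f"unknown test {test!r}")
    rows = []
    for (name_a, vals_a), (name_b, vals_b) in combinations(groups.items(), 2):
        a = np.asarray(list(vals_a), dtype=float)
        b = np.asarray(list(vals_b), dtype=float)
        if len(a) < MIN_GROUP_SIZE or len(b) < MIN_GROUP_SIZE:
            rows.append({"group_a": name_a, "group_b": name_b,
                         "statistic": np.nan, "p_raw": np.nan,
                         "flag": "too_few"})
            continue
        if test == "mannwhitney":
            stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        else:
            stat, p = sps.ttest_ind(a, b, equal_var=False)
        rows.append({"group_a": name_a, "group_b": name_b,
                     "statistic": float(stat), "p_raw": float(p), "flag": ""})
    df = pd.DataFrame(rows)
    df["p_adj"] = np.nan
    valid = df["p_raw"].notna()
    if valid.any():
        _, p_adj, *_ = multipletests(df.loc[valid, "p_raw"], method="holm")
        df.loc[valid, "p_adj"] = p_adj
    df.attrs["test"] = test
    df.attrs["adjustment"] = "holm"
    return df[["group_a", "group_b", "statistic", "p_raw", "p_adj", "flag"]]


def boxplot_figure(groups: Mapping[str, Sequence[float]], ylabel: str = "binding efficiency"):
    """Median / 25th-75th percentile box / min-max whisker plot per condition."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.2 + 0.9 * len(groups), 4))
    ax.boxplot([np.asarray(list(v), dtype=float) for v in groups.values()],
               tick_labels=list(groups), whis=(0, 100), showfliers=False)
    ax.set_ylabel(ylabel)
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    return fig
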