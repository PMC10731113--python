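"""Two-group comparison with a normality-gated test choice.

Each parameter is compared between the control and case group by first
testing both groups for normality; if both pass at the chosen alpha the
groups are compared with a two-sided Student's t test, otherwise with a
two-sided Mann-Whitney U test.  Significance is declared below alpha = 0.05
with no multiple-testing correction.

The normality gate defaults to the Lilliefors variant of the
Kolmogorov-Smirnov test (KS against a normal with *estimated* parameters;
the naive KS with estimated parameters is strongly anticonservative).  The
raw KS-against-fitted-normal gate is available via configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

from .config import StatsConfig
from .errors import ValidationError

__all__ = ["GroupComparison", "compare", "compare_cohort", "summarize_cohort"]


@dataclass
class GroupComparison:
    """Outcome of one gated two-group comparison."""

    parameter: str
    n_a: int
    n_b: int
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    normality_p_a: float
    normality_p_b: float
    test: str            # "t" or "mwu"
    statistic: float
    p_value: float
    significant: bool
    alpha: float

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def _normality_p(values: np.ndarray, cfg: StatsConfig) -> float:
    method = cfg.normality
    if method == "lilliefors" and len(values) < 4:
        method = "ks"  # Lilliefors tables need n >= 4
    if method == "lilliefors":
        _, p = lilliefors(values, dist="norm")
        return float(p)
    mu, sd = values.mean(), values.std(ddof=1)
    if sd == 0:
        return 0.0
    _, p = sps.kstest(values, "norm", args=(mu, sd))
    return float(p)


def compare(group_a, group_b, alpha: float = 0.05, parameter: str = "",
            cfg: StatsConfig | None = None) -> GroupComparison:
    """Normality-gated two-sided comparison of two groups of values.

    Both groups need at least 3 values.  ``cfg.force_test`` bypasses the
    gate ("t" or "mwu"); otherwise the t branch is taken iff both groups
    pass the normality test at ``alpha``.
    """
    cfg = cfg or StatsConfig(alpha=alpha)
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValidationError("each group needs at least 3 values")
    p_norm_a = _normality_p(a, cfg)
    p_norm_b = _normality_p(b, cfg)
    if cfg.force_test is not None:
        use_t = cfg.force_test == "t"
    else:
        use_t = p_norm_a > cfg.alpha and p_norm_b > cfg.alpha
    if use_t:
        stat, p = sps.ttest_ind(a, b, equal_var=True)
        test = "t"
    else:
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        test = "mwu"
    ddof_a = 1 if len(a) > 1 else 0
    ddof_b = 1 if len(b) > 1 else 0
    return GroupComparison(
        parameter=parameter, n_a=len(a), n_b=len(b),
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=ddof_a)),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=ddof_b)),
        normality_p_a=p_norm_a, normality_p_b=p_norm_b,
        test=test, statistic=float(stat), p_value=float(p),
        significant=bool(p < cfg.alpha), alpha=cfg.alpha)


def compare_cohort(table: pd.DataFrame, group_col: str = "group",
                   param_col: str = "parameter", value_col: str = "value",
                   cfg: StatsConfig | None = None) -> pd.DataFrame:
    """Run the gated comparison for every parameter of a tidy results table.

    The table must contain exactly two group labels; groups are ordered by
    first appearance.
    """
    cfg = cfg or StatsConfig()
    groups = list(pd.unique(table[group_col]))
    if len(groups) != 2:
        raise ValidationError(f"expected exactly two groups, found {groups}")
    rows = []
    for param, sub in table.groupby(param_col, sort=False):
        a = sub.loc[sub[group_col] == groups[0], value_col].to_numpy()
        b = sub.loc[sub[group_col] == groups[1], value_col].to_numpy()
        rows.append(compare(a, b, parameter=str(param), cfg=cfg).as_dict())
    return pd.DataFrame(rows)


def summarize_cohort(table: pd.DataFrame, group_col: str = "group",
                     param_col: str = "parameter", value_col: str = "value",
                     decimals: int = 2) -> pd.DataFrame:
    """Mean +- sample-SD summary per parameter and group.

    The ``formatted`` column follows the conventional "mean +- SD" layout,
    e.g. ``74.22 +- 6.67``.  A single value gets SD = 0.
    """
    rows = []
    for (param, group), sub in table.groupby([param_col, group_col], sort=False):
        v = sub[value_col].to_numpy(dtype=float)
        mean = float(v.mean())
        sd = float(v.std(ddof=1)) if len(v) > 1 else 0.0
        rows.append({
            param_col: param, group_col: group, "n": len(v),
            "mean": mean, "sd": sd,
            "formatted": f"{mean:.{decimals}f} ± {sd:.{decimals}f}",
        })
    return pd.DataFrame(rows)
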