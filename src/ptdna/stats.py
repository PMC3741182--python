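"""Two-sample comparisons matching the study's reporting conventions.

Group differences (persistence lengths, bound-Pt counts, AFM statistics) are
assessed with a two-sample t test at alpha = 0.05 and reported with
per-group means and t-based 95% confidence half-widths.  Welch's variance
treatment is the default (robust to unequal variances across enantiomer
groups); the pooled variant is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = ["GroupComparison", "two_sample_t"]


@dataclass
class GroupComparison:
    mean_a: float
    mean_b: float
    ci95_a: float
    ci95_b: float
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    significant: bool
    variant: str


def _mean_ci(v: np.ndarray) -> Tuple[float, float]:
    se = v.std(ddof=1) / np.sqrt(v.size)
    return float(v.mean()), float(stats.t.ppf(0.975, v.size - 1) * se)


def two_sample_t(
    a: Sequence[float],
    b: Sequence[float],
    variant: str = "welch",
    alpha: float = 0.05,
) -> GroupComparison:
    """Two-sample t test between groups ``a`` and ``b``.

    ``variant`` is "welch" (default, unequal variances) or "pooled".
    Significance is declared at p < alpha (default 0.05).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if variant not in ("welch", "pooled"):
        raise ValueError("variant must be 'welch' or 'pooled'")
    equal_var = variant == "pooled"
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    if equal_var:
        df = a.size + b.size - 2
    else:
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    mean_a, ci_a = _mean_ci(a)
    mean_b, ci_b = _mean_ci(b)
    p = float(res.pvalue)
    return GroupComparison(
        mean_a=mean_a, mean_b=mean_b, ci95_a=ci_a, ci95_b=ci_b,
        t_statistic=float(res.statistic), degrees_of_freedom=float(df),
        p_value=p, significant=bool(p < alpha), variant=variant,
    )
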