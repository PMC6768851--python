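"""Group comparisons used across the motility analyses.

Rank-sum (Mann-Whitney U) tests with Bonferroni correction for
multi-condition wound-healing rates, Mann-Whitney comparisons of
non-normal cell-speed distributions, unpaired t-tests on normalized
invasion counts, and a generic equal-weighted grouped-value comparison
against a reference group.

Small tie-free samples (min group size <= 8 in auto mode) use the exact
rank-sum null by full enumeration; otherwise the normal approximation
with continuity and tie correction is used. The number of comparisons
``m`` entering the Bonferroni adjustment is always recorded in the
result rather than guessed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from motilitykit.errors import InputError, NormalizationError

__all__ = [
    "GroupResult",
    "rank_sum_test",
    "bonferroni_adjust",
    "unpaired_t_test",
    "normalized_invasion_analysis",
    "grouped_expression_compare",
]

EXACT_MAX_N = 8  # largest min(n_a, n_b) for exact enumeration in auto mode


@dataclass(frozen=True)
class GroupResult:
    """Outcome of a two-group comparison."""

    statistic: float  # U for rank-sum, t for t-tests
    p_raw: float
    p_adjusted: float
    m_comparisons: int
    method: str  # "exact" | "normal-approximation" | "t-test" | "welch-t-test"
    comparison: str = ""


def _as_group(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=np.float64).ravel()
    if arr.size == 0:
        raise InputError(f"group {name!r} is empty")
    if np.isnan(arr).any():
        raise InputError(f"group {name!r} contains NaN")
    return arr


def rank_sum_test(
    group_a,
    group_b,
    mode: str = "auto",
    alternative: str = "two-sided",
) -> GroupResult:
    """Two-sided rank-sum (Mann-Whitney U) test.

    ``mode="auto"`` enumerates the exact null when ``min(n_a, n_b) <= 8``
    and the pooled data are tie-free, else applies the normal
    approximation with continuity correction and tie-corrected variance.
    ``mode="exact"`` / ``mode="approx"`` force the choice. The reported
    statistic is the U of ``group_a``.
    """
    a = _as_group(group_a, "a")
    b = _as_group(group_b, "b")
    if a.size + b.size < 3:
        raise InputError("combined sample size must be >= 3")
    if mode not in ("auto", "exact", "approx"):
        raise InputError(f"unknown mode {mode!r}")

    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    if mode == "exact" or (
        mode == "auto" and min(a.size, b.size) <= EXACT_MAX_N and not has_ties
    ):
        method = "exact"
        res = sps.mannwhitneyu(a, b, alternative=alternative, method="exact")
    else:
        method = "normal-approximation"
        res = sps.mannwhitneyu(
            a, b, alternative=alternative, method="asymptotic", use_continuity=True
        )
    return GroupResult(
        statistic=float(res.statistic),
        p_raw=float(res.pvalue),
        p_adjusted=float(res.pvalue),
        m_comparisons=1,
        method=method,
    )


def bonferroni_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni: each p multiplied by ``m`` (default: count), capped at 1."""
    p = np.asarray(p_values, dtype=np.float64).ravel()
    if p.size and (p.min() < 0 or p.max() > 1):
        raise InputError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise InputError(f"m={m} smaller than the number of p-values ({p.size})")
    return np.minimum(1.0, m * p)


def unpaired_t_test(group_a, group_b, equal_var: bool = True) -> GroupResult:
    """Two-sided unpaired Student t-test (Welch with ``equal_var=False``).

    Two identical-variance-free groups with equal means (all values
    identical across both) report t=0, p=1 by convention.
    """
    a = _as_group(group_a, "a")
    b = _as_group(group_b, "b")
    if a.size < 2 or b.size < 2:
        raise InputError("each group needs n >= 2 for a t-test")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
        t_stat, p = 0.0, 1.0
    else:
        res = sps.ttest_ind(a, b, equal_var=equal_var)
        t_stat, p = float(res.statistic), float(res.pvalue)
    return GroupResult(
        statistic=t_stat,
        p_raw=p,
        p_adjusted=p,
        m_comparisons=1,
        method="t-test" if equal_var else "welch-t-test",
    )


def normalized_invasion_analysis(
    treatment_counts, control_counts
) -> tuple[float, float, GroupResult]:
    """Invasion normalized to controls, with an unpaired t-test.

    Returns ``(ratio, percent_reduction, result)`` where ``ratio`` is
    mean(treatment) / mean(control) over per-field invaded-cell counts
    and ``percent_reduction = 100 * (1 - ratio)``.
    """
    treatment = _as_group(treatment_counts, "treatment")
    control = _as_group(control_counts, "control")
    if (treatment < 0).any() or (control < 0).any():
        raise InputError("invasion counts must be >= 0")
    if control.mean() <= 0:
        raise NormalizationError("control mean count must be > 0")
    ratio = float(treatment.mean() / control.mean())
    result = unpaired_t_test(treatment, control)
    return ratio, 100.0 * (1.0 - ratio), result


def grouped_expression_compare(
    table: pd.DataFrame,
    reference_group: str,
    value_col: str = "value",
    group_col: str = "group",
    bonferroni: bool = False,
    mode: str = "auto",
) -> pd.DataFrame:
    """Rank-sum of each non-reference group against the reference.

    Every sample is weighted equally (the test is run on raw per-sample
    values, never on per-group aggregates). P-values are uncorrected by
    default; ``bonferroni=True`` multiplies by the number of
    comparisons. Returns a DataFrame with one row per comparison:
    ``comparison, statistic, p_raw, p_adjusted, m_comparisons, method``.
    """
    for col in (value_col, group_col):
        if col not in table.columns:
            raise InputError(f"missing column {col!r}")
    groups = list(dict.fromkeys(table[group_col]))
    if reference_group not in groups:
        raise InputError(f"reference group {reference_group!r} not in table")
    if len(groups) < 2:
        raise InputError("need at least two groups")
    ref_values = table.loc[table[group_col] == reference_group, value_col]
    others = [g for g in groups if g != reference_group]
    m = len(others) if bonferroni else 1
    rows = []
    for g in others:
        res = rank_sum_test(
            table.loc[table[group_col] == g, value_col], ref_values, mode=mode
        )
        p_adj = float(bonferroni_adjust([res.p_raw], m=m)[0])
        rows.append(
            {
                "comparison": f"{g} vs {reference_group}",
                "statistic": res.statistic,
                "p_raw": res.p_raw,
                "p_adjusted": p_adj,
                "m_comparisons": m,
                "method": res.method,
            }
        )
    return pd.DataFrame(rows)
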