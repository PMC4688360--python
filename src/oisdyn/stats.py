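"""Group-level statistics on per-animal metrics and per-bin traces.

Two-group comparisons use a two-sided Mann-Whitney U test (exact for small
tie-free samples, tie-corrected normal approximation otherwise) or an
independent-samples t test (Welch by default). Frame-wise trace comparisons
run the Mann-Whitney test per bin at an unadjusted alpha — matching the
field's shaded-frames convention — with an optional Benjamini-Hochberg
correction. Three or more groups use one-way ANOVA with Fisher-LSD
pairwise post-hoc tests on the pooled mean square error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "GroupComparison",
    "FramewiseResult",
    "compare_groups",
    "framewise_compare",
    "anova_lsd",
]


@dataclass
class GroupSummary:
    name: str
    n: int
    mean: float
    sem: float


@dataclass
class GroupComparison:
    metric_name: str
    test_name: str
    statistic: float
    p_value: float
    group_summaries: list[GroupSummary] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value out of [0, 1]")


@dataclass
class FramewiseResult:
    p_values: np.ndarray
    significant_bins: np.ndarray  # indices with p < alpha
    alpha: float
    corrected: bool = False


def _summary(name: str, x: np.ndarray) -> GroupSummary:
    x = np.asarray(x, dtype=float)
    return GroupSummary(
        name=name, n=x.size, mean=float(x.mean()),
        sem=float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else float("nan"),
    )


def compare_groups(
    a,
    b,
    test: str = "mann_whitney",
    metric_name: str = "",
    equal_var: bool = False,
    names: tuple[str, str] = ("A", "B"),
) -> GroupComparison:
    """Two-sided two-group comparison.

    ``test`` is ``"mann_whitney"`` (exact when both n <= 8 and there are no
    ties) or ``"t_test"`` (Welch unless ``equal_var=True``; the variant is
    recorded in ``test_name``).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if test == "mann_whitney":
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
        name = "mann_whitney"
    elif test == "t_test":
        res = sps.ttest_ind(a, b, equal_var=equal_var)
        name = "t_test_pooled" if equal_var else "t_test_welch"
    else:
        raise ValueError(f"unknown test: {test!r}")
    return GroupComparison(
        metric_name=metric_name,
        test_name=name,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        group_summaries=[_summary(names[0], a), _summary(names[1], b)],
    )


def framewise_compare(
    traces_a: np.ndarray,
    traces_b: np.ndarray,
    alpha: float = 0.05,
    correction: str | None = None,
) -> FramewiseResult:
    """Per-bin Mann-Whitney tests across animals.

    ``traces_*`` are (animal, bin) arrays sharing the bin structure. By
    default the per-bin p-values are unadjusted (shaded-frames convention);
    ``correction="bh"`` applies Benjamini-Hochberg.
    """
    traces_a = np.atleast_2d(np.asarray(traces_a, dtype=float))
    traces_b = np.atleast_2d(np.asarray(traces_b, dtype=float))
    if traces_a.shape[1] != traces_b.shape[1]:
        raise ValueError("trace bin structures differ")
    if traces_a.shape[0] < 2 or traces_b.shape[0] < 2:
        raise ValueError("each group needs n >= 2 animals")
    n_bins = traces_a.shape[1]
    p = np.empty(n_bins)
    for k in range(n_bins):
        xa, xb = traces_a[:, k], traces_b[:, k]
        if np.all(xa == xa[0]) and np.all(xb == xb[0]) and xa[0] == xb[0]:
            p[k] = 1.0  # identical constant samples carry no evidence
        else:
            p[k] = sps.mannwhitneyu(xa, xb, alternative="two-sided", method="auto").pvalue
    corrected = False
    p_eval = p
    if correction == "bh":
        p_eval = sps.false_discovery_control(p, method="bh")
        corrected = True
    elif correction is not None:
        raise ValueError(f"unknown correction: {correction!r}")
    return FramewiseResult(
        p_values=p_eval,
        significant_bins=np.flatnonzero(p_eval < alpha),
        alpha=alpha,
        corrected=corrected,
    )


def anova_lsd(
    groups: list[np.ndarray],
    metric_name: str = "",
    names: list[str] | None = None,
) -> tuple[GroupComparison, list[GroupComparison]]:
    """One-way ANOVA with Fisher-LSD pairwise post-hoc comparisons.

    The LSD t statistic for groups i, j uses the pooled within-group mean
    square error: ``t = (mi - mj) / sqrt(MSE (1/ni + 1/nj))`` with
    ``N - k`` degrees of freedom.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("anova_lsd needs >= 3 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    if names is None:
        names = [f"group{i}" for i in range(len(groups))]
    f_res = sps.f_oneway(*groups)
    omnibus = GroupComparison(
        metric_name=metric_name,
        test_name="anova_oneway",
        statistic=float(f_res.statistic),
        p_value=float(f_res.pvalue),
        group_summaries=[_summary(n, g) for n, g in zip(names, groups)],
    )
    n_total = sum(g.size for g in groups)
    k = len(groups)
    df_err = n_total - k
    mse = sum(((g - g.mean()) ** 2).sum() for g in groups) / df_err
    pairwise = []
    for i, j in combinations(range(k), 2):
        gi, gj = groups[i], groups[j]
        se = np.sqrt(mse * (1.0 / gi.size + 1.0 / gj.size))
        if se == 0:
            t = 0.0 if gi.mean() == gj.mean() else np.inf
        else:
            t = (gi.mean() - gj.mean()) / se
        pval = 2.0 * sps.t.sf(abs(t), df_err) if np.isfinite(t) else 0.0
        pairwise.append(
            GroupComparison(
                metric_name=metric_name,
                test_name=f"lsd:{names[i]}-{names[j]}",
                statistic=float(t),
                p_value=float(min(pval, 1.0)),
                group_summaries=[_summary(names[i], gi), _summary(names[j], gj)],
            )
        )
    return omnibus, pairwise
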