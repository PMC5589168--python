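"""Group-level comparison of batch potencies: one-way ANOVA with Fisher-LSD
pairwise verdicts, Bartlett's homogeneity check, CVs, and a seeded
cross-validation subgroup analysis."""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PotencyGroup",
    "PairwiseVerdict",
    "ComparisonResult",
    "CrossValidationResult",
    "coefficient_of_variation",
    "compare_groups",
    "bartlett_check",
    "cross_validate",
    "two_sample_power",
]


@dataclass(frozen=True)
class PotencyGroup:
    """A labelled set of batch potencies on the percent-of-nominal scale."""

    label: str
    values: tuple[float, ...]

    def __init__(self, label: str, values: Sequence[float]):
        object.__setattr__(self, "label", label)
        object.__setattr__(self, "values", tuple(float(v) for v in values))
        if len(self.values) < 2:
            raise ValueError(
                f"group {label!r} needs n ≥ 2 for variance-based statistics"
            )

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1))

    @property
    def cv(self) -> float:
        return coefficient_of_variation(self.values)


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Sample CV in percent: 100 × sd(ddof=1) / mean."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("CV needs at least two values")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(100.0 * arr.std(ddof=1) / mean)


def _cv_or_nan(group: PotencyGroup) -> float:
    try:
        return group.cv
    except ValueError:
        return float("nan")


@dataclass(frozen=True)
class PairwiseVerdict:
    group_a: str
    group_b: str
    mean_difference: float
    t_statistic: float
    p_value: float
    significant: bool


@dataclass
class ComparisonResult:
    """One-way ANOVA across groups plus Fisher-LSD pairwise verdicts."""

    groups: list[PotencyGroup]
    means: dict[str, float]
    cvs: dict[str, float]
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    mse: float
    pairwise: list[PairwiseVerdict]
    bartlett_statistic: float
    bartlett_p: float
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def summary(self) -> str:
        lines = [
            "Group comparison (one-way ANOVA, Fisher LSD at "
            f"{100 * (1 - self.alpha):.0f}% confidence)",
            "",
        ]
        for g in self.groups:
            lines.append(
                f"  {g.label}: n = {g.n}, mean = {g.mean:.1f}%, CV = {self.cvs[g.label]:.1f}%"
            )
        lines.append(
            f"\n  F({self.df_between}, {self.df_within}) = {self.f_statistic:.3f}, "
            f"p = {self.p_value:.4f}"
            + (" (significant)" if self.significant else " (not significant)")
        )
        lines.append(
            f"  Bartlett's variance check: statistic = {self.bartlett_statistic:.2f}, "
            f"p = {self.bartlett_p:.3f}"
        )
        lines.append("\n  Pairwise (Fisher LSD):")
        for v in self.pairwise:
            mark = "*" if v.significant else " "
            lines.append(
                f"   {mark} {v.group_a} vs {v.group_b}: Δ = {v.mean_difference:+.2f}%, "
                f"p = {v.p_value:.4f}"
            )
        return "\n".join(lines)


def compare_groups(
    groups: Sequence[PotencyGroup], alpha: float = 0.05
) -> ComparisonResult:
    """One-way ANOVA F-test across ≥2 groups with Fisher-LSD pairwise tests.

    The LSD tests use the pooled within-group mean square, so for exactly two
    groups the ANOVA F equals the square of the pairwise t statistic.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g.values, dtype=float) for g in groups]
    n_total = sum(a.size for a in arrays)
    k = len(groups)
    grand = np.concatenate(arrays).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_between, df_within = k - 1, n_total - k
    if ss_within == 0 and ss_between == 0:
        raise ValueError("degenerate comparison: no variance within or between groups")
    mse = ss_within / df_within
    if mse == 0:
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = (ss_between / df_between) / mse
        p = float(stats.f.sf(f_stat, df_between, df_within))
    if ss_between == 0:
        f_stat, p = 0.0, 1.0

    pairwise = []
    for ga, gb in itertools.combinations(groups, 2):
        diff = ga.mean - gb.mean
        if mse == 0:
            t_stat = float("inf") if diff != 0 else 0.0
            p_pair = 0.0 if diff != 0 else 1.0
        else:
            se = np.sqrt(mse * (1.0 / ga.n + 1.0 / gb.n))
            t_stat = diff / se
            p_pair = float(2 * stats.t.sf(abs(t_stat), df_within))
        pairwise.append(
            PairwiseVerdict(
                group_a=ga.label, group_b=gb.label, mean_difference=diff,
                t_statistic=float(t_stat), p_value=p_pair,
                significant=p_pair < alpha,
            )
        )

    bart_stat, bart_p = bartlett_check(groups)
    return ComparisonResult(
        groups=list(groups),
        means={g.label: g.mean for g in groups},
        cvs={g.label: _cv_or_nan(g) for g in groups},
        f_statistic=float(f_stat),
        df_between=df_between,
        df_within=df_within,
        p_value=float(p),
        mse=float(mse),
        pairwise=pairwise,
        bartlett_statistic=bart_stat,
        bartlett_p=bart_p,
        alpha=alpha,
    )


def bartlett_check(groups: Sequence[PotencyGroup]) -> tuple[float, float]:
    """Bartlett's test of homogeneity of variances across groups."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g.values, dtype=float) for g in groups]
    if all(a.std(ddof=1) == arrays[0].std(ddof=1) for a in arrays):
        # identical spreads: statistic exactly 0 (scipy would also return ~0)
        if arrays[0].std(ddof=1) == 0:
            return 0.0, 1.0
    stat, p = stats.bartlett(*arrays)
    return float(stat), float(p)


@dataclass
class CrossValidationResult:
    """Randomised subgroup analysis of the reference group against a comparator."""

    subgroups: list[PotencyGroup]
    comparator: PotencyGroup
    partition: list[np.ndarray]  # indices into the reference values
    comparison: ComparisonResult  # all subgroups + comparator
    subgroup_only: ComparisonResult  # subgroups among themselves
    seed: int

    def subgroup_means(self) -> dict[str, float]:
        return {g.label: g.mean for g in self.subgroups}


def cross_validate(
    reference: PotencyGroup,
    comparator: PotencyGroup,
    subgroup_sizes: Sequence[int],
    seed: int,
    alpha: float = 0.05,
) -> CrossValidationResult:
    """Randomly partition the reference group into subgroups and compare.

    The subgroup sizes must partition the reference group exactly.  All
    subgroup-vs-subgroup and subgroup-vs-comparator comparisons are run via
    :func:`compare_groups`; the comparator's data are never resampled.
    """
    sizes = [int(s) for s in subgroup_sizes]
    if any(s < 2 for s in sizes):
        raise ValueError("every subgroup needs n ≥ 2")
    if sum(sizes) != reference.n:
        raise ValueError(
            f"subgroup sizes {sizes} sum to {sum(sizes)}, but reference has "
            f"n = {reference.n}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(reference.n)
    partition = []
    subgroups = []
    offset = 0
    for i, size in enumerate(sizes):
        idx = np.sort(perm[offset: offset + size])
        offset += size
        partition.append(idx)
        label = f"{reference.label}-{chr(ord('A') + i)}"
        subgroups.append(
            PotencyGroup(label, [reference.values[j] for j in idx])
        )
    comparison = compare_groups(subgroups + [comparator], alpha=alpha)
    subgroup_only = compare_groups(subgroups, alpha=alpha)
    return CrossValidationResult(
        subgroups=subgroups,
        comparator=comparator,
        partition=partition,
        comparison=comparison,
        subgroup_only=subgroup_only,
        seed=seed,
    )


def two_sample_power(
    n1: int, n2: int, mean_difference: float, sd: float, alpha: float = 0.05
) -> float:
    """Approximate power of a two-sample t-test (descriptive only).

    Uses the noncentral t distribution with pooled-variance degrees of
    freedom.  Reported for orientation; the published power figure's
    assumptions are not stated, so this is not a comparability surface.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    df = n1 + n2 - 2
    ncp = mean_difference / (sd * np.sqrt(1.0 / n1 + 1.0 / n2))
    t_crit = stats.t.ppf(1 - alpha / 2, df)
    return float(
        stats.nct.sf(t_crit, df, ncp) + stats.nct.cdf(-t_crit, df, ncp)
    )


def groups_from_csv(path) -> list[PotencyGroup]:
    """Read groups from a CSV with columns batch_id, product, relative_percent."""
    df = pd.read_csv(path)
    return [
        PotencyGroup(str(product), sub["relative_percent"].tolist())
        for product, sub in df.groupby("product", sort=False)
    ]


__all__.append("groups_from_csv")
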