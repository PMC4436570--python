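"""Group comparison: mean +/- SE, one-way ANOVA, Tukey HSD, letter display.

The ANOVA F statistic is computed from the definitional sums of squares
(between-group and within-group), with the p-value from the F
distribution.  Pairwise comparisons use Tukey's honestly significant
difference based on the studentized range distribution; unbalanced
designs fall back to the Tukey-Kramer standard error and are flagged.
Compact letters are assigned by the insert-and-absorb algorithm in
ascending order of group means, so the smallest mean receives "a" and
groups sharing any letter are not significantly different.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class GroupSample:
    label: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) < 2:
            raise ValueError(
                f"group {self.label!r}: need >= 2 values for variance-based "
                f"tests, got {len(self.values)}")


def mean_se(group: GroupSample) -> tuple[float, float]:
    """Mean and standard error (sample sd / sqrt(n))."""
    v = np.asarray(group.values, dtype=float)
    return float(v.mean()), float(v.std(ddof=1) / math.sqrt(v.size))


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    ms_within: float
    degenerate: bool = False  # zero within-group variance, nonzero between


def one_way_anova(groups: list[GroupSample]) -> AnovaResult:
    """One-way fixed-effects ANOVA from first-principles sums of squares."""
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(g.values, dtype=float) for g in groups]
    n_total = sum(a.size for a in arrays)
    grand = sum(a.sum() for a in arrays) / n_total

    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b = len(groups) - 1
    df_w = n_total - len(groups)
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w

    if ms_w == 0.0:
        if ss_between == 0.0:
            return AnovaResult(0.0, df_b, df_w, 1.0, 0.0)
        # groups internally constant but different: infinite evidence
        return AnovaResult(math.inf, df_b, df_w, 0.0, 0.0, degenerate=True)

    F = ms_b / ms_w
    p = float(sps.f.sf(F, df_b, df_w))
    return AnovaResult(float(F), df_b, df_w, p, float(ms_w))


@dataclass(frozen=True)
class ComparisonResult:
    anova: AnovaResult
    alpha: float
    labels: tuple[str, ...]
    significant: np.ndarray = field(repr=False)  # boolean pairwise matrix
    letters: dict[str, str] = field(default_factory=dict)
    balanced: bool = True

    @property
    def F(self) -> float:
        return self.anova.F

    @property
    def p(self) -> float:
        return self.anova.p


@lru_cache(maxsize=256)
def _q_critical(alpha: float, k: int, df: int) -> float:
    """Upper quantile of the studentized range (scipy's vetted routine)."""
    return float(sps.studentized_range.ppf(1.0 - alpha, k, df))


def _tukey_significant(groups: list[GroupSample], anova: AnovaResult,
                       alpha: float) -> tuple[np.ndarray, bool]:
    """Pairwise significance matrix under Tukey HSD / Tukey-Kramer."""
    k = len(groups)
    sig = np.zeros((k, k), dtype=bool)
    sizes = [len(g.values) for g in groups]
    balanced = len(set(sizes)) == 1
    if anova.degenerate:
        means = [np.mean(g.values) for g in groups]
        for i in range(k):
            for j in range(i + 1, k):
                sig[i, j] = sig[j, i] = means[i] != means[j]
        return sig, balanced

    q_crit = _q_critical(alpha, k, anova.df_within)
    means = [float(np.mean(g.values)) for g in groups]
    for i in range(k):
        for j in range(i + 1, k):
            se = math.sqrt(anova.ms_within / 2.0
                           * (1.0 / sizes[i] + 1.0 / sizes[j]))
            diff = abs(means[i] - means[j])
            if se > 0:
                sig[i, j] = sig[j, i] = diff / se > q_crit
            else:
                sig[i, j] = sig[j, i] = diff > 0
    return sig, balanced


def _letters_from_matrix(labels: list[str], means: list[float],
                         sig: np.ndarray) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Start from one column containing every group; for each significant
    pair split every column that contains both members; drop columns that
    became subsets of others; name columns in ascending order of their
    smallest member mean.
    """
    k = len(labels)
    order = sorted(range(k), key=lambda i: means[i])
    cols: list[set[int]] = [set(range(k))]
    for a in range(k):
        for b in range(a + 1, k):
            if not sig[a, b]:
                continue
            new_cols = []
            for col in cols:
                if a in col and b in col:
                    new_cols.append(col - {a})
                    new_cols.append(col - {b})
                else:
                    new_cols.append(col)
            # absorb: drop duplicates and proper subsets
            cols = [c for c in new_cols
                    if c and not any(c < d for d in new_cols)]
            dedup = []
            for c in cols:
                if c not in dedup:
                    dedup.append(c)
            cols = dedup
    # order columns by the rank of their smallest-mean member
    rank = {g: r for r, g in enumerate(order)}
    cols.sort(key=lambda c: min(rank[g] for g in c))
    letters = {lab: "" for lab in labels}
    for letter, col in zip(string.ascii_lowercase, cols):
        for g in sorted(col, key=lambda i: rank[i]):
            letters[labels[g]] += letter
    return letters


def tukey_letters(groups: list[GroupSample], alpha: float = 0.05
                  ) -> ComparisonResult:
    """All-pairs Tukey HSD with a compact letter display.

    Groups sharing no letter are exactly the significantly different
    pairs at level ``alpha``.
    """
    if len(groups) == 1:
        g = groups[0]
        trivial = AnovaResult(0.0, 0, len(g.values) - 1, 1.0,
                              float(np.var(g.values, ddof=1)))
        return ComparisonResult(anova=trivial, alpha=alpha,
                                labels=(g.label,),
                                significant=np.zeros((1, 1), dtype=bool),
                                letters={g.label: "a"}, balanced=True)
    anova = one_way_anova(groups)
    sig, balanced = _tukey_significant(groups, anova, alpha)
    labels = [g.label for g in groups]
    means = [float(np.mean(g.values)) for g in groups]
    letters = _letters_from_matrix(labels, means, sig)
    return ComparisonResult(anova=anova, alpha=alpha, labels=tuple(labels),
                            significant=sig, letters=letters,
                            balanced=balanced)
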