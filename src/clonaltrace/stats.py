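"""Statistical toolkit: ANOVA, Duncan's multiple range test, helpers.

The omnibus and pairwise machinery used to compare organ measurements
across growth stages: a normality gate with square-root fallback
transform, one-way ANOVA, Duncan's multiple range test with a compact
letter display (groups sharing a letter are not significantly
different), and Pearson correlation with its t-distribution p-value.

Shapiro–Wilk, the F/t distributions and the studentized range come from
scipy; the Duncan step-down procedure and the insert–absorb letter
algorithm are implemented here (no installed package provides them).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupedSample",
    "AnovaResult",
    "DuncanResult",
    "normality_gate",
    "anova_oneway",
    "duncan_mrt",
    "duncan_critical_range",
    "compact_letter_display",
    "pearson_with_p",
]


@dataclass(frozen=True)
class GroupedSample:
    """Numeric values with group labels, ready for ANOVA / post hoc tests."""

    groups: tuple
    values: tuple

    @classmethod
    def from_arrays(cls, groups, values) -> "GroupedSample":
        groups = tuple(groups)
        values = tuple(float(v) for v in values)
        if len(groups) != len(values):
            raise ValueError("groups and values must have equal length")
        return cls(groups, values)

    def split(self) -> dict:
        out: dict[object, list[float]] = {}
        for g, v in zip(self.groups, self.values):
            out.setdefault(g, []).append(v)
        return {g: np.asarray(v) for g, v in out.items()}


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


@dataclass(frozen=True)
class DuncanResult:
    """Duncan MRT outcome: ranked means, pairwise decisions, letters."""

    means: dict
    letters: dict
    significant: dict  # (group_i, group_j) -> bool
    alpha: float


def normality_gate(
    values, alpha: float = 0.05
) -> tuple[np.ndarray, bool]:
    """Shapiro–Wilk gate with square-root fallback transform.

    Returns ``(values', transformed)``: the data unchanged when
    normality is not rejected at ``alpha``, else square-root transformed
    (requiring non-negative input). A constant vector makes the test
    undefined and passes through with a warning.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3 or np.ptp(x) == 0:
        warnings.warn(
            "normality test undefined (constant or too-short sample); "
            "passing data through untransformed",
            UserWarning,
            stacklevel=2,
        )
        return x, False
    _, p = sps.shapiro(x)
    if p >= alpha:
        return x, False
    if np.any(x < 0):
        raise ValueError(
            "square-root transform requested for data with negative values"
        )
    return np.sqrt(x), True


def anova_oneway(sample: GroupedSample) -> AnovaResult:
    """One-way ANOVA via the classical between/within decomposition."""
    by_group = sample.split()
    k = len(by_group)
    if k < 2:
        raise ValueError("ANOVA requires at least two groups")
    for g, v in by_group.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than two values")
    all_vals = np.asarray(sample.values)
    grand = all_vals.mean()
    n_total = all_vals.size
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in by_group.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in by_group.values())
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0:
        if ss_between == 0:
            return AnovaResult(F=0.0, df_between=df_b, df_within=df_w, p=1.0)
        warnings.warn(
            "zero within-group variance with distinct means; "
            "p reported at the machine floor",
            UserWarning,
            stacklevel=2,
        )
        return AnovaResult(
            F=np.inf, df_between=df_b, df_within=df_w, p=np.nextafter(0, 1)
        )
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(sps.f.sf(F, df_b, df_w))
    return AnovaResult(F=float(F), df_between=df_b, df_within=df_w, p=p)


@lru_cache(maxsize=4096)
def _q_crit(alpha: float, span: int, df: int) -> float:
    """Studentized-range point at Duncan's protection level for a span.

    Duncan's special protection level for a stretch of ``span`` ranked
    means is 1 − (1 − α)^(span − 1).
    """
    protect = 1.0 - (1.0 - alpha) ** (span - 1)
    return float(sps.studentized_range.ppf(1.0 - protect, span, df))


def duncan_critical_range(
    alpha: float, span: int, df: int, mse: float, n: float
) -> float:
    """Duncan least significant range for a stretch of ``span`` means."""
    return _q_crit(alpha, span, df) * np.sqrt(mse / n)


def compact_letter_display(
    order: list, significant: dict
) -> dict:
    """Insert–absorb compact letter display from pairwise decisions.

    ``order`` lists groups by descending mean; ``significant`` maps
    unordered pairs (as ordered tuples following ``order``) to booleans.
    Groups share a letter iff they sit in a common non-significant
    column. Letters run a, b, c, … down the ranked means.
    """
    columns: list[set] = [set(order)]
    for (gi, gj), sig in significant.items():
        if not sig:
            continue
        new_cols: list[set] = []
        for col in columns:
            if gi in col and gj in col:
                new_cols.append(col - {gi})
                new_cols.append(col - {gj})
            else:
                new_cols.append(col)
        # absorb: drop columns contained in another
        columns = [
            c
            for i, c in enumerate(new_cols)
            if c and not any(i != j and c < other or (c == other and i > j)
                             for j, other in enumerate(new_cols))
        ]
    rank = {g: i for i, g in enumerate(order)}
    columns.sort(key=lambda col: min(rank[g] for g in col))
    letters = {g: "" for g in order}
    for letter_i, col in enumerate(columns):
        letter = chr(ord("a") + letter_i)
        for g in order:
            if g in col:
                letters[g] += letter
    return letters


def duncan_mrt(sample: GroupedSample, alpha: float = 0.05) -> DuncanResult:
    """Duncan's multiple range test with compact letter display.

    Group means are ranked; each stretch of ``p`` consecutive ranked
    means is tested against the least significant range built from the
    studentized range at Duncan's protection level 1 − (1 − α)^(p−1),
    with the step-down rule that a stretch inside a non-significant
    stretch is itself non-significant. Unbalanced designs use the
    harmonic mean of the group sizes.
    """
    by_group = sample.split()
    k = len(by_group)
    if k < 2:
        raise ValueError("Duncan's test requires at least two groups")
    anova = anova_oneway(sample)
    df_w = anova.df_within
    ns = np.array([len(v) for v in by_group.values()], dtype=float)
    n_h = len(ns) / (1.0 / ns).sum()
    mse = sum(((v - v.mean()) ** 2).sum() for v in by_group.values()) / df_w
    means = {g: float(v.mean()) for g, v in by_group.items()}
    order = sorted(means, key=means.get, reverse=True)

    significant: dict[tuple, bool] = {}
    protected: list[tuple[int, int]] = []  # non-significant stretches
    for span in range(k, 1, -1):
        rng = duncan_critical_range(alpha, span, df_w, mse, n_h)
        for i in range(0, k - span + 1):
            j = i + span - 1
            pair = (order[i], order[j])
            inside = any(pi <= i and j <= pj for pi, pj in protected)
            diff = means[order[i]] - means[order[j]]
            if inside or diff <= rng:
                significant[pair] = False
                protected.append((i, j))
            else:
                significant[pair] = True
    letters = compact_letter_display(order, significant)
    return DuncanResult(
        means=means, letters=letters, significant=significant, alpha=alpha
    )


def pearson_with_p(x, y) -> tuple[float, float]:
    """Pearson correlation with its t-distribution p-value.

    Requires n ≥ 3 paired observations and non-constant vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if x.size < 3:
        raise ValueError(f"need at least 3 paired observations, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
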