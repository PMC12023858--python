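"""Independent brute-force oracles used to check the main implementations."""

import itertools

import numpy as np
from scipy import stats as sps


def duncan_pairwise_oracle(by_group: dict, alpha: float) -> dict:
    """All-pairs Duncan decisions computed directly from the definition.

    For every pair of groups: the span is their distance in the ranked
    means plus one; the pair is significant iff its mean difference
    exceeds the Duncan least significant range for that span AND no
    enclosing ranked stretch (checked exhaustively here, not by the
    step-down scan) has a difference within its own range.
    """
    means = {g: float(np.mean(v)) for g, v in by_group.items()}
    order = sorted(means, key=means.get, reverse=True)
    k = len(order)
    ns = np.array([len(by_group[g]) for g in order], dtype=float)
    n_h = k / (1.0 / ns).sum()
    df = int(ns.sum()) - k
    mse = sum(
        float(((np.asarray(v) - np.mean(v)) ** 2).sum()) for v in by_group.values()
    ) / df

    crit_cache: dict[int, float] = {}

    def crit(span):
        if span not in crit_cache:
            protect = 1.0 - (1.0 - alpha) ** (span - 1)
            q = sps.studentized_range.ppf(1.0 - protect, span, df)
            crit_cache[span] = q * np.sqrt(mse / n_h)
        return crit_cache[span]

    def stretch_exceeds(i, j):
        return means[order[i]] - means[order[j]] > crit(j - i + 1)

    decisions = {}
    for i, j in itertools.combinations(range(k), 2):
        enclosing_ok = all(
            stretch_exceeds(i2, j2)
            for i2 in range(0, i + 1)
            for j2 in range(j, k)
        )
        decisions[(order[i], order[j])] = enclosing_ok and stretch_exceeds(i, j)
    return decisions


def letters_to_classes(letters: dict) -> set:
    """Letter display → the set of groups sharing each letter."""
    classes: dict[str, set] = {}
    for g, ls in letters.items():
        for letter in ls:
            classes.setdefault(letter, set()).add(g)
    return {frozenset(v) for v in classes.values()}


def clique_classes_oracle(groups, significant: dict) -> set:
    """Letter classes as maximal cliques of the 'not different' graph.

    Independent of the insert–absorb algorithm: enumerates all maximal
    subsets in which no pair is significantly different (Bron–Kerbosch
    by brute force over the power set; fine for ≤ 6 groups).
    """
    groups = list(groups)
    sig = {frozenset(p) for p, s in significant.items() if s}

    def compatible(subset):
        return all(
            frozenset((a, b)) not in sig
            for a, b in itertools.combinations(subset, 2)
        )

    cliques = []
    for r in range(len(groups), 0, -1):
        for combo in itertools.combinations(groups, r):
            if compatible(combo) and not any(
                set(combo) < c for c in cliques
            ):
                cliques.append(set(combo))
    return {frozenset(c) for c in cliques}
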