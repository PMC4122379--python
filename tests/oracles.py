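"""Independent oracles for cross-checking the implementation.

Each oracle recomputes a quantity by a route the package itself never
takes: exhaustive enumeration, sympy nullspaces, or a third-party
reference implementation.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations

import numpy as np

from efmsig.network import MetabolicNetwork, stoichiometric_matrix


def brute_force_efm_supports(net: MetabolicNetwork) -> set[frozenset[str]]:
    """All EFM supports by trying every reaction subset.

    A subset is an EFM support iff the internal S restricted to it has a
    one-dimensional nullspace whose vector is nonzero everywhere and can
    be oriented to satisfy every irreversibility constraint; supports
    that strictly contain another feasible support are discarded.
    """
    import sympy

    rxns = net.reactions
    S = stoichiometric_matrix(net)
    m = S.shape[0]
    feasible: set[frozenset[str]] = set()
    for r in range(1, len(rxns) + 1):
        for subset in combinations(range(len(rxns)), r):
            if m == 0:
                # no internal metabolites: steady state is vacuous, the
                # nullspace is all of R^r; one-dimensional only for r = 1
                if r == 1:
                    feasible.add(frozenset([rxns[subset[0]].id]))
                continue
            sub = sympy.Matrix([[S.iat[i, j] for j in subset] for i in range(m)])
            ns = sub.nullspace()
            if len(ns) != 1:
                continue
            v = ns[0]
            if any(x == 0 for x in v):
                continue  # true support is a smaller subset, found elsewhere
            irrev = [k for k, j in enumerate(subset) if not rxns[j].reversible]
            if irrev and not (all(v[k] > 0 for k in irrev)
                              or all(v[k] < 0 for k in irrev)):
                continue
            feasible.add(frozenset(rxns[j].id for j in subset))
    return {s for s in feasible if not any(o < s for o in feasible)}


def hypergeom_upper_tail_by_enumeration(N: int, K: int, n: int, x: int) -> Fraction:
    """P[X >= x] for X ~ Hypergeom(N, K, n) by enumerating all C(N, n) draws."""
    successes = set(range(K))
    hits = total = 0
    for draw in combinations(range(N), n):
        total += 1
        if len(successes.intersection(draw)) >= x:
            hits += 1
    return Fraction(hits, total)


def bh_adjusted(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values via statsmodels (reference)."""
    from statsmodels.stats.multitest import multipletests
    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]


def venn_regions_by_membership(sets: dict[str, set]) -> dict[tuple[bool, ...], int]:
    """Region counts keyed by the membership pattern of each union element."""
    names = list(sets)
    counts: dict[tuple[bool, ...], int] = {}
    for x in set.union(*sets.values()):
        key = tuple(x in sets[n] for n in names)
        counts[key] = counts.get(key, 0) + 1
    return counts


def plain_t_bh_calls(expr, group_a: str, group_b: str, alpha: float = 0.05):
    """Plain (unmoderated) per-gene two-sample t-test with BH, as an
    independent check that a planted regime is easy."""
    from scipy import stats
    gmat = expr.gene_level()
    a = gmat[expr.samples_in(group_a)].to_numpy()
    b = gmat[expr.samples_in(group_b)].to_numpy()
    t, p = stats.ttest_ind(a, b, axis=1)
    q = bh_adjusted(p)
    return {g: (int(np.sign(t[i])) if q[i] < alpha else 0)
            for i, g in enumerate(gmat.index)}
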