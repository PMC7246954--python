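"""Independent reference implementations used to check the package.

Each oracle recomputes a quantity by a route the package does not use:
exhaustive enumeration, dynamic programming, or closed forms.  They are
deliberately slow and simple.
"""

from __future__ import annotations

import itertools
from scipy.stats import binom, hypergeom

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def lcs_identity(a: str, b: str) -> float:
    """Matches / shorter length under a unit-score global alignment, by DP."""
    if not a or not b:
        return 0.0
    prev = [0] * (len(b) + 1)
    for ca in a:
        cur = [0]
        for j, cb in enumerate(b, 1):
            cur.append(prev[j - 1] + 1 if ca == cb else max(prev[j], cur[-1]))
        prev = cur
    return prev[-1] / min(len(a), len(b))


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by hypergeometric-tail enumeration.

    Sums the probabilities of all tables with the observed margins whose
    probability does not exceed the observed table's (with a relative
    slack for float ties).
    """
    row1 = a + b
    col1 = a + c
    n = a + b + c + d
    p_obs = hypergeom.pmf(a, n, col1, row1)
    total = 0.0
    for x in range(max(0, col1 - (n - row1)), min(row1, col1) + 1):
        p = hypergeom.pmf(x, n, col1, row1)
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(total, 1.0)


def binom_two_sided(k: int, n: int, p: float) -> float:
    """Two-sided exact binomial p, minimum-likelihood definition."""
    p_obs = binom.pmf(k, n, p)
    total = 0.0
    for x in range(n + 1):
        px = binom.pmf(x, n, p)
        if px <= p_obs * (1 + 1e-7):
            total += px
    return min(total, 1.0)


def bh_stepup(pvalues, alpha: float = 0.05):
    """Benjamini-Hochberg step-up rule: boolean rejections in input order."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    k_max = 0
    for rank, i in enumerate(order, 1):
        if pvalues[i] <= rank / m * alpha:
            k_max = rank
    rejected = [False] * m
    for rank, i in enumerate(order, 1):
        if rank <= k_max:
            rejected[i] = True
    return rejected


def parsimony_call(column: tuple[str, str, str]):
    """Minimum-change call for a 3-taxon column by exhaustive enumeration.

    Enumerates all 400 assignments of states to the two internal nodes of
    the rooted tree ((in1, in2), out) — the ingroup ancestor and the root —
    scoring each by the number of changed edges.  A column is informative
    iff all minimum-cost assignments imply the same ingroup-ancestor state
    and the same (possibly empty) set of ingroup-branch events, with no
    change elsewhere.  Returns (ancestral, (from, to) or None, branch or
    None), or None when excluded.
    """
    in1, in2, out = column
    best_cost = None
    interpretations = set()
    for root in AMINO_ACIDS:
        for anc in AMINO_ACIDS:
            cost = (root != anc) + (anc != in1) + (anc != in2) + (root != out)
            if best_cost is None or cost < best_cost:
                best_cost = cost
                interpretations = set()
            if cost == best_cost:
                events = []
                if root != anc:
                    events.append(("stem", root, anc))
                if anc != in1:
                    events.append((1, anc, in1))
                if anc != in2:
                    events.append((2, anc, in2))
                if root != out:
                    events.append(("out", root, out))
                interpretations.add((anc, tuple(sorted(events, key=str))))
    if best_cost > 1 or len(interpretations) != 1:
        return None
    anc, events = next(iter(interpretations))
    if not events:
        return (anc, None, None)
    (branch, src, dst), = events
    if branch not in (1, 2):
        return None
    return (anc, (src, dst), branch)


def select_best_triplet_bruteforce(lookup, species, ds_range=(0.2, 1.0),
                                   out_factor=(1.2, 2.0), out_target=1.5):
    """Exhaustive scoring over all (pair, outgroup) combinations."""
    best = None
    for a, b in itertools.combinations(sorted(species), 2):
        ds = lookup.get((a, b), lookup.get((b, a)))
        if ds is None or not ds_range[0] <= ds <= ds_range[1]:
            continue
        for out in sorted(species):
            if out in (a, b):
                continue
            d1 = lookup.get((a, out), lookup.get((out, a)))
            d2 = lookup.get((b, out), lookup.get((out, b)))
            if d1 is None or d2 is None:
                continue
            if not all(out_factor[0] * ds <= d <= out_factor[1] * ds for d in (d1, d2)):
                continue
            score = (
                abs(ds - ds_range[0]),
                abs(d1 - out_target * ds) + abs(d2 - out_target * ds),
                a, b, out,
            )
            if best is None or score < best[0]:
                best = (score, (a, b, out))
    return None if best is None else best[1]
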