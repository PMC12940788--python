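"""Independent brute-force oracles used by unit and acceptance tests.

Every function here recomputes a quantity from first principles with no
shared code paths with the package implementation, so agreement is an
end-to-end check rather than a tautology.
"""

from fractions import Fraction
from itertools import combinations
from math import comb, exp, log

import numpy as np


# ---------------------------------------------------------------------------
# Ward agglomeration by exhaustive search over pair merges
# ---------------------------------------------------------------------------

def ward_greedy_partitions(X):
    """Partitions after each merge of greedy minimum-ESS-increase Ward.

    At every step evaluates the error-sum-of-squares increase of merging
    each cluster pair directly from the points and merges the minimum.
    Returns the list of partitions (sets of frozensets of point indices)
    from n clusters down to 1.
    """
    X = np.asarray(X, dtype=float)

    def ess(idx):
        pts = X[list(idx)]
        return float(((pts - pts.mean(axis=0)) ** 2).sum())

    clusters = [frozenset([i]) for i in range(len(X))]
    parts = [set(clusters)]
    while len(clusters) > 1:
        best = None
        for a, b in combinations(clusters, 2):
            inc = ess(a | b) - ess(a) - ess(b)
            if best is None or inc < best[0] - 1e-12:
                best = (inc, a, b)
        _, a, b = best
        clusters = [c for c in clusters if c not in (a, b)] + [a | b]
        parts.append(set(clusters))
    return parts


def partitions_from_linkage(Z, n):
    """Partition sequence implied by a scipy linkage matrix."""
    clusters = {i: frozenset([i]) for i in range(n)}
    parts = [set(clusters.values())]
    for step, (i, j, _, _) in enumerate(Z):
        merged = clusters.pop(int(i)) | clusters.pop(int(j))
        clusters[n + step] = merged
        parts.append(set(clusters.values()))
    return parts


# ---------------------------------------------------------------------------
# ARI directly from the contingency-table formula
# ---------------------------------------------------------------------------

def ari_contingency(a, b):
    a, b = list(a), list(b)
    la, lb = sorted(set(a)), sorted(set(b))
    n = len(a)
    table = [[sum(1 for x, y in zip(a, b) if x == u and y == v) for v in lb] for u in la]
    sum_ij = sum(comb(c, 2) for row in table for c in row)
    sum_a = sum(comb(sum(row), 2) for row in table)
    sum_b = sum(comb(sum(col), 2) for col in zip(*table))
    expected = Fraction(sum_a * sum_b, comb(n, 2)) if n > 1 else Fraction(0)
    max_index = Fraction(sum_a + sum_b, 2)
    if max_index == expected:
        return 1.0
    return float(Fraction(sum_ij) - expected) / float(max_index - expected)


# ---------------------------------------------------------------------------
# Fisher exact p by exhaustive enumeration with exact rationals
# ---------------------------------------------------------------------------

def fisher_exact_fraction(table):
    """Two-sided exact p (sum of table probabilities <= observed)."""
    t = [list(map(int, row)) for row in table]
    rows = [sum(r) for r in t]
    cols = [sum(c) for c in zip(*t)]
    n = sum(rows)

    from math import factorial

    def prob(cells):
        num = 1
        for r in rows:
            num *= factorial(r)
        for c in cols:
            num *= factorial(c)
        den = factorial(n)
        for x in cells:
            den *= factorial(x)
        return Fraction(num, den)

    obs = prob([x for row in t for x in row])

    tables = []

    def enumerate_tables(i, col_rem, acc):
        if i == len(rows) - 1:
            if all(v >= 0 for v in col_rem):
                tables.append(acc + list(col_rem))
            return

        def fill(j, rem, partial):
            if j == len(cols) - 1:
                if 0 <= rem <= col_rem[j]:
                    new_rem = [col_rem[q] - (partial + [rem])[q] for q in range(len(cols))]
                    enumerate_tables(i + 1, new_rem, acc + partial + [rem])
                return
            for v in range(min(rem, col_rem[j]) + 1):
                fill(j + 1, rem - v, partial + [v])

        fill(0, rows[i], [])

    enumerate_tables(0, list(cols), [])
    total = sum(prob(cells) for cells in tables if prob(cells) <= obs)
    return float(min(total, Fraction(1)))


# ---------------------------------------------------------------------------
# Cox partial likelihood by direct product formula (no ties) + grid search
# ---------------------------------------------------------------------------

def cox_grid_beta(x, time, event, lo=-5.0, hi=5.0, step=1e-3):
    """Brute-force maximizer of the (tie-free) Cox partial likelihood."""
    x = np.asarray(x, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)

    def pl(beta):
        ll = 0.0
        for i in np.flatnonzero(event == 1):
            risk = time >= time[i]
            ll += beta * x[i] - log(np.exp(beta * x[risk]).sum())
        return ll

    grid = np.arange(lo, hi + step, step)
    vals = [pl(b) for b in grid]
    return float(grid[int(np.argmax(vals))])


# ---------------------------------------------------------------------------
# Kaplan-Meier by the hand product-limit formula
# ---------------------------------------------------------------------------

def km_product_limit(times, events, query):
    """S(query) computed as the explicit product over event times."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    s = 1.0
    for t in sorted(set(times[events == 1])):
        if t > query:
            break
        at_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d / at_risk
    return s


# ---------------------------------------------------------------------------
# log-rank by direct observed-minus-expected tabulation (2 groups)
# ---------------------------------------------------------------------------

def logrank_tabulate(times, events, groups):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    g0 = np.unique(groups)[0]
    o_minus_e, var = 0.0, 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = int(at_risk.sum())
        n0 = int((at_risk & (groups == g0)).sum())
        d = int(((times == t) & (events == 1)).sum())
        d0 = int(((times == t) & (events == 1) & (groups == g0)).sum())
        o_minus_e += d0 - d * n0 / n
        if n > 1:
            var += d * (n0 / n) * (1 - n0 / n) * (n - d) / (n - 1)
    return (o_minus_e ** 2 / var) if var > 0 else 0.0


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank two-sided p by sign-flip enumeration
# ---------------------------------------------------------------------------

def wilcoxon_exact_p(diffs):
    """Exhaustive sign-permutation p for the signed-rank statistic."""
    d = np.asarray([v for v in diffs if v != 0], dtype=float)
    n = len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_plus = ranks[d > 0].sum()
    total = 0
    count = 0
    for mask in range(2 ** n):
        w = sum(ranks[i] for i in range(n) if (mask >> i) & 1)
        total += 1
        # two-sided: as or more extreme in either tail
        mean = n * (n + 1) / 4
        if abs(w - mean) >= abs(w_plus - mean) - 1e-12:
            count += 1
    return count / total
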