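"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from first principles — direct summation, exhaustive
enumeration — and deliberately shares no code path with the package.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def pearson_brute(x, y) -> float:
    """Product-moment correlation by direct summation."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    sx = sum(x)
    sy = sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = math.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))
    return num / den


def chi2_hand(obs) -> float:
    """Sum of (O - E)^2 / E with expected counts from the margins."""
    obs = [[float(v) for v in row] for row in obs]
    n = sum(sum(row) for row in obs)
    row_tot = [sum(row) for row in obs]
    col_tot = [sum(row[j] for row in obs) for j in range(len(obs[0]))]
    stat = 0.0
    for i, row in enumerate(obs):
        for j, o in enumerate(row):
            e = row_tot[i] * col_tot[j] / n
            stat += (o - e) ** 2 / e
    return stat


def ward_brute(X):
    """Exhaustive Ward agglomeration.

    At each step every candidate merge's increase in total within-cluster sum
    of squares (ESS) is evaluated directly from the member coordinates and the
    minimum is taken. Returns a list of (members_a, members_b, height) with
    height = sqrt(2 * delta-ESS), the Euclidean-scale convention under which
    two singletons merge at their Euclidean distance.
    """
    X = np.asarray(X, dtype=float)
    clusters = {i: [i] for i in range(X.shape[0])}
    merges = []
    next_id = X.shape[0]
    while len(clusters) > 1:
        best = None
        for a, b in combinations(sorted(clusters), 2):
            ma = X[clusters[a]].mean(axis=0)
            mb = X[clusters[b]].mean(axis=0)
            na, nb = len(clusters[a]), len(clusters[b])
            d_ess = na * nb / (na + nb) * float(((ma - mb) ** 2).sum())
            if best is None or d_ess < best[0]:
                best = (d_ess, a, b)
        d_ess, a, b = best
        merges.append((frozenset(clusters[a]), frozenset(clusters[b]),
                       math.sqrt(2.0 * d_ess)))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return merges


def linkage_merge_sets(linkage, n: int):
    """Reconstruct each linkage row as (members_a, members_b, height)."""
    members = {i: frozenset([i]) for i in range(n)}
    out = []
    for m, (a, b, h, _) in enumerate(linkage):
        sa, sb = members[int(a)], members[int(b)]
        out.append((sa, sb, float(h)))
        members[n + m] = sa | sb
    return out


def best_two_partition(X):
    """Exhaustive minimum total within-cluster SS over all 2-partitions.

    Returns a boolean membership array for the best split.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]

    def wss(rows):
        sub = X[rows]
        return float(((sub - sub.mean(axis=0)) ** 2).sum())

    best = None
    for mask in range(1, 2 ** (n - 1)):
        side = np.array([(mask >> i) & 1 == 1 for i in range(n)])
        if side.all() or not side.any():
            continue
        total = wss(np.flatnonzero(side)) + wss(np.flatnonzero(~side))
        if best is None or total < best[0]:
            best = (total, side)
    return best[1]


def planted_gene_sample_r(target_r: float, n: int, n_genes: int,
                          rng: np.random.Generator):
    """Directly simulate the planted-gene construction and return sample r's.

    x = r * z + sqrt(1 - r^2) * eps with z, eps iid standard normal; the
    population correlation of x with z is exactly r.
    """
    out = []
    mix = math.sqrt(1.0 - target_r ** 2)
    for _ in range(n_genes):
        z = rng.standard_normal(n)
        x = target_r * z + mix * rng.standard_normal(n)
        out.append(pearson_brute(x, z))
    return np.array(out)


def same_partition(labels_a, labels_b) -> bool:
    """True when two labelings induce the same partition (up to relabeling)."""
    fwd: dict = {}
    bwd: dict = {}
    for a, b in zip(labels_a, labels_b):
        if fwd.setdefault(a, b) != b or bwd.setdefault(b, a) != a:
            return False
    return True
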