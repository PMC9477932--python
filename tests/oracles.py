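"""Independent brute-force oracles used to verify the fast implementations.

Every function here is a direct, exhaustive re-statement of a definition —
pair enumeration for co-occurrence, line walking for runs, flood fill for
zones, all-pairs counting for the AUC, arrangement enumeration for the
exact Mann-Whitney p — deliberately free of any code shared with the
package.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter

import numpy as np

DIRECTIONS = ((0, 1), (1, 0), (1, 1), (1, -1))


def glcm_counts_oracle(levels, mask, direction, distance=1):
    """Symmetric co-occurrence counts by explicit pair enumeration."""
    nr, nc = np.asarray(levels).shape
    dr, dc = direction[0] * distance, direction[1] * distance
    counts: Counter = Counter()
    for r in range(nr):
        for c in range(nc):
            if not mask[r][c]:
                continue
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < nr and 0 <= c2 < nc and mask[r2][c2]:
                counts[(levels[r][c], levels[r2][c2])] += 1
                counts[(levels[r2][c2], levels[r][c])] += 1
    return counts


def glrlm_counts_oracle(levels, mask, direction):
    """Run-length counts by walking every maximal line segment."""
    nr, nc = np.asarray(levels).shape
    dr, dc = direction
    runs: Counter = Counter()
    visited = set()
    for r in range(nr):
        for c in range(nc):
            if not mask[r][c] or (r, c) in visited:
                continue
            pr, pc = r - dr, c - dc
            if 0 <= pr < nr and 0 <= pc < nc and mask[pr][pc] \
                    and levels[pr][pc] == levels[r][c]:
                continue
            g = levels[r][c]
            length = 0
            rr, cc = r, c
            while 0 <= rr < nr and 0 <= cc < nc and mask[rr][cc] \
                    and levels[rr][cc] == g:
                visited.add((rr, cc))
                length += 1
                rr, cc = rr + dr, cc + dc
            runs[(g, length)] += 1
    return runs


def glszm_counts_oracle(levels, mask):
    """Zone counts via breadth-first flood fill over equal-level 8-neighbors."""
    nr, nc = np.asarray(levels).shape
    seen = set()
    zones: Counter = Counter()
    for r in range(nr):
        for c in range(nc):
            if not mask[r][c] or (r, c) in seen:
                continue
            g = levels[r][c]
            queue = [(r, c)]
            seen.add((r, c))
            size = 0
            while queue:
                rr, cc = queue.pop()
                size += 1
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        r2, c2 = rr + dr, cc + dc
                        if (0 <= r2 < nr and 0 <= c2 < nc and (r2, c2) not in seen
                                and mask[r2][c2] and levels[r2][c2] == g):
                            seen.add((r2, c2))
                            queue.append((r2, c2))
            zones[(g, size)] += 1
    return zones


def imc2_oracle(P):
    """IMC2 by direct double summation of HXY and HXY2 (log base 2)."""
    P = np.asarray(P, dtype=float)
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    hxy = 0.0
    hxy2 = 0.0
    for i in range(P.shape[0]):
        for j in range(P.shape[1]):
            if P[i, j] > 0:
                hxy -= P[i, j] * math.log2(P[i, j])
            q = px[i] * py[j]
            if q > 0:
                hxy2 -= q * math.log2(q)
    return math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))


def inn_oracle(zone_counts):
    """Intensity Non-Uniformity Normalized from a {(g, z): count} mapping."""
    nz = sum(zone_counts.values())
    per_gray: Counter = Counter()
    for (g, _z), n in zone_counts.items():
        per_gray[g] += n
    return sum(v ** 2 for v in per_gray.values()) / nz ** 2


def auc_pairs_oracle(scores, labels):
    """AUC by exhaustive positive/negative pair counting (ties half)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def best_product_cutoff_oracle(scores, labels):
    """Max of sensitivity x specificity over every threshold placement."""
    uniq = sorted(set(scores))
    candidates = [uniq[0] - 1.0] + uniq + [uniq[-1] + 1.0]
    best = -1.0
    for t in candidates:
        sens = np.mean([s >= t for s, y in zip(scores, labels) if y == 1])
        spec = np.mean([s < t for s, y in zip(scores, labels) if y == 0])
        best = max(best, sens * spec)
    return best


def mann_whitney_exact_oracle(a, b):
    """Exact two-sided p by enumerating all group assignments of the pooled
    sample (requires no ties)."""
    pooled = list(a) + list(b)
    na = len(a)

    def u_stat(group_a, group_b):
        return sum(1 for x in group_a for y in group_b if x > y)

    u_obs = u_stat(a, b)
    n_total = 0
    n_extreme = 0
    u_mid = na * len(b) / 2.0
    for combo in itertools.combinations(range(len(pooled)), na):
        ga = [pooled[i] for i in combo]
        gb = [pooled[i] for i in range(len(pooled)) if i not in combo]
        u = u_stat(ga, gb)
        n_total += 1
        if abs(u - u_mid) >= abs(u_obs - u_mid) - 1e-12:
            n_extreme += 1
    return n_extreme / n_total


def fisher_exact_oracle(table):
    """Two-sided p by enumerating every table with the observed margins."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def hyper(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    p_obs = hyper(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = hyper(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return total
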