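"""Independent brute-force reference implementations used only by tests.

These deliberately use naive explicit loops (no shared code with the package)
so that each texture/first-order statistic can be checked for exact equality
on small ROIs.
"""

from __future__ import annotations

import numpy as np

NEIGHBORS_26 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]
DIRECTIONS_13 = [d for d in NEIGHBORS_26 if d > (0, 0, 0)]


def _in(shape, v):
    return all(0 <= v[k] < shape[k] for k in range(3))


def gldm_dependence_variance(levels, mask, alpha=0, count_center=True):
    levels = np.asarray(levels)
    mask = np.asarray(mask, bool)
    deps = []
    for v in map(tuple, np.argwhere(mask)):
        dep = 1 if count_center else 0
        for d in NEIGHBORS_26:
            w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            if _in(mask.shape, w) and mask[w] and abs(int(levels[w]) - int(levels[v])) <= alpha:
                dep += 1
        deps.append(dep)
    deps = np.array(deps, float)
    return float(np.mean((deps - deps.mean()) ** 2))


def glrlm_runs(levels, mask, direction):
    """All maximal (level, length) runs along one direction."""
    levels = np.asarray(levels)
    mask = np.asarray(mask, bool)
    runs = []
    for v in map(tuple, np.argwhere(mask)):
        prev = tuple(v[k] - direction[k] for k in range(3))
        if _in(mask.shape, prev) and mask[prev] and levels[prev] == levels[v]:
            continue  # not a run start
        length = 1
        cur = v
        while True:
            nxt = tuple(cur[k] + direction[k] for k in range(3))
            if _in(mask.shape, nxt) and mask[nxt] and levels[nxt] == levels[v]:
                length += 1
                cur = nxt
            else:
                break
        runs.append((int(levels[v]), length))
    return runs


def glrlm_lrhgle(levels, mask):
    vals = []
    for d in DIRECTIONS_13:
        runs = glrlm_runs(levels, mask, d)
        vals.append(np.mean([i * i * j * j for i, j in runs]))
    return float(np.mean(vals))


def glszm_zones(levels, mask):
    """All (level, size) zones by explicit 26-connected flood fill."""
    levels = np.asarray(levels)
    mask = np.asarray(mask, bool)
    seen = np.zeros(mask.shape, bool)
    zones = []
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        lv = int(levels[start])
        stack = [start]
        seen[start] = True
        size = 0
        while stack:
            v = stack.pop()
            size += 1
            for d in NEIGHBORS_26:
                w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
                if _in(mask.shape, w) and mask[w] and not seen[w] and levels[w] == lv:
                    seen[w] = True
                    stack.append(w)
        zones.append((lv, size))
    return zones


def glszm_hglze(levels, mask):
    zones = glszm_zones(levels, mask)
    return float(np.mean([i * i for i, _ in zones]))


def kurtosis(values):
    x = np.asarray(values, float)
    d = x - x.mean()
    return float(np.mean(d**4) / np.mean(d**2) ** 2)


def pairwise_auc(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))


def bh_adjust(p):
    """Sort, cumulative-minimum from the largest, unsort."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


def fisher_2x2(a, b, c, d):
    """Two-sided 2x2 Fisher p by hypergeometric enumeration."""
    from math import comb

    n = a + b + c + d
    r1, c1 = a + b, a + c

    def prob(x):
        return comb(c1, x) * comb(n - c1, r1 - x) / comb(n, r1)

    p_obs = prob(a)
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-7))
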