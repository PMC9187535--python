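"""Independent brute-force reference implementations used only by tests.

Each oracle recomputes a package result by the most literal method
available (explicit loops, exhaustive enumeration, closed forms) so that
agreement is evidence, not tautology.
"""

from itertools import product
from math import comb

import numpy as np


def loop_mean_std(stack: np.ndarray):
    """Per-voxel sample mean and sd (ddof=1) by explicit voxel loops."""
    n, nx, ny, nz = stack.shape
    mean = np.zeros((nx, ny, nz))
    std = np.zeros((nx, ny, nz))
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                vals = [stack[t, i, j, k] for t in range(n)]
                m = sum(vals) / n
                var = sum((v - m) ** 2 for v in vals) / (n - 1)
                mean[i, j, k] = m
                std[i, j, k] = var ** 0.5
    return mean, std


def loop_outlier_flags(scan, lower, upper, brain):
    """Triple-loop outlier detection with strict inequalities."""
    nx, ny, nz = scan.shape
    flags = np.zeros(scan.shape, dtype=bool)
    direction = np.zeros(scan.shape, dtype=np.int8)
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if not brain[i, j, k]:
                    continue
                v = scan[i, j, k]
                if v > upper[i, j, k]:
                    flags[i, j, k] = True
                    direction[i, j, k] = 1
                elif v < lower[i, j, k]:
                    flags[i, j, k] = True
                    direction[i, j, k] = -1
    return flags, direction


def flood_fill_components(mask: np.ndarray):
    """26-connected components by explicit BFS flood fill."""
    visited = np.zeros(mask.shape, dtype=bool)
    comps = []
    neighbours = [d for d in product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]
    for start in zip(*np.nonzero(mask)):
        if visited[start]:
            continue
        comp = []
        queue = [start]
        visited[start] = True
        while queue:
            cur = queue.pop()
            comp.append(cur)
            for d in neighbours:
                nb = tuple(c + o for c, o in zip(cur, d))
                if all(0 <= c < s for c, s in zip(nb, mask.shape)):
                    if mask[nb] and not visited[nb]:
                        visited[nb] = True
                        queue.append(nb)
        comps.append(comp)
    return comps


def size_filtered_mask(mask: np.ndarray, min_voxels: int) -> np.ndarray:
    out = np.zeros(mask.shape, dtype=bool)
    for comp in flood_fill_components(mask):
        if len(comp) >= min_voxels:
            for vox in comp:
                out[vox] = True
    return out


def pairwise_auc(normal_scores, path_scores) -> float:
    """Mann-Whitney AUC: mean over all (normal, pathological) pairs of
    1[p > n] + 0.5 * 1[p == n]."""
    total = 0.0
    for p in path_scores:
        for n in normal_scores:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(normal_scores) * len(path_scores))


def exhaustive_best_thresholds(cases):
    """All (t_low <= t_high) threshold pairs over a candidate grid; returns
    the minimum number of definite false positives achievable under a
    false omission rate of exactly 0, by enumeration.

    ``cases``: (score, truth) pairs with truth in {"normal", "pathological"}.
    """
    scores = sorted({s for s, _ in cases})
    candidates = sorted({0.0, 1.0, *scores, *(min(1.0, s + 1e-9) for s in scores),
                         *(max(0.0, s - 1e-9) for s in scores)})
    best_fp = None
    for lo in candidates:
        for hi in candidates:
            if lo > hi:
                continue
            labelled_normal = [(s, t) for s, t in cases if s < lo]
            fn = sum(1 for _, t in labelled_normal if t == "pathological")
            if fn > 0:  # false omission constraint violated
                continue
            fp = sum(1 for s, t in cases if t == "normal" and s > hi)
            if best_fp is None or fp < best_fp:
                best_fp = fp
    return best_fp


def fisher_two_sided(a, b, c, d) -> float:
    """Two-sided Fisher exact p by full hypergeometric enumeration."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-12))
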