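"""Independent brute-force oracles shared by the test modules.

Each function re-derives a quantity from its definition by enumeration or
naive computation, deliberately avoiding the package's own implementation
paths.
"""

import numpy as np
from scipy import stats
from sympy.utilities.iterables import multiset_permutations

from pmexposure.grouptests import kw_statistic


def direct_bh(p):
    """Step-up definition written out: adj_(i) = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def oracle_kw_pvalue(groups):
    """Exact permutation p via label multiset permutations."""
    pooled = np.concatenate(groups)
    labels = np.concatenate([[k] * len(g) for k, g in enumerate(groups)])
    obs = kw_statistic(groups)
    count = total = 0
    for perm in multiset_permutations(list(labels)):
        perm = np.array(perm)
        gs = [pooled[perm == k] for k in range(len(groups))]
        total += 1
        if kw_statistic(gs) >= obs - 1e-12:
            count += 1
    return count / total


def oracle_stay_windows(t, x, y, eps, min_dur):
    """Naive maximal eps-bounded windows (O(n^3) distance checks)."""
    n = len(t)
    stays = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n:
            w = slice(i, j + 2)
            cx, cy = x[w].mean(), y[w].mean()
            if max((x[w] - cx) ** 2 + (y[w] - cy) ** 2) <= eps**2:
                j += 1
            else:
                break
        if t[j] - t[i] + 1 >= min_dur:
            stays.append((i, j))
            i = j + 1
        else:
            i += 1
    return stays


def random_track(rng, n):
    """Plateaus (stays) joined by drifting runs, with jitter."""
    x, y = [], []
    cx = cy = 0.0
    while len(x) < n:
        if rng.random() < 0.5:
            k = int(rng.integers(3, 40))
            x += list(cx + rng.normal(0, 5, k))
            y += list(cy + rng.normal(0, 5, k))
        else:
            k = int(rng.integers(2, 15))
            step = rng.uniform(20, 120)
            ang = rng.uniform(0, 2 * np.pi)
            for _ in range(k):
                cx += step * np.cos(ang)
                cy += step * np.sin(ang)
                x.append(cx + rng.normal(0, 5))
                y.append(cy + rng.normal(0, 5))
    return np.array(x[:n]), np.array(y[:n])
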