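"""Brute-force enumeration oracles used to check the fast test statistics.

These deliberately re-derive every quantity from first principles (full
enumeration of pairings, sign assignments, or group assignments; Pearson
correlation of ranks) so they share no code path with the implementations
they validate.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
import scipy.stats


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    return float((a @ b) / np.sqrt((a @ a) * (b @ b)))


@lru_cache(maxsize=None)
def _perm_matrix(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.int64)


def spearman_oracle(x, y) -> tuple[float, float]:
    """rho as Pearson of average ranks; exact two-sided p by enumerating all
    n! pairings of y against x (valid for untied inputs)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    rho_obs = _pearson(rx, ry)
    perms = _perm_matrix(len(x))
    ry_perm = ry[perms]  # each row: one pairing
    rc = rx - rx.mean()
    yc = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    rhos = (yc @ rc) / np.sqrt((rc @ rc) * (yc * yc).sum(axis=1))
    p = float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))
    return rho_obs, p


def signed_rank_oracle(before, after) -> float:
    """Exact two-sided signed-rank p over all 2^n sign assignments (zeros
    dropped), using the symmetric doubling rule."""
    d = np.asarray(after, float) - np.asarray(before, float)
    d = d[d != 0]
    if len(d) == 0:
        return 1.0
    ranks = scipy.stats.rankdata(np.abs(d))
    t_obs = ranks[d > 0].sum()
    ts = []
    for signs in itertools.product((0, 1), repeat=len(d)):
        ts.append(sum(r for r, s in zip(ranks, signs) if s))
    ts = np.array(ts, float)
    return float(min(1.0, 2 * min((ts <= t_obs).mean(), (ts >= t_obs).mean())))


def rank_sum_oracle(a, b) -> float:
    """Exact two-sided Mann-Whitney p over all C(n+m, n) group assignments."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n = len(a)
    pooled = np.concatenate([a, b])
    ranks = scipy.stats.rankdata(pooled)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    us = []
    for comb in itertools.combinations(range(len(pooled)), n):
        us.append(ranks[list(comb)].sum() - n * (n + 1) / 2)
    us = np.array(us, float)
    return float(min(1.0, 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())))


def bh_oracle(pvals) -> np.ndarray:
    """Step-up BH adjustment straight from the definition."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


def bray_curtis_oracle(matrix: np.ndarray) -> np.ndarray:
    """d(u, v) = 1 - 2 sum(min(u_i, v_i)) / sum(u_i + v_i), double loop."""
    n = matrix.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            w = np.minimum(matrix[i], matrix[j]).sum()
            denom = (matrix[i] + matrix[j]).sum()
            out[i, j] = 1.0 - 2.0 * w / denom
    return out
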