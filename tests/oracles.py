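"""Independent brute-force reference implementations used only by tests.

Everything here is written as plain per-element loops, deliberately sharing
no code with the package, so agreement is evidence rather than tautology.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_vc_sqrt(V: np.ndarray) -> np.ndarray:
    """Per-entry VC_SQRT with total-sum rescaling."""
    n = V.shape[0]
    r = [sum(V[i][j] for j in range(n)) for i in range(n)]
    W = np.zeros_like(np.asarray(V, float))
    for i in range(n):
        for j in range(n):
            if r[i] > 0 and r[j] > 0:
                W[i, j] = V[i][j] / math.sqrt(r[i] * r[j])
    return W * (np.sum(V) / W.sum())


def brute_expected(V: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Mean contact value per bin separation over unmasked pairs."""
    n = V.shape[0]
    out = np.full(n, np.nan)
    for s in range(n):
        vals = [
            V[i, i + s]
            for i in range(n - s)
            if mask[i] and mask[i + s]
        ]
        if vals:
            out[s] = sum(vals) / len(vals)
    return out


def bin_point_map(blocks, bin_size: int, n_src: int) -> dict[int, int]:
    """Source-bin -> target-bin map for bin-aligned synteny blocks."""
    out = {}
    for b in blocks:
        assert b.src_start % bin_size == 0 and b.src_end % bin_size == 0
        assert b.tgt_start % bin_size == 0 and b.tgt_end % bin_size == 0
        nb = (b.src_end - b.src_start) // bin_size
        for k in range(nb):
            i = b.src_start // bin_size + k
            if b.orientation == "+":
                j = b.tgt_start // bin_size + k
            else:
                j = b.tgt_end // bin_size - 1 - k
            out[i] = j
    return out


def brute_liftover(
    V: np.ndarray,
    mask: np.ndarray,
    blocks,
    bin_size: int,
    n_tgt: int,
    expected: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair remap through bin-aligned blocks; ``expected`` enables the
    distance-decay rescaling (balanced model).  Returns (matrix, bin mask)."""
    n = V.shape[0]
    pmap = bin_point_map(blocks, bin_size, n)
    out = np.zeros((n_tgt, n_tgt))
    tmask = np.zeros(n_tgt, dtype=bool)
    for i, t in pmap.items():
        if mask[i]:
            tmask[t] = True
    for i in range(n):
        for j in range(n):
            if not (mask[i] and mask[j]):
                continue
            if i not in pmap or j not in pmap:
                continue
            ti, tj = pmap[i], pmap[j]
            v = V[i, j]
            if expected is not None:
                s_old, s_new = abs(i - j), abs(ti - tj)
                p_old = expected[s_old]
                p_new = expected[s_new] if s_new < len(expected) else np.nan
                if np.isnan(p_old) or np.isnan(p_new) or p_old <= 0:
                    v = 0.0
                else:
                    v = v * p_new / p_old
            out[ti, tj] += v
    return out, tmask


def brute_d_score(V: np.ndarray, W: np.ndarray, mask_v, mask_w, f: int):
    """Triple-loop D(k, f) with mutual scaling, plus Z-transform."""
    n = V.shape[0]
    valid = [
        [
            V[i, j] > 0 and W[i, j] > 0 and mask_v[i] and mask_v[j]
            and mask_w[i] and mask_w[j]
            for j in range(n)
        ]
        for i in range(n)
    ]
    ta = sum(V[i, j] for i in range(n) for j in range(n) if valid[i][j])
    tb = sum(W[i, j] for i in range(n) for j in range(n) if valid[i][j])
    target = (ta + tb) / 2
    sa, sb = target / ta, target / tb
    d = np.full(n, np.nan)
    for k in range(n):
        vals = []
        for i in range(max(0, k - f), k):
            for j in range(k + 1, min(n - 1, k + f) + 1):
                if valid[i][j]:
                    vals.append(math.log((sa * V[i, j]) / (sb * W[i, j])))
        if vals:
            d[k] = sum(vals) / len(vals)
    z = np.full(n, np.nan)
    fin = ~np.isnan(d)
    if fin.any():
        mu = d[fin].mean()
        sd = d[fin].std()
        z[fin] = (d[fin] - mu) / sd if sd > 0 else 0.0
    return d, z


def brute_mannwhitney_exact(x, y) -> tuple[float, float]:
    """Two-tailed exact Mann-Whitney by full enumeration of group labelings.

    p = 2 * min(P(U <= u_obs), P(U >= u_obs)), capped at 1, where the null
    distribution of U is generated by every C(n1+n2, n1) assignment of the
    pooled values to group x.  Requires no ties.
    """
    x, y = list(x), list(y)
    pooled = x + y
    n1 = len(x)

    def u_stat(xs, ys):
        return sum(1 for a in xs for b in ys if a > b)

    u_obs = u_stat(x, y)
    us = [
        u_stat([pooled[i] for i in comb],
               [pooled[i] for i in range(len(pooled)) if i not in set(comb)])
        for comb in itertools.combinations(range(len(pooled)), n1)
    ]
    lo = sum(u <= u_obs for u in us) / len(us)
    hi = sum(u >= u_obs for u in us) / len(us)
    return float(u_obs), min(1.0, 2 * min(lo, hi))
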