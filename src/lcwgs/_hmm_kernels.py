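"""Numba kernels for the diploid copying HMM.

The hidden state is an ordered template pair (j, k); the transition
factorizes per haplotype as t(j -> j') = c*delta(j, j') + d with
c = 1 - recomb_switch and d = recomb_switch / H, which keeps every lattice
update O(H^2).  All kernels operate on the per-site emission array
E[j, k, s] and use per-site normalization for numerical stability.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def _margins(prev):
    H = prev.shape[0]
    rowsum = np.empty(H)
    colsum = np.zeros(H)
    total = 0.0
    for j in range(H):
        rs = 0.0
        for k in range(H):
            v = prev[j, k]
            rs += v
            colsum[k] += v
        rowsum[j] = rs
        total += rs
    return rowsum, colsum, total


@njit(cache=False)
def _transition_into(prev, out, c, d):
    H = prev.shape[0]
    rowsum, colsum, total = _margins(prev)
    tot = 0.0
    for j in range(H):
        for k in range(H):
            v = c * c * prev[j, k] + c * d * (rowsum[j] + colsum[k]) + d * d * total
            out[j, k] = v
            tot += v
    return tot


@njit(cache=False)
def _transition_emit_into(prev, out, E_s, c, d):
    H = prev.shape[0]
    rowsum, colsum, total = _margins(prev)
    tot = 0.0
    for j in range(H):
        for k in range(H):
            v = (
                c * c * prev[j, k] + c * d * (rowsum[j] + colsum[k]) + d * d * total
            ) * E_s[j, k]
            out[j, k] = v
            tot += v
    return tot


@njit(cache=False)
def forward(E, c, d):
    H, _, S = E.shape
    alphas = np.empty((S, H, H))
    tot = 0.0
    for j in range(H):
        for k in range(H):
            v = E[j, k, 0]
            alphas[0, j, k] = v
            tot += v
    inv = 1.0 / tot
    for j in range(H):
        for k in range(H):
            alphas[0, j, k] *= inv
    for s in range(1, S):
        tot = _transition_emit_into(alphas[s - 1], alphas[s], E[:, :, s], c, d)
        inv = 1.0 / tot
        for j in range(H):
            for k in range(H):
                alphas[s, j, k] *= inv
    return alphas


@njit(cache=False)
def backward(E, c, d):
    H, _, S = E.shape
    betas = np.empty((S, H, H))
    for j in range(H):
        for k in range(H):
            betas[S - 1, j, k] = 1.0
    tmp = np.empty((H, H))
    for s in range(S - 2, -1, -1):
        for j in range(H):
            for k in range(H):
                tmp[j, k] = betas[s + 1, j, k] * E[j, k, s + 1]
        tot = _transition_into(tmp, betas[s], c, d)
        inv = 1.0 / tot
        for j in range(H):
            for k in range(H):
                betas[s, j, k] *= inv
    return betas


@njit(cache=False)
def genotype_posteriors(alphas, betas, templates, m, lik, c, d):
    """Per-site genotype posterior triples from the forward/backward lattices.

    Uses the pre-emission forward message at each site so the genotype
    likelihood enters exactly once, via the emission mixture.
    """
    S, H, _ = alphas.shape
    out = np.empty((S, 3))
    pre = np.empty((H, H))
    for s in range(S):
        if s == 0:
            u = 1.0 / (H * H)
            for j in range(H):
                for k in range(H):
                    pre[j, k] = u
        else:
            _transition_into(alphas[s - 1], pre, c, d)
        g00 = 0.0
        g01 = 0.0
        g10 = 0.0
        g11 = 0.0
        for j in range(H):
            aj = templates[j, s]
            for k in range(H):
                p = pre[j, k] * betas[s, j, k]
                if aj == 0:
                    if templates[k, s] == 0:
                        g00 += p
                    else:
                        g01 += p
                else:
                    if templates[k, s] == 0:
                        g10 += p
                    else:
                        g11 += p
        tot = 0.0
        for g in range(3):
            v = (
                g00 * m[0, 0, g]
                + g01 * m[0, 1, g]
                + g10 * m[1, 0, g]
                + g11 * m[1, 1, g]
            ) * lik[s, g]
            out[s, g] = v
            tot += v
        inv = 1.0 / tot
        for g in range(3):
            out[s, g] *= inv
    return out


@njit(cache=False)
def sample_path(alphas, c, d, uniforms):
    """Backward-sample one state path from the forward lattice."""
    S, H, _ = alphas.shape
    path = np.empty((S, 2), dtype=np.int64)

    tot = 0.0
    for j in range(H):
        for k in range(H):
            tot += alphas[S - 1, j, k]
    target = uniforms[S - 1] * tot
    acc = 0.0
    done = False
    for j in range(H):
        if done:
            break
        for k in range(H):
            acc += alphas[S - 1, j, k]
            if acc >= target:
                path[S - 1, 0] = j
                path[S - 1, 1] = k
                done = True
                break
    if not done:
        path[S - 1, 0] = H - 1
        path[S - 1, 1] = H - 1

    for s in range(S - 2, -1, -1):
        jn = path[s + 1, 0]
        kn = path[s + 1, 1]
        tot = 0.0
        for j in range(H):
            wj = d + (c if j == jn else 0.0)
            for k in range(H):
                wk = d + (c if k == kn else 0.0)
                tot += alphas[s, j, k] * wj * wk
        target = uniforms[s] * tot
        acc = 0.0
        done = False
        for j in range(H):
            if done:
                break
            wj = d + (c if j == jn else 0.0)
            for k in range(H):
                wk = d + (c if k == kn else 0.0)
                acc += alphas[s, j, k] * wj * wk
                if acc >= target:
                    path[s, 0] = j
                    path[s, 1] = k
                    done = True
                    break
        if not done:
            path[s, 0] = H - 1
            path[s, 1] = H - 1
    return path
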