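"""Numba kernels for the phylogenetic (pruning) likelihood.

The tree is passed as flat postorder arrays; transition matrices are
reconstructed inside the kernel from a cached eigendecomposition of the
rate matrix, so a full likelihood evaluation is a single compiled call.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False, fastmath=True)
def prune_site_likelihoods(order, child1, child2, data_idx, blen,
                           evals, umat, uinv, tip_partials, freqs):
    """Per-pattern site likelihoods and log-scalers at the root.

    order : int32[nnodes] postorder node ids (root last)
    child1, child2 : int32[nnodes], -1 when absent
    data_idx : int32[nnodes], row into tip_partials or -1
    blen : float64[nnodes] branch length above each node, in substitutions
    evals, umat, uinv : eigendecomposition of the rate matrix
    tip_partials : float64[nrows, npat, nstates]
    freqs : float64[nstates] stationary frequencies

    Returns (site_lik[npat], log_scale[npat]).
    """
    nnodes = order.shape[0]
    npat = tip_partials.shape[1]
    ns = tip_partials.shape[2]
    partial = np.empty((nnodes, npat, ns))
    scale = np.zeros((nnodes, npat))
    pmat = np.empty((ns, ns))
    tmp = np.empty((ns, ns))

    for oi in range(nnodes):
        node = order[oi]
        c1 = child1[node]
        c2 = child2[node]
        di = data_idx[node]
        if c1 < 0:
            continue  # tips are read directly from tip_partials below
        first = True
        for ci in range(2):
            c = c1 if ci == 0 else c2
            if c < 0:
                continue
            # P = U diag(exp(evals * t)) Uinv for this child branch
            t = blen[c]
            for i in range(ns):
                for j in range(ns):
                    tmp[i, j] = umat[i, j] * np.exp(evals[j] * t)
            for i in range(ns):
                for j in range(ns):
                    acc = 0.0
                    for k in range(ns):
                        acc += tmp[i, k] * uinv[k, j]
                    pmat[i, j] = acc if acc > 0.0 else 0.0
            # child partial source: tip rows are read in place
            if child1[c] < 0:
                src = tip_partials[data_idx[c]]
            else:
                src = partial[c]
            for p in range(npat):
                for i in range(ns):
                    acc = 0.0
                    for j in range(ns):
                        acc += pmat[i, j] * src[p, j]
                    if first:
                        partial[node, p, i] = acc
                    else:
                        partial[node, p, i] *= acc
            if first:
                if child1[c] >= 0:
                    for p in range(npat):
                        scale[node, p] = scale[c, p]
                else:
                    for p in range(npat):
                        scale[node, p] = 0.0
                first = False
            else:
                if child1[c] >= 0:
                    for p in range(npat):
                        scale[node, p] += scale[c, p]
        if di >= 0:
            for p in range(npat):
                for s in range(ns):
                    partial[node, p, s] *= tip_partials[di, p, s]
        # rescale to avoid underflow
        for p in range(npat):
            m = 0.0
            for s in range(ns):
                if partial[node, p, s] > m:
                    m = partial[node, p, s]
            if 0.0 < m < 1e-120:
                for s in range(ns):
                    partial[node, p, s] /= m
                scale[node, p] += np.log(m)

    root = order[nnodes - 1]
    site_lik = np.empty(npat)
    log_scale = np.empty(npat)
    if child1[root] < 0:  # degenerate single-tip tree
        src = tip_partials[data_idx[root]]
        for p in range(npat):
            acc = 0.0
            for s in range(ns):
                acc += freqs[s] * src[p, s]
            site_lik[p] = acc
            log_scale[p] = 0.0
        return site_lik, log_scale
    for p in range(npat):
        acc = 0.0
        for s in range(ns):
            acc += freqs[s] * partial[root, p, s]
        site_lik[p] = acc
        log_scale[p] = scale[root, p]
    return site_lik, log_scale


@njit(cache=False, fastmath=True)
def prune_loglik(order, child1, child2, data_idx, blen,
                 evals, umat, uinv, tip_partials, freqs, weights):
    """Total log-likelihood (single rate category)."""
    site_lik, log_scale = prune_site_likelihoods(
        order, child1, child2, data_idx, blen, evals, umat, uinv,
        tip_partials, freqs)
    total = 0.0
    for p in range(site_lik.shape[0]):
        if site_lik[p] <= 0.0:
            return -np.inf
        total += weights[p] * (np.log(site_lik[p]) + log_scale[p])
    return total


@njit(cache=False, fastmath=True)
def log_likelihood_from_site(site_lik, log_scale, weights):
    total = 0.0
    for p in range(site_lik.shape[0]):
        if site_lik[p] <= 0.0:
            return -np.inf
        total += weights[p] * (np.log(site_lik[p]) + log_scale[p])
    return total
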