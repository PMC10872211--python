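"""Independent oracles used by the tests.

These deliberately avoid the code paths they check: relatedness by
memoized coancestry recursion and by gene-dropping Monte Carlo, and the
covariance tensor by explicit elementwise double loops.
"""

import numpy as np
from numba import njit

from wildg.pedigree import UNKNOWN, Pedigree


def kinship_amatrix(ped: Pedigree) -> np.ndarray:
    """A by memoized kinship recursion: a_ij = 2 f(i, j)."""
    sire, dam = ped.sire, ped.dam
    memo = {}

    def f(i, j):
        if i == UNKNOWN or j == UNKNOWN:
            return 0.0
        if i > j:
            i, j = j, i
        key = (i, j)
        if key in memo:
            return memo[key]
        if i == j:
            v = 0.5 * (1.0 + f(sire[i], dam[i]))
        else:
            v = 0.5 * (f(i, sire[j]) + f(i, dam[j]))
        memo[key] = v
        return v

    n = ped.n
    A = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            # f(i,i) = (1 + F_i)/2, so 2 f gives the a_ii = 1 + F_i diagonal too
            A[i, j] = A[j, i] = 2.0 * f(i, j)
    return A


@njit(cache=True)
def _gene_drop_counts(sire, dam, n_drops, seed):
    """Accumulate allele-sharing counts by gene dropping.

    Returns C where C[i, j] counts matching (slot, slot) allele pairs over
    drops: E[C_ij / n_drops] = 4 * kinship(i, j) for i != j, and
    E[diag] = 2 + 2 F_i (self pairs always match).
    """
    np.random.seed(seed)
    n = sire.shape[0]
    C = np.zeros((n, n))
    al = np.zeros((n, 2), dtype=np.int64)
    # counting-sort workspace over allele labels (< 2n + 2)
    nlab = 2 * n + 2
    head = np.full(nlab, -1, dtype=np.int64)
    nxt = np.zeros(2 * n, dtype=np.int64)
    for _ in range(n_drops):
        lab = 0
        for i in range(n):
            for k in range(2):
                p = sire[i] if k == 0 else dam[i]
                if p == UNKNOWN:
                    al[i, k] = lab
                    lab += 1
                else:
                    al[i, k] = al[p, np.random.randint(0, 2)]
        # group (individual, slot) entries by allele label
        for L in range(lab):
            head[L] = -1
        for i in range(n):
            for k in range(2):
                e = 2 * i + k
                L = al[i, k]
                nxt[e] = head[L]
                head[L] = e
        for L in range(lab):
            e1 = head[L]
            while e1 != -1:
                i1 = e1 // 2
                e2 = e1
                while e2 != -1:
                    i2 = e2 // 2
                    C[i1, i2] += 1.0
                    if i1 != i2:
                        C[i2, i1] += 1.0
                    e2 = nxt[e2]
                e1 = nxt[e1]
    return C


def gene_drop_amatrix(ped: Pedigree, n_drops: int = 100_000, seed: int = 0) -> np.ndarray:
    """Monte Carlo estimate of A from allele sharing."""
    C = _gene_drop_counts(ped.sire, ped.dam, n_drops, seed)
    A = C / (2.0 * n_drops)
    # diagonal: the two self slot-pairs always match (2 per drop); the
    # cross-slot pair matches with probability F_i, so a_ii = 1 + F_i
    for i in range(ped.n):
        A[i, i] = (C[i, i] - 2.0 * n_drops) / n_drops + 1.0
    return A


def brute_force_tensor(G_list):
    """Covariance tensor by explicit loops over matrix elements.

    Returns (S, alphas, eigentensor matrices) using the sqrt-2
    off-diagonal convention, built without any vectorization helpers.
    """
    m = len(G_list)
    n = G_list[0].shape[0]
    pairs = [(i, i) for i in range(n)] + [
        (i, j) for i in range(n) for j in range(i + 1, n)
    ]
    q = len(pairs)
    V = np.zeros((m, q))
    for k, G in enumerate(G_list):
        for c, (i, j) in enumerate(pairs):
            V[k, c] = G[i, j] if i == j else np.sqrt(2.0) * G[i, j]
    mean = V.mean(axis=0)
    S = np.zeros((q, q))
    for a in range(q):
        for b in range(q):
            s = 0.0
            for k in range(m):
                s += (V[k, a] - mean[a]) * (V[k, b] - mean[b])
            S[a, b] = s / (m - 1)
    w, E = np.linalg.eigh(S)
    order = np.argsort(w)[::-1]
    w = w[order]
    E = E[:, order]
    tensors = []
    for c in range(q):
        M = np.zeros((n, n))
        for cc, (i, j) in enumerate(pairs):
            if i == j:
                M[i, i] = E[cc, c]
            else:
                M[i, j] = M[j, i] = E[cc, c] / np.sqrt(2.0)
        tensors.append(M)
    return S, w, tensors
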