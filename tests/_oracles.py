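"""Shared independent oracles and generators for the test suite.

Everything here is written straight from the definitions with plain Python
loops, deliberately independent of the package's vectorized implementations.
"""

import numpy as np

from pspcp import RESIDUE_ORDER, StandardizedProfile


def random_profile(rng, L):
    """A random valid row-stochastic L x 20 profile (Dirichlet rows)."""
    A = rng.dirichlet(np.ones(20) * rng.uniform(0.2, 5.0), size=L)
    return StandardizedProfile("random", A, origin="pssm")


def naive_descriptor(A, h, w, lam):
    """Straight-from-the-definitions descriptor vector."""
    L, R = A.shape[0], h.shape[0]
    d = [[sum(A[i][j] * h[r][j] for j in range(20)) for r in range(R)]
         for i in range(L)]
    f = [sum(A[i][j] for i in range(L)) / L for j in range(20)]
    u = [[sum(d[i][r] * d[i + k][r] for i in range(L - k)) / (L - k)
          for r in range(R)] for k in range(1, lam + 1)]
    denom = sum(f) + w * sum(u[k][r] for k in range(lam) for r in range(R))
    q = [x / denom for x in f]
    for r in range(R):
        for k in range(lam):
            q.append(w * u[k][r] / denom)
    return np.array(q)


def naive_ampseaac(sequence, h, w, lam):
    """Independent amphiphilic pseudo-amino-acid composition of a raw
    sequence (no profile machinery): counts plus lagged property products."""
    L, R = len(sequence), h.shape[0]
    idx = [RESIDUE_ORDER.index(aa) for aa in sequence]
    f = [idx.count(j) / L for j in range(20)]
    u = [[sum(h[r][idx[i]] * h[r][idx[i + k]] for i in range(L - k)) / (L - k)
          for r in range(R)] for k in range(1, lam + 1)]
    denom = sum(f) + w * sum(u[k][r] for k in range(lam) for r in range(R))
    q = [x / denom for x in f]
    for r in range(R):
        for k in range(lam):
            q.append(w * u[k][r] / denom)
    return np.array(q)


def indicator_pearson(tp, tn, fp, fn):
    """MCC oracle: Pearson correlation of the paired binary indicators."""
    truth = [1] * (tp + fn) + [0] * (fp + tn)
    pred = [1] * tp + [0] * fn + [1] * fp + [0] * tn
    return np.corrcoef(truth, pred)[0, 1]
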