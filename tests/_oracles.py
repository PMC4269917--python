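"""Independently coded, loop-based oracles for the message-passing update.

Kept deliberately naive (scalar loops, literal formulas) and separate
from the vectorized implementation they check.
"""

import math

import numpy as np


def oracle_normalize(M):
    M = np.asarray(M, float)
    n_r, n_c = M.shape
    out = np.zeros_like(M)
    for i in range(n_r):
        for j in range(n_c):
            zr = zc = 0.0
            r = M[i, :]
            if n_c > 1 and np.std(r, ddof=1) > 0:
                zr = (M[i, j] - r.mean()) / np.std(r, ddof=1)
            c = M[:, j]
            if n_r > 1 and np.std(c, ddof=1) > 0:
                zc = (M[i, j] - c.mean()) / np.std(c, ddof=1)
            out[i, j] = (zr + zc) / math.sqrt(2.0)
    return out


def oracle_tanimoto(X, Y):
    X, Y = np.asarray(X, float), np.asarray(Y, float)
    out = np.zeros((X.shape[0], Y.shape[1]))
    for i in range(X.shape[0]):
        for j in range(Y.shape[1]):
            d = float(X[i, :] @ Y[:, j])
            den = math.sqrt(max((X[i, :] ** 2).sum() + (Y[:, j] ** 2).sum()
                                - abs(d), 0.0))
            out[i, j] = d / den if den > 0 else 0.0
    return out


def oracle_single_step(W0, P0, C0, alpha):
    W = oracle_normalize(W0)
    P = oracle_normalize(P0)
    C = oracle_normalize(C0)
    R = oracle_tanimoto(P, W)
    A = oracle_tanimoto(W, C)
    return (1 - alpha) * W + alpha * (R + A) / 2.0
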