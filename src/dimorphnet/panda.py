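"""Message-passing reconstruction of a TF-by-gene regulatory network.

Starting from a binary motif prior W0, a TF-TF interaction matrix P0
and a gene-gene co-expression matrix C0, the algorithm alternately
estimates how *responsible* cooperating TFs are for an edge and how
*available* co-expressed genes make it, nudging all three networks
toward consensus with learning rate alpha.  Similarities are continuous
Tanimoto scores; inputs are first brought onto a common Z-score scale.
The final W is reported in Z-score units as the edge-score matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


def normalize_network(M) -> np.ndarray:
    """(Z_rows + Z_cols) / sqrt(2) with sample (n-1) standard deviations.

    A zero-variance row (or column) contributes 0 so the surviving
    component enters scaled by 1/sqrt(2); entries degenerate in both
    directions become 0.  Affine-invariant: normalize(a*M + b) equals
    normalize(M) for a > 0.
    """
    M = np.asarray(M, dtype=float)
    if M.size == 0:
        raise ValueError("empty matrix")
    if not np.isfinite(M).all():
        raise ValueError("non-finite entries")
    with np.errstate(invalid="ignore", divide="ignore"):
        rm = M.mean(axis=1, keepdims=True)
        rs = M.std(axis=1, ddof=1, keepdims=True) if M.shape[1] > 1 else np.zeros_like(rm)
        cm = M.mean(axis=0, keepdims=True)
        cs = M.std(axis=0, ddof=1, keepdims=True) if M.shape[0] > 1 else np.zeros_like(cm)
        zr = np.where(rs > 0, (M - rm) / rs, 0.0)
        zc = np.where(cs > 0, (M - cm) / cs, 0.0)
    return (zr + zc) / np.sqrt(2.0)


def tanimoto(X, Y) -> np.ndarray:
    """Continuous Tanimoto similarity of the rows of X with the columns of Y.

    S_ij = d_ij / sqrt(|X_i|^2 + |Y_j|^2 - |d_ij|) with d = X @ Y;
    entries with zero denominator are 0.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if not (np.isfinite(X).all() and np.isfinite(Y).all()):
        raise ValueError("non-finite input")
    d = X @ Y
    xn = np.einsum("ij,ij->i", X, X)
    yn = np.einsum("ij,ij->j", Y, Y)
    # |d_ij| <= (|X_i|^2 + |Y_j|^2)/2, so the argument is non-negative and
    # vanishes only where d itself vanishes; in-place ops avoid temporaries
    den = np.abs(d)
    den *= -1.0
    den += xn[:, None]
    den += yn[None, :]
    np.maximum(den, 0.0, out=den)
    np.sqrt(den, out=den)
    with np.errstate(invalid="ignore", divide="ignore"):
        np.divide(d, den, out=d, where=den > 0)
    d[den == 0] = 0.0
    return d


def coexpression(values) -> np.ndarray:
    """Pearson correlation of genes across samples.

    Zero-variance genes get 0 off-diagonal and 1 on the diagonal.
    """
    X = np.asarray(values, dtype=float)
    if X.shape[1] < 3:
        raise ValueError("co-expression needs >= 3 samples")
    sd = X.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(X)
    C = np.atleast_2d(C)
    bad = sd == 0
    if bad.any():
        C[bad, :] = 0.0
        C[:, bad] = 0.0
    np.fill_diagonal(C, 1.0)
    return np.nan_to_num(C, nan=0.0)


def _offdiag_sd(M: np.ndarray) -> np.ndarray:
    """Per-row sample (ddof=1) sd of off-diagonal entries; 0 if < 2 entries."""
    n = M.shape[0]
    if n < 3:
        return np.zeros(n)
    diag = np.diagonal(M)
    s1 = M.sum(axis=1) - diag
    s2 = np.einsum("ij,ij->i", M, M) - diag**2
    m = n - 1  # off-diagonal count
    mean = s1 / m
    var = (s2 - m * mean**2) / (m - 1)
    return np.sqrt(np.maximum(var, 0.0))


def _update_diagonal(M: np.ndarray, alpha: float, step: int) -> None:
    np.fill_diagonal(M, _offdiag_sd(M) * M.shape[0] * np.exp(2.0 * alpha * step))


@dataclass
class RegulatoryNetwork:
    tfs: list[str]
    genes: list[str]
    edge_scores: np.ndarray
    converged: bool
    iterations: int

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edge_scores, index=self.tfs, columns=self.genes)


def panda(
    prior,
    ppi,
    coexpr,
    alpha: float = 0.1,
    tol: float = 1e-3,
    max_iter: int = 200,
) -> RegulatoryNetwork:
    """Run message passing to convergence and return the edge-score matrix.

    Per iteration: responsibility R = T(P, W) and availability
    A = T(W, C) are averaged into W with learning rate alpha; P and C
    are then re-estimated from the updated W by Tanimoto self-similarity
    with the diagonal refilled from the off-diagonal spread (times the
    matrix dimension and exp(2*alpha*step), keeping self-similarity from
    dominating).  The loop stops when the mean absolute change of W
    drops below ``tol`` or after ``max_iter`` iterations, in which case
    the network is returned unconverged with a warning.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must be in (0, 1]")
    if isinstance(prior, pd.DataFrame):
        tf_names = list(prior.index)
        gene_names = list(prior.columns)
        if isinstance(ppi, pd.DataFrame):
            ppi = ppi.reindex(index=tf_names, columns=tf_names)
        if isinstance(coexpr, pd.DataFrame):
            coexpr = coexpr.reindex(index=gene_names, columns=gene_names)
    else:
        tf_names = [f"tf{i}" for i in range(np.asarray(prior).shape[0])]
        gene_names = [f"g{j}" for j in range(np.asarray(prior).shape[1])]
    W0 = np.asarray(prior, dtype=float)
    P0 = np.asarray(ppi, dtype=float)
    C0 = np.asarray(coexpr, dtype=float)
    n_tf, n_gene = W0.shape
    if P0.shape != (n_tf, n_tf) or C0.shape != (n_gene, n_gene):
        raise ValueError("dimension mismatch between prior, ppi and coexpression")

    W = normalize_network(W0)
    P = normalize_network(P0)
    C = normalize_network(C0)
    hamming = np.inf
    step = 0
    while step < max_iter and hamming > tol:
        R = tanimoto(P, W)
        A = tanimoto(W, C)
        W_new = (1.0 - alpha) * W + alpha * 0.5 * (R + A)
        hamming = float(np.abs(W_new - W).mean())
        W = W_new
        P_hat = tanimoto(W, W.T)
        _update_diagonal(P_hat, alpha, step)
        P *= 1.0 - alpha
        P_hat *= alpha
        P += P_hat
        P = 0.5 * (P + P.T)
        C_hat = tanimoto(W.T, W)
        _update_diagonal(C_hat, alpha, step)
        C *= 1.0 - alpha
        C_hat *= alpha
        C += C_hat
        C = 0.5 * (C + C.T)
        step += 1
    converged = bool(hamming <= tol)
    if not converged:
        warnings.warn(f"message passing not converged after {step} iterations "
                      f"(hamming={hamming:.3g} > tol={tol:.3g})", stacklevel=2)
    return RegulatoryNetwork(tfs=tf_names, genes=gene_names, edge_scores=W,
                             converged=converged, iterations=step)
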