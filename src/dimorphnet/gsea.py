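"""Weighted Kolmogorov-Smirnov gene-set enrichment with set permutation.

The same machinery scores differential expression (genes x samples),
differential targeting (genes x networks, values = in-degree), and
TF-specific targeting (genes x networks, values = one TF's edge
weights).  Genes are ranked by a signal-to-noise metric between the two
column classes; a running sum walks the ranked list, rising by the
weighted hit mass and falling by the miss penalty; significance comes
from random same-size gene sets drawn from the ranked universe.  The
signed convention reports female-(first-class-)enriched sets as
-log10(FDR) > 0 and male-enriched sets as +log10(FDR) < 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass
class RankedList:
    genes: np.ndarray    # ids, ordered by metric descending
    metrics: np.ndarray  # signal-to-noise values in the same order

    def __len__(self) -> int:
        return self.genes.size


def rank_metric(table: pd.DataFrame, classes: Sequence) -> RankedList:
    """Signal-to-noise ranking of rows between two column classes.

    metric = (mu_A - mu_B) / (s_A + s_B), each s floored at 0.2*|mu| (or
    0.2 when mu = 0), the classic GSEA variance floor.  Classes compare
    in sorted label order; ties in the metric break by gene id so the
    ranking is deterministic.
    """
    labels = np.asarray(classes)
    if labels.shape[0] != table.shape[1]:
        raise ValueError("class labels must align with columns")
    levels = sorted(pd.unique(labels))
    if len(levels) != 2:
        raise ValueError("exactly two classes required")
    a, b = levels
    if (labels == a).sum() < 2 or (labels == b).sum() < 2:
        raise ValueError("each class needs >= 2 columns")
    xa = table.loc[:, labels == a].to_numpy(dtype=float)
    xb = table.loc[:, labels == b].to_numpy(dtype=float)

    def _floored(x):
        mu = x.mean(axis=1)
        s = x.std(axis=1, ddof=1)
        floor = np.where(mu == 0, 0.2, 0.2 * np.abs(mu))
        return mu, np.maximum(s, floor)

    mu_a, s_a = _floored(xa)
    mu_b, s_b = _floored(xb)
    metric = (mu_a - mu_b) / (s_a + s_b)
    genes = np.asarray(table.index, dtype=object)
    order = np.lexsort((genes, -metric))
    return RankedList(genes=genes[order], metrics=metric[order])


def enrichment_score(ranked: RankedList, gene_set, weight_p: float = 1.0
                     ) -> tuple[float, np.ndarray]:
    """Weighted KS enrichment score and the full running sum.

    Hits add |metric|^p normalized by the total hit mass; misses
    subtract 1/(N - N_hits).  ES is the running-sum value of maximal
    absolute deviation from zero (signed; first such position on ties).
    """
    members = set(gene_set)
    hit = np.fromiter((g in members for g in ranked.genes), bool, len(ranked))
    n_hit = int(hit.sum())
    if n_hit == 0:
        raise ValueError("gene set disjoint from the ranked universe")
    running = _running_sum(ranked.metrics, hit, weight_p)
    es = float(running[np.abs(running).argmax()])
    return es, running


def _running_sum(metrics: np.ndarray, hit: np.ndarray, weight_p: float) -> np.ndarray:
    N = metrics.size
    n_hit = int(hit.sum())
    w = np.abs(metrics) ** weight_p
    nr = w[hit].sum()
    inc = np.empty(N)
    if N == n_hit:
        inc[:] = w / nr if nr > 0 else 1.0 / N
        return np.cumsum(inc)
    inc[~hit] = -1.0 / (N - n_hit)
    inc[hit] = w[hit] / nr if nr > 0 else 1.0 / n_hit
    return np.cumsum(inc)


def _es_batch(metrics: np.ndarray, idx: np.ndarray, weight_p: float) -> np.ndarray:
    """ES for a batch of index sets (rows of ``idx``) on one ranked list."""
    B, k = idx.shape
    N = metrics.size
    w = np.abs(metrics) ** weight_p
    inc = np.full((B, N), -1.0 / (N - k) if N > k else 0.0)
    hit_w = w[idx]
    nr = hit_w.sum(axis=1, keepdims=True)
    safe = np.where(nr > 0, nr, 1.0)
    vals = np.where(nr > 0, hit_w / safe, 1.0 / k)
    rows = np.repeat(np.arange(B), k)
    inc[rows, idx.ravel()] = vals.ravel()
    run = np.cumsum(inc, axis=1)
    pos = np.abs(run).argmax(axis=1)
    return run[np.arange(B), pos]


def _null_index_sets(rng: np.random.Generator, N: int, k: int, n_perm: int) -> np.ndarray:
    """Same-size random subsets; exhaustive when the universe allows it."""
    if comb(N, k) <= n_perm:
        return np.array(list(combinations(range(N), k)), dtype=int)
    out = np.empty((n_perm, k), dtype=int)
    chunk = max(1, min(n_perm, 50_000_000 // max(N, 1)))
    for lo in range(0, n_perm, chunk):
        hi = min(lo + chunk, n_perm)
        out[lo:hi] = np.argsort(rng.random((hi - lo, N)), axis=1)[:, :k]
    return out


def gsea(table: pd.DataFrame, classes: Sequence,
         gene_sets: Mapping[str, Sequence[str]], n_perm: int = 1000,
         seed: int = 0, min_size: int = 15, max_size: int = 500,
         weight_p: float = 1.0) -> pd.DataFrame:
    """Gene-set permutation GSEA over an entity-by-column table.

    For each surviving set (universe-intersected size within
    [min_size, max_size]) the observed ES is compared with the ES of
    ``n_perm`` random same-size sets on the fixed ranked list (all
    subsets, when the universe is small enough to enumerate).  NES is
    ES over the mean same-sign null magnitude, the nominal p the
    same-sign null tail, and the FDR the sign-stratified NES-ratio.
    Deterministic for a given seed.
    """
    ranked = rank_metric(table, classes)
    universe = set(ranked.genes)
    pos_of = {g: i for i, g in enumerate(ranked.genes)}
    surviving: dict[str, list[int]] = {}
    for name, members in gene_sets.items():
        inside = sorted({g for g in members if g in universe})
        if min_size <= len(inside) <= max_size:
            surviving[name] = sorted(pos_of[g] for g in inside)
    if not surviving:
        raise ValueError("no gene sets survive size filtering")

    N = len(ranked)
    rng = np.random.default_rng(seed)
    null_by_size: dict[int, np.ndarray] = {}
    obs_es, null_es = {}, {}
    for name, idx in surviving.items():
        k = len(idx)
        if k not in null_by_size:
            null_by_size[k] = _es_batch(
                ranked.metrics, _null_index_sets(rng, N, k, n_perm), weight_p)
        obs_es[name] = _es_batch(ranked.metrics,
                                 np.array([idx], dtype=int), weight_p)[0]
        null_es[name] = null_by_size[k]

    # per-set normalization of observed and null ES by same-sign null mean
    rows = []
    pooled_null_nes = []
    for name in surviving:
        es = obs_es[name]
        nulls = null_es[name]
        pos_mean = nulls[nulls > 0].mean() if (nulls > 0).any() else np.nan
        neg_mean = np.abs(nulls[nulls < 0]).mean() if (nulls < 0).any() else np.nan
        nes = _normalize_es(es, pos_mean, neg_mean)
        null_nes = np.where(nulls >= 0,
                            nulls / pos_mean if np.isfinite(pos_mean) else 0.0,
                            nulls / neg_mean if np.isfinite(neg_mean) else 0.0)
        pooled_null_nes.append(null_nes)
        if es >= 0:
            same = nulls[nulls >= 0]
            p_nom = float((same >= es).sum() / same.size) if same.size else 1.0
        else:
            same = nulls[nulls <= 0]
            p_nom = float((same <= es).sum() / same.size) if same.size else 1.0
        rows.append((name, len(surviving[name]), es, nes, p_nom))
    pooled = np.concatenate(pooled_null_nes)
    result = pd.DataFrame(rows, columns=["set", "size", "es", "nes", "nominal_p"])

    obs_nes = result["nes"].to_numpy()
    fdr = np.ones(len(result))
    n_pos_obs = (obs_nes >= 0).sum()
    n_neg_obs = (obs_nes < 0).sum()
    n_pos_null = (pooled >= 0).sum()
    n_neg_null = (pooled < 0).sum()
    for i, nes in enumerate(obs_nes):
        if nes > 0:
            num = (pooled >= nes).sum() / n_pos_null if n_pos_null else 0.0
            den = (obs_nes >= nes).sum() / n_pos_obs
        elif nes < 0:
            num = (pooled <= nes).sum() / n_neg_null if n_neg_null else 0.0
            den = (obs_nes <= nes).sum() / n_neg_obs
        else:
            fdr[i] = 1.0
            continue
        fdr[i] = min(1.0, num / den) if den > 0 else 1.0
    result["fdr_q"] = fdr
    result["direction"] = np.where(result["es"] >= 0, "A_enriched", "B_enriched")
    floor = 1.0 / (n_perm + 1)
    q = np.maximum(fdr, floor)
    result["signed_score"] = np.where(result["es"] >= 0, -np.log10(q), np.log10(q))
    return result.sort_values("signed_score", ascending=False,
                              kind="stable").reset_index(drop=True)


def _normalize_es(es: float, pos_mean: float, neg_mean: float) -> float:
    if es > 0:
        return es / pos_mean if np.isfinite(pos_mean) and pos_mean > 0 else 0.0
    if es < 0:
        return es / neg_mean if np.isfinite(neg_mean) and neg_mean > 0 else 0.0
    return 0.0


def signed_significance(results: pd.DataFrame, n_perm: int = 1000) -> pd.Series:
    """Per-set signed -log10 FDR: positive = first-class (female) enriched.

    FDR values of 0 are clamped to 1/(n_perm + 1) so scores stay finite.
    """
    floor = 1.0 / (n_perm + 1)
    q = np.maximum(results["fdr_q"].to_numpy(), floor)
    signed = np.where(results["direction"] == "A_enriched", -np.log10(q), np.log10(q))
    return pd.Series(signed, index=results["set"], name="signed_score")
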