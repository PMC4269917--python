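"""Edge-level comparison of two network ensembles and derived summaries.

The sex-specific edge caller follows three criteria: an absolute
difference in mean edge score of at least 0.25, an FDR below 1e-5 from
an unpaired pooled t-test across the per-ensemble score distributions,
and a mean edge score above zero in at least one ensemble (edges with
negative mean weight in both are unlikely to be real).  Degree tables
summarize targeting per gene (in-degree) or per TF (out-degree), and a
complete-linkage clustering of the per-edge t-statistics exposes
block structure in the rewiring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .ensembles import NetworkEnsemble
from .expression_stats import bh_fdr, pooled_ttest


def edge_differential(ens_a: NetworkEnsemble, ens_b: NetworkEnsemble) -> pd.DataFrame:
    """Per-edge means, mean difference, pooled t, p and BH q (A vs B)."""
    if ens_a.tfs != ens_b.tfs or ens_a.genes != ens_b.genes:
        raise ValueError("ensembles must share TF and gene universes")
    if ens_a.n_networks < 2 or ens_b.n_networks < 2:
        raise ValueError("each ensemble needs >= 2 networks")
    t, p = pooled_ttest(ens_a.scores, ens_b.scores)
    mean_a = ens_a.scores.mean(axis=1)
    mean_b = ens_b.scores.mean(axis=1)
    idx = ens_a.edge_labels()
    return pd.DataFrame({
        "mean_a": mean_a,
        "mean_b": mean_b,
        "diff": mean_a - mean_b,
        "t_stat": t,
        "p_value": p,
        "fdr_q": bh_fdr(p),
    }, index=idx)


@dataclass
class SexSpecificSubnetwork:
    label: str
    edges: pd.DataFrame  # subset of the edge table, (tf, gene) index

    @property
    def target_genes(self) -> set[str]:
        return set(self.edges.index.get_level_values("gene"))

    @property
    def tf_set(self) -> set[str]:
        return set(self.edges.index.get_level_values("tf"))


def select_sex_specific_edges(table: pd.DataFrame, diff_min: float = 0.25,
                              q_max: float = 1e-5, mean_min: float = 0.0
                              ) -> tuple[SexSpecificSubnetwork, SexSpecificSubnetwork]:
    """Apply the three-criterion edge caller to an edge table.

    A-specific: diff >= diff_min, q < q_max, max(mean_a, mean_b) > mean_min;
    B-specific symmetric with diff <= -diff_min.
    """
    if not np.isfinite([diff_min, q_max, mean_min]).all():
        raise ValueError("thresholds must be finite")
    strong = (table["fdr_q"] < q_max) & \
        (np.maximum(table["mean_a"], table["mean_b"]) > mean_min)
    a_mask = strong & (table["diff"] >= diff_min)
    b_mask = strong & (table["diff"] <= -diff_min)
    return (SexSpecificSubnetwork("A_specific", table[a_mask]),
            SexSpecificSubnetwork("B_specific", table[b_mask]))


def calibrate_edge_thresholds(table: pd.DataFrame, q_max: float = 1e-5,
                              target_fraction: tuple[float, float] = (0.01, 0.05),
                              grid: Sequence[float] = (0.5, 0.4, 0.3, 0.25, 0.2,
                                                       0.15, 0.1, 0.05, 0.0),
                              ) -> float:
    """Pick ``diff_min`` so each subnetwork holds 1-5% of all edges.

    Walks a decreasing grid of difference cutoffs and returns the first
    for which both subnetworks' selected fractions fall inside the
    target band; if none does, returns the cutoff whose worse-side
    fraction is closest to the band.
    """
    n = len(table)
    best, best_err = grid[0], np.inf
    lo, hi = target_fraction
    for diff_min in grid:
        sub_a, sub_b = select_sex_specific_edges(table, diff_min=diff_min, q_max=q_max)
        fracs = (len(sub_a.edges) / n, len(sub_b.edges) / n)
        err = max(max(lo - f, f - hi, 0.0) for f in fracs)
        if err == 0.0:
            return diff_min
        if err < best_err:
            best, best_err = diff_min, err
    return best


def targeted_gene_sets(sub_a: SexSpecificSubnetwork, sub_b: SexSpecificSubnetwork) -> dict:
    """Overlap of the genes targeted by the two sex-specific subnetworks.

    A gene counted as shared may still be regulated by different TFs in
    the two subnetworks; only target identity is compared here.
    """
    ta, tb = sub_a.target_genes, sub_b.target_genes
    return {
        "a_only": sorted(ta - tb),
        "b_only": sorted(tb - ta),
        "shared": sorted(ta & tb),
        "counts": (len(ta - tb), len(tb - ta), len(ta & tb)),
    }


def fisher_enrichment(query_genes: Iterable[str], universe: Iterable[str],
                      gene_sets: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """One-sided hypergeometric (upper-tail Fisher) enrichment per gene set."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query_genes)
    if not query <= universe:
        raise ValueError("query genes must be a subset of the universe")
    N, n = len(universe), len(query)
    rows = []
    for name, members in gene_sets.items():
        members = set(members) & universe
        k = len(members & query)
        p = float(stats.hypergeom.sf(k - 1, N, len(members), n)) if members else 1.0
        rows.append((name, len(members), k, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "p_value"])
    out["fdr_q"] = bh_fdr(out["p_value"])
    return out.sort_values("p_value", kind="stable").reset_index(drop=True)


@dataclass
class DegreeTable:
    axis: str                 # "gene_in" or "tf_out"
    values: pd.DataFrame      # entity x network


def degree_table(ens: NetworkEnsemble, axis: str) -> DegreeTable:
    """Sum of edge weights into each gene (gene_in) or out of each TF (tf_out)."""
    if ens.scores.size == 0:
        raise ValueError("empty ensemble")
    cube = ens.scores.reshape(len(ens.tfs), len(ens.genes), ens.n_networks)
    cols = [f"net{c:03d}" for c in range(ens.n_networks)]
    if axis == "gene_in":
        vals = pd.DataFrame(cube.sum(axis=0), index=ens.genes, columns=cols)
    elif axis == "tf_out":
        vals = pd.DataFrame(cube.sum(axis=1), index=ens.tfs, columns=cols)
    else:
        raise ValueError("axis must be 'gene_in' or 'tf_out'")
    return DegreeTable(axis=axis, values=vals)


def tf_specific_table(ens: NetworkEnsemble, tf: str) -> pd.DataFrame:
    """One TF's edge weights: genes by networks."""
    if tf not in ens.tfs:
        raise KeyError(f"unknown TF {tf!r}")
    i = ens.tfs.index(tf)
    g = len(ens.genes)
    block = ens.scores[i * g:(i + 1) * g, :]
    cols = [f"net{c:03d}" for c in range(ens.n_networks)]
    return pd.DataFrame(block, index=ens.genes, columns=cols)


@dataclass
class EdgeClustering:
    matrix: pd.DataFrame      # gene x TF t-statistics
    row_order: list[str]
    col_order: list[str]
    row_linkage: np.ndarray
    col_linkage: np.ndarray


def _correlation_distance(X: np.ndarray) -> np.ndarray:
    """1 - Pearson between rows; constant rows get correlation 0."""
    sd = X.std(axis=1, ddof=1)
    if (sd == 0).any():
        warnings.warn(f"{int((sd == 0).sum())} constant rows: correlation set to 0",
                      stacklevel=3)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(X)
    C = np.atleast_2d(np.nan_to_num(C, nan=0.0))
    np.fill_diagonal(C, 1.0)
    D = 1.0 - np.clip(C, -1.0, 1.0)
    np.fill_diagonal(D, 0.0)
    return D


def edge_tstat_clustering(table: pd.DataFrame, tfs: Sequence[str],
                          genes: Sequence[str]) -> EdgeClustering:
    """Complete-linkage clustering of the gene-by-TF t-statistic matrix.

    Distance is one minus the Pearson correlation, applied separately to
    rows (genes) and columns (TFs).
    """
    t = table["t_stat"].to_numpy().reshape(len(tfs), len(genes)).T  # gene x TF
    mat = pd.DataFrame(t, index=list(genes), columns=list(tfs))
    links, orders = [], []
    for X, labels in ((t, list(genes)), (t.T, list(tfs))):
        D = _correlation_distance(X)
        Z = hierarchy.linkage(squareform(D, checks=False), method="complete")
        links.append(Z)
        orders.append([labels[i] for i in hierarchy.leaves_list(Z)])
    return EdgeClustering(matrix=mat, row_order=orders[0], col_order=orders[1],
                          row_linkage=links[0], col_linkage=links[1])
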