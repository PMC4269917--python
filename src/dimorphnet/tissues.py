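"""Cross-tissue comparison of TF-level differential-targeting profiles.

For every TF, GSEA on its gene-by-network edge-weight table gives a
signed-significance profile over a panel of gene sets, per tissue.  A
TF whose profiles anticorrelate between tissues (Spearman rho below
-0.4) reverses its sex-specific targeting between compartments — the
candidate disease-specific regulator.  The core subnetwork restricts
the sex-specific edge lists to those TFs and the panel's genes.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffnet import SexSpecificSubnetwork, tf_specific_table
from .ensembles import NetworkEnsemble
from .gsea import gsea


def tf_function_profiles(
    ensemble_pairs: Mapping[str, tuple[NetworkEnsemble, NetworkEnsemble]],
    gene_sets: Mapping[str, Sequence[str]],
    selected_sets: Sequence[str],
    n_perm: int = 200,
    seed: int = 0,
    min_size: int = 2,
    max_size: int = 500,
) -> dict[str, pd.DataFrame]:
    """Per-tissue TF-by-set matrices of signed differential-targeting scores.

    ``ensemble_pairs`` maps tissue -> (female ensemble, male ensemble).
    For each TF and tissue, GSEA runs on the TF's gene-by-network table
    with networks labelled by sex; the signed scores of
    ``selected_sets`` populate that TF's row.  Set order is identical
    across tissues.
    """
    missing = [s for s in selected_sets if s not in gene_sets]
    if missing:
        raise ValueError(f"selected sets not in the collection: {missing}")
    panel = {s: gene_sets[s] for s in selected_sets}
    profiles: dict[str, pd.DataFrame] = {}
    ss = np.random.SeedSequence(seed)
    for tissue, (ens_f, ens_m) in sorted(ensemble_pairs.items()):
        if ens_f.tfs != ens_m.tfs or ens_f.genes != ens_m.genes:
            raise ValueError(f"{tissue}: ensembles do not share a universe")
        classes = ["F"] * ens_f.n_networks + ["M"] * ens_m.n_networks
        mat = pd.DataFrame(0.0, index=ens_f.tfs, columns=list(selected_sets))
        for tf in ens_f.tfs:
            tbl = pd.concat([tf_specific_table(ens_f, tf),
                             tf_specific_table(ens_m, tf)], axis=1)
            tbl.columns = range(tbl.shape[1])
            tf_seed = int(ss.spawn(1)[0].generate_state(1)[0]) & 0x7FFFFFFF
            res = gsea(tbl, classes, panel, n_perm=n_perm, seed=tf_seed,
                       min_size=min_size, max_size=max_size)
            scores = res.set_index("set")["signed_score"]
            mat.loc[tf, scores.index] = scores.to_numpy()
        profiles[tissue] = mat
    return profiles


def tissue_discordance(profile_a: pd.DataFrame, profile_b: pd.DataFrame,
                       rho_cutoff: float = -0.4) -> tuple[pd.Series, list[str]]:
    """Per-TF Spearman correlation of signed profiles between two tissues.

    Discordant TFs are those with rho below ``rho_cutoff``.  Constant
    profiles have undefined rank correlation: rho is NaN and the TF is
    excluded from selection, with a warning.
    """
    if list(profile_a.columns) != list(profile_b.columns):
        raise ValueError("profiles must share gene-set columns in the same order")
    if profile_a.shape[1] < 3:
        raise ValueError("need >= 3 gene sets for a meaningful rank correlation")
    common = [t for t in profile_a.index if t in set(profile_b.index)]
    rhos = {}
    n_const = 0
    for tf in common:
        x = profile_a.loc[tf].to_numpy()
        y = profile_b.loc[tf].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rhos[tf] = np.nan
            n_const += 1
            continue
        rhos[tf] = float(stats.spearmanr(x, y).statistic)
    if n_const:
        warnings.warn(f"{n_const} TFs with constant profiles: rho = NaN, excluded",
                      stacklevel=2)
    rho = pd.Series(rhos, name="spearman_rho")
    discordant = sorted(t for t, r in rhos.items() if np.isfinite(r) and r < rho_cutoff)
    return rho, discordant


def extract_core_subnetwork(
    sex_subnets: Mapping[str, tuple[SexSpecificSubnetwork, SexSpecificSubnetwork]],
    discordant_tfs: Sequence[str],
    selected_sets: Sequence[str],
    gene_sets: Mapping[str, Sequence[str]],
) -> dict[str, pd.DataFrame]:
    """Sex-specific edges from discordant TFs into the selected sets' genes.

    ``sex_subnets`` maps tissue -> (female subnetwork, male subnetwork).
    Returns per tissue an edge list (tf, gene, sex_label) containing
    exactly the source edges whose TF is discordant and whose target is
    annotated to a selected set.
    """
    tf_keep = set(discordant_tfs)
    gene_keep: set[str] = set()
    for s in selected_sets:
        gene_keep |= set(gene_sets[s])
    out: dict[str, pd.DataFrame] = {}
    for tissue, (sub_f, sub_m) in sorted(sex_subnets.items()):
        rows = []
        for sub, label in ((sub_f, "female"), (sub_m, "male")):
            for tf, gene in sub.edges.index:
                if tf in tf_keep and gene in gene_keep:
                    rows.append((tf, gene, label, tissue))
        out[tissue] = pd.DataFrame(rows, columns=["tf", "gene", "sex_label", "tissue"])
    return out


def core_subnetwork_to_graphml(edges: pd.DataFrame, path) -> None:
    """Write a core subnetwork edge list as GraphML for external viewers."""
    import networkx as nx

    g = nx.DiGraph()
    for tf, gene, label, tissue in edges[["tf", "gene", "sex_label", "tissue"]
                                         ].itertuples(index=False):
        g.add_node(tf, kind="tf")
        g.add_node(gene, kind="gene")
        g.add_edge(tf, gene, sex=label, tissue=tissue)
    nx.write_graphml(g, str(path))
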