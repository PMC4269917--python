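"""Readers and writers for the plain-text formats the pipeline consumes.

Expression matrices and metadata travel as TSV, gene sets as GMT,
sequences as FASTA, motifs as JASPAR-style PFM blocks, and networks as
(tf, gene, weight) edge lists.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_expression_tsv(path: str | os.PathLike) -> pd.DataFrame:
    """Genes-by-samples matrix; first column holds gene ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError(f"missing values in expression matrix {path}")
    if df.columns.duplicated().any():
        raise ValueError("duplicate sample ids")
    return df


def write_expression_tsv(values: pd.DataFrame, path: str | os.PathLike) -> None:
    values.to_csv(path, sep="\t", index_label="gene")


def read_metadata_tsv(path: str | os.PathLike) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    if meta.index.duplicated().any():
        raise ValueError("duplicate sample ids in metadata")
    return meta


def write_metadata_tsv(meta: pd.DataFrame, path: str | os.PathLike) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def read_edge_list(path: str | os.PathLike) -> pd.DataFrame:
    """Edge list with columns (source, target, weight); header optional."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("edge list needs at least two columns")
    cols = list(df.columns[:3])
    df = df.rename(columns=dict(zip(cols, ["source", "target", "weight"][: len(cols)])))
    if "weight" not in df.columns:
        df["weight"] = 1.0
    return df


def write_edge_list(matrix: pd.DataFrame, path: str | os.PathLike,
                    source_name: str = "tf", target_name: str = "gene") -> None:
    """Dense source-by-target matrix to a three-column TSV (all entries)."""
    long = matrix.stack()
    long.index.names = [source_name, target_name]
    long.rename("weight").reset_index().to_csv(path, sep="\t", index=False)


def edge_list_to_matrix(edges: pd.DataFrame, sources: Iterable[str] | None = None,
                        targets: Iterable[str] | None = None) -> pd.DataFrame:
    src = list(sources) if sources is not None else sorted(edges["source"].unique())
    tgt = list(targets) if targets is not None else sorted(edges["target"].unique())
    mat = pd.DataFrame(0.0, index=src, columns=tgt)
    for s, t, w in edges[["source", "target", "weight"]].itertuples(index=False):
        mat.loc[s, t] = w
    return mat


def read_gmt(path: str | os.PathLike) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, _desc, *genes = parts
            sets[name] = [g for g in genes if g]
    return sets


def write_gmt(gene_sets: Mapping[str, Iterable[str]], path: str | os.PathLike,
              descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    """BED (0-based, half-open) with at least chrom/start/end/name; strand optional."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    df.columns = names + list(df.columns[len(names):])
    if "strand" not in df.columns:
        df["strand"] = "+"
    return df


def write_pfms(pwms, path: str | os.PathLike, scale: int = 1000) -> None:
    """JASPAR-style PFM text: '>name' then four letter-prefixed count rows."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.tf_name}\n")
            counts = np.round(pwm.matrix * scale).astype(int)
            for i, base in enumerate("ACGT"):
                row = " ".join(str(c) for c in counts[:, i])
                fh.write(f"{base} [ {row} ]\n")
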