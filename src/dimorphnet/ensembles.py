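"""Jack-knife sampling plans, permutation controls, and network ensembles.

Every network in an ensemble is inferred from exactly k (default 10)
subjects of one sex and tissue drawn without replacement, so ensembles
of different sizes are comparable and per-edge score distributions can
be tested.  Replicates are drawn independently; subjects may recur
across replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panda import coexpression, panda


@dataclass
class JackknifePlan:
    group: tuple[str, str]                # (sex, tissue)
    replicates: list[tuple[str, ...]]     # subject ids, each of size k
    mode: str
    seed: int

    @property
    def k(self) -> int:
        return len(self.replicates[0]) if self.replicates else 0


@dataclass
class NetworkEnsemble:
    """Edge-by-network matrix of final edge scores.

    Rows enumerate TF-gene pairs TF-major: edge (i, j) lives in row
    ``i * len(genes) + j``.  Columns follow replicate order.
    """

    tfs: list[str]
    genes: list[str]
    scores: np.ndarray
    plan: JackknifePlan
    panda_config: dict = field(default_factory=dict)

    @property
    def n_networks(self) -> int:
        return self.scores.shape[1]

    def edge_index(self, tf: str, gene: str) -> int:
        return self.tfs.index(tf) * len(self.genes) + self.genes.index(gene)

    def edge_labels(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_product([self.tfs, self.genes],
                                          names=["tf", "gene"])


def _subject_table(metadata: pd.DataFrame, sex: str, tissue: str) -> pd.DataFrame:
    rows = metadata[(metadata["sex"] == sex) & (metadata["tissue"] == tissue)]
    sub = rows.drop_duplicates("subject_id").set_index("subject_id")
    return sub.sort_index()


def jackknife_plan(metadata: pd.DataFrame, group: tuple[str, str], k: int = 10,
                   reps: int = 100, mode: str = "random", seed: int = 0) -> JackknifePlan:
    """Draw ``reps`` subject subsets of size ``k`` for one sex/tissue group.

    ``random`` draws each replicate uniformly without replacement.
    ``covariate_matched`` builds female/male plans in pairs (see
    :func:`matched_jackknife_plans`) and returns the plan for the
    requested sex.
    """
    if mode == "covariate_matched":
        plan_f, plan_m = matched_jackknife_plans(metadata, group[1], k=k,
                                                 reps=reps, seed=seed)
        return plan_f if group[0] == "F" else plan_m
    if mode != "random":
        raise ValueError(f"unknown mode {mode!r}")
    sex, tissue = group
    subjects = list(_subject_table(metadata, sex, tissue).index)
    if len(subjects) < k:
        raise ValueError(f"group {group} has {len(subjects)} subjects < k={k}")
    rng = np.random.default_rng(seed)
    replicates = [tuple(sorted(rng.choice(subjects, size=k, replace=False)))
                  for _ in range(reps)]
    return JackknifePlan(group=group, replicates=replicates, mode="random", seed=seed)


def matched_jackknife_plans(metadata: pd.DataFrame, tissue: str, k: int = 10,
                            reps: int = 100, seed: int = 0
                            ) -> tuple[JackknifePlan, JackknifePlan]:
    """Paired female/male plans with matched covariates.

    Each female replicate is a uniform draw; its male partner matches
    the female GOLD-stage composition exactly and greedily minimizes the
    summed standardized (age, pack-years) distance within stage.
    """
    fem = _subject_table(metadata, "F", tissue)
    mal = _subject_table(metadata, "M", tissue)
    if len(fem) < k or len(mal) < k:
        raise ValueError("a sex group has fewer subjects than k")
    both = pd.concat([fem, mal])
    z = {}
    for col in ("age", "pack_years"):
        mu, sd = both[col].mean(), both[col].std(ddof=1)
        z[col] = (both[col] - mu) / (sd if sd > 0 else 1.0)
    zboth = pd.DataFrame(z)

    rng = np.random.default_rng(seed)
    fem_ids = list(fem.index)
    reps_f, reps_m = [], []
    males_by_stage = {
        stage: list(ids) for stage, ids in mal.groupby("gold_stage").groups.items()
    }
    for _ in range(reps):
        chosen_f = sorted(rng.choice(fem_ids, size=k, replace=False))
        used: set[str] = set()
        chosen_m = []
        for f_id in chosen_f:
            stage = fem.loc[f_id, "gold_stage"]
            candidates = [m for m in males_by_stage.get(stage, []) if m not in used]
            if not candidates:
                raise ValueError(
                    f"not enough male subjects of GOLD stage {stage} to match")
            fz = zboth.loc[f_id]
            dists = [((zboth.loc[m] - fz) ** 2).sum() for m in candidates]
            best = candidates[int(np.argmin(dists))]
            used.add(best)
            chosen_m.append(best)
        reps_f.append(tuple(chosen_f))
        reps_m.append(tuple(sorted(chosen_m)))
    plan_f = JackknifePlan(group=("F", tissue), replicates=reps_f,
                           mode="covariate_matched", seed=seed)
    plan_m = JackknifePlan(group=("M", tissue), replicates=reps_m,
                           mode="covariate_matched", seed=seed)
    return plan_f, plan_m


def build_ensemble(expr: pd.DataFrame, metadata: pd.DataFrame, plan: JackknifePlan,
                   prior: pd.DataFrame, ppi: pd.DataFrame,
                   panda_config: Mapping | None = None) -> NetworkEnsemble:
    """Infer one network per replicate and stack edge scores column-wise."""
    cfg = dict(panda_config or {})
    sex, tissue = plan.group
    meta_t = metadata[metadata["tissue"] == tissue]
    sample_of = dict(zip(meta_t["subject_id"], meta_t.index))
    genes = list(prior.columns)
    expr = expr.loc[genes]
    columns = []
    for r, subjects in enumerate(plan.replicates):
        missing = [s for s in subjects if s not in sample_of]
        if missing:
            raise ValueError(f"replicate {r}: subjects without {tissue} samples: {missing}")
        try:
            cols = [sample_of[s] for s in subjects]
            C = coexpression(expr[cols].to_numpy())
            net = panda(prior, ppi, C, **cfg)
        except Exception as err:  # pragma: no cover - defensive
            raise RuntimeError(f"network inference failed at replicate {r}") from err
        columns.append(net.edge_scores.ravel())
    scores = np.column_stack(columns)
    return NetworkEnsemble(tfs=list(prior.index), genes=genes, scores=scores,
                           plan=plan, panda_config=cfg)


def permutation_control(expr: pd.DataFrame, metadata: pd.DataFrame, mode: str,
                        seed: int = 0, exclude: Sequence[str] = ()
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-control inputs: permuted gene labels or permuted sex labels.

    ``gene_labels`` permutes the row labels of the expression matrix
    once (genes in ``exclude``, e.g. markers, keep their labels);
    ``sex_labels`` permutes the per-subject sex assignments while
    preserving the group sizes exactly.  Identity permutations are
    redrawn whenever more than 3 items are permuted.
    """
    rng = np.random.default_rng(seed)
    if mode == "gene_labels":
        movable = [g for g in expr.index if g not in set(exclude)]
        perm = _non_identity_permutation(rng, len(movable))
        mapping = dict(zip(movable, (movable[i] for i in perm)))
        new_index = [mapping.get(g, g) for g in expr.index]
        out = expr.copy()
        out.index = pd.Index(new_index, name=expr.index.name)
        return out, metadata.copy()
    if mode == "sex_labels":
        meta = metadata.copy()
        subjects = meta.drop_duplicates("subject_id")["subject_id"].tolist()
        sex_of = meta.drop_duplicates("subject_id").set_index("subject_id")["sex"]
        perm = _non_identity_permutation(rng, len(subjects))
        permuted = {subjects[i]: sex_of[subjects[perm[i]]] for i in range(len(subjects))}
        meta["sex"] = [permuted[s] for s in meta["subject_id"]]
        return expr.copy(), meta
    raise ValueError(f"unknown permutation mode {mode!r}")


def _non_identity_permutation(rng: np.random.Generator, n: int) -> np.ndarray:
    perm = rng.permutation(n)
    while n > 3 and np.array_equal(perm, np.arange(n)):
        perm = rng.permutation(n)
    return perm
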