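import numpy as np
import pandas as pd
import pytest

import dimorphnet as dn


@pytest.fixture(scope="session")
def small_study():
    """Tiny single-tissue study with one female-sputum module planted."""
    cohort, truth = dn.simulate_study(
        7, n_genes=150, n_tfs=12, n_female=15, n_male=15, tissues=("sputum",),
        module_specs=(("F", "sputum", 2, 20, 1.0),), n_decoy_sets=8,
    )
    return cohort, truth


@pytest.fixture(scope="session")
def small_ensembles(small_study):
    """Female/male jack-knife ensembles (8 networks each) on the tiny study."""
    cohort, truth = small_study
    expr = cohort.expression_by_tissue["sputum"]
    ens_f, ens_m, table = dn.sex_comparison(
        expr, cohort.metadata, truth.motif_prior, truth.ppi,
        tissue="sputum", reps=8, k=10, seed=3,
    )
    return ens_f, ens_m, table


@pytest.fixture
def toy_ensemble():
    """Hand-sized ensemble with known scores for bookkeeping checks."""
    tfs = ["t1", "t2"]
    genes = ["g1", "g2", "g3"]
    # 2 networks; edge rows TF-major
    scores = np.arange(12, dtype=float).reshape(6, 2)
    plan = dn.JackknifePlan(group=("F", "sputum"), replicates=[("a",) * 10] * 2,
                            mode="random", seed=0)
    return dn.NetworkEnsemble(tfs=tfs, genes=genes, scores=scores, plan=plan)


def make_ensemble(tfs, genes, scores):
    plan = dn.JackknifePlan(group=("F", "sputum"),
                            replicates=[("s",) * 10] * scores.shape[1],
                            mode="random", seed=0)
    return dn.NetworkEnsemble(tfs=list(tfs), genes=list(genes),
                              scores=np.asarray(scores, float), plan=plan)


@pytest.fixture
def ensemble_factory():
    return make_ensemble
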