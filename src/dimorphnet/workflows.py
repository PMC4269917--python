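"""Convenience drivers chaining the pipeline stages for one comparison."""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from .diffnet import edge_differential
from .ensembles import NetworkEnsemble, build_ensemble, jackknife_plan


def sex_comparison(
    expr: pd.DataFrame,
    metadata: pd.DataFrame,
    prior: pd.DataFrame,
    ppi: pd.DataFrame,
    tissue: str,
    reps: int = 20,
    k: int = 10,
    seed: int = 0,
    mode: str = "random",
    panda_config: Mapping | None = None,
) -> tuple[NetworkEnsemble, NetworkEnsemble, pd.DataFrame]:
    """Female and male jack-knife ensembles for one tissue plus their edge table."""
    plan_f = jackknife_plan(metadata, ("F", tissue), k=k, reps=reps,
                            mode=mode, seed=2 * seed + 1)
    plan_m = jackknife_plan(metadata, ("M", tissue), k=k, reps=reps,
                            mode=mode, seed=2 * seed + 2)
    ens_f = build_ensemble(expr, metadata, plan_f, prior, ppi, panda_config)
    ens_m = build_ensemble(expr, metadata, plan_m, prior, ppi, panda_config)
    return ens_f, ens_m, edge_differential(ens_f, ens_m)
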