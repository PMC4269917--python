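"""Synthetic cohorts, regulatory ground truth, and promoter fixtures.

The generator emulates the statistical structure the downstream analysis
assumes: a two-tissue COPD cohort with a 1:2 female/male ratio, bimodal
Y-marker genes for the PCA sex check, essentially no autosomal
differential expression, a block of differentially *variable* genes, and
sex-by-tissue restricted co-regulation modules driven by latent
transcription-factor activities.  Because module activities have zero
mean, planted modules create differential co-expression without
differential expression — the regime the network comparison is designed
to detect.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as dio

KNOWN_TISSUES = ("sputum", "blood")
_GOLD_STAGES = np.array([2, 3, 4])
_GOLD_PROBS = np.array([0.45, 0.40, 0.15])


def gene_id(i: int) -> str:
    return f"G{i:05d}"


def tf_id(i: int) -> str:
    return f"TF{i:03d}"


def marker_id(i: int) -> str:
    return f"YMRK{i:02d}"


@dataclass(frozen=True)
class PlantedModule:
    """A sex-by-tissue restricted co-regulation module.

    In the designated stratum each module TF has a latent activity drawn
    per sample from N(0, 1); every module gene receives
    ``coupling * sum(activities)`` on top of its baseline and noise.
    """

    sex: str
    tissue: str
    tf_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]
    coupling: float = 1.0

    def __post_init__(self):
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be F or M, got {self.sex!r}")


@dataclass
class SyntheticCohort:
    expression_by_tissue: dict[str, pd.DataFrame]
    metadata: pd.DataFrame
    marker_genes: list[str]
    mislabeled_subjects: list[str]
    seed: int


@dataclass
class RegulatoryTruth:
    motif_prior: pd.DataFrame
    ppi: pd.DataFrame
    planted_modules: tuple[PlantedModule, ...]
    gene_sets: dict[str, list[str]]
    de_genes: list[str]
    dv_genes: list[str]
    seed: int


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Defaults follow the post-QC design of the emulated study: 42 female
    and 84 male former smokers with expression in both sputum and blood,
    log-intensity scale, unit noise.
    """

    n_female: int = 42
    n_male: int = 84
    n_genes: int = 2000
    tissues: tuple[str, ...] = ("sputum", "blood")
    noise_sd: float = 1.0
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    modules: tuple[PlantedModule, ...] = ()
    de_shifts: Mapping[str, float] = field(default_factory=dict)
    dv_factors: Mapping[str, float] = field(default_factory=dict)
    n_marker_genes: int = 24
    n_mislabeled: int = 0
    seed: int = 0


@dataclass(frozen=True)
class TruthConfig:
    n_tfs: int = 130
    n_genes: int = 2000
    prior_density: float = 0.05
    ppi_density: float = 0.10
    modules: tuple[PlantedModule, ...] = ()
    n_decoy_sets: int = 20
    decoy_size: int = 30
    seed: int = 0


def _covariates(rng: np.random.Generator, n: int, sex: str) -> pd.DataFrame:
    # Females younger and with fewer pack-years, GOLD distribution shared:
    # the direction of imbalance seen in the emulated cohort.
    if sex == "F":
        age = rng.normal(60.0, 7.0, n)
        pack_years = np.clip(rng.normal(38.0, 12.0, n), 5.0, None)
    else:
        age = rng.normal(64.0, 7.0, n)
        pack_years = np.clip(rng.normal(48.0, 14.0, n), 5.0, None)
    gold = rng.choice(_GOLD_STAGES, size=n, p=_GOLD_PROBS)
    return pd.DataFrame({
        "sex": sex,
        "age": np.round(age, 1),
        "pack_years": np.round(pack_years, 1),
        "gold_stage": gold,
    })


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a two-sex, multi-tissue expression cohort.

    Expression of gene g in sample s is
    ``baseline_g + sum_modules coupling * activity + shift + noise``
    where module activities are drawn only in the module's sex/tissue
    stratum.  Marker genes (emulating Y-chromosome probe sets) are
    bimodal: high in males, low in females, following the subject's
    *true* sex even when the recorded label is flipped for a planted
    mislabel.
    """
    if config.n_female < 10 or config.n_male < 10:
        raise ValueError("each sex group needs >= 10 subjects (jack-knife size)")
    unknown = set(config.tissues) - set(KNOWN_TISSUES)
    if unknown:
        raise ValueError(f"unknown tissue names: {sorted(unknown)}")
    if len(set(config.tissues)) != len(config.tissues):
        raise ValueError("duplicate tissue names")
    genes = [gene_id(i) for i in range(config.n_genes)]
    gene_pos = {g: i for i, g in enumerate(genes)}
    for mod in config.modules:
        if mod.tissue not in config.tissues:
            raise ValueError(f"module tissue {mod.tissue!r} not in cohort tissues")
        missing = [g for g in mod.gene_ids if g not in gene_pos]
        if missing:
            raise ValueError(f"module genes outside gene universe: {missing[:3]}")

    rng = np.random.default_rng(config.seed)
    subjects_f = [f"F{i:03d}" for i in range(config.n_female)]
    subjects_m = [f"M{i:03d}" for i in range(config.n_male)]
    cov = pd.concat([
        _covariates(rng, config.n_female, "F"),
        _covariates(rng, config.n_male, "M"),
    ], ignore_index=True)
    cov.insert(0, "subject_id", subjects_f + subjects_m)

    true_sex = cov["sex"].to_numpy().copy()
    mislabeled: list[str] = []
    if config.n_mislabeled:
        flip = rng.choice(len(cov), size=config.n_mislabeled, replace=False)
        for i in flip:
            cov.loc[i, "sex"] = "M" if true_sex[i] == "F" else "F"
            mislabeled.append(cov.loc[i, "subject_id"])

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, config.n_genes)
    n_sub = len(cov)
    markers = [marker_id(i) for i in range(config.n_marker_genes)]

    # per-gene noise sd, inflated for planted differentially-variable genes
    # in females (true sex determines the biology)
    sd_f = np.full(config.n_genes, config.noise_sd)
    sd_m = np.full(config.n_genes, config.noise_sd)
    for g, fac in config.dv_factors.items():
        sd_f[gene_pos[g]] = config.noise_sd * fac
    shift_f = np.zeros(config.n_genes)
    for g, sh in config.de_shifts.items():
        shift_f[gene_pos[g]] = sh

    is_f = true_sex == "F"
    expr_by_tissue: dict[str, pd.DataFrame] = {}
    meta_frames = []
    for tissue in config.tissues:
        sd = np.where(is_f[None, :], sd_f[:, None], sd_m[:, None])
        x = baseline[:, None] + shift_f[:, None] * is_f[None, :] \
            + rng.standard_normal((config.n_genes, n_sub)) * sd
        for mod in config.modules:
            if mod.tissue != tissue:
                continue
            in_stratum = true_sex == mod.sex
            n_str = int(in_stratum.sum())
            act = rng.standard_normal((len(mod.tf_ids), n_str))
            contrib = mod.coupling * act.sum(axis=0)
            rows = [gene_pos[g] for g in mod.gene_ids]
            x[np.ix_(rows, np.flatnonzero(in_stratum))] += contrib[None, :]
        # bimodal sex markers driven by true sex
        mk = np.where(is_f[None, :], 4.0, 8.0) \
            + rng.standard_normal((config.n_marker_genes, n_sub)) * 0.5
        sample_ids = [f"{s}-{tissue}" for s in cov["subject_id"]]
        df = pd.DataFrame(np.vstack([x, mk]), index=genes + markers,
                          columns=sample_ids)
        expr_by_tissue[tissue] = df
        mt = cov.copy()
        mt.insert(0, "sample_id", sample_ids)
        mt["tissue"] = tissue
        meta_frames.append(mt)

    metadata = pd.concat(meta_frames, ignore_index=True).set_index("sample_id")
    return SyntheticCohort(
        expression_by_tissue=expr_by_tissue,
        metadata=metadata,
        marker_genes=markers,
        mislabeled_subjects=mislabeled,
        seed=config.seed,
    )


def generate_regulatory_truth(config: TruthConfig) -> RegulatoryTruth:
    """Motif prior, TF-TF interaction matrix, and gene-set collection.

    The prior is Bernoulli(prior_density) with every planted module
    TF->gene pair forced present.  Gene sets comprise one set per
    planted module plus size-matched decoy sets sampled without
    replacement, so enrichment specificity is testable.
    """
    if not (0.0 <= config.prior_density <= 1.0):
        raise ValueError("prior density outside [0, 1]")
    if not (0.0 <= config.ppi_density <= 1.0):
        raise ValueError("ppi density outside [0, 1]")
    tfs = [tf_id(i) for i in range(config.n_tfs)]
    genes = [gene_id(i) for i in range(config.n_genes)]
    tf_pos = {t: i for i, t in enumerate(tfs)}
    gene_pos = {g: i for i, g in enumerate(genes)}
    for mod in config.modules:
        if len(mod.gene_ids) > config.n_genes or len(mod.tf_ids) > config.n_tfs:
            raise ValueError("module larger than universe")
        for t in mod.tf_ids:
            if t not in tf_pos:
                raise ValueError(f"module TF {t!r} outside TF universe")
        for g in mod.gene_ids:
            if g not in gene_pos:
                raise ValueError(f"module gene {g!r} outside gene universe")

    rng = np.random.default_rng(config.seed)
    prior = (rng.random((config.n_tfs, config.n_genes)) < config.prior_density)
    prior = prior.astype(np.int8)
    for mod in config.modules:
        rows = [tf_pos[t] for t in mod.tf_ids]
        cols = [gene_pos[g] for g in mod.gene_ids]
        prior[np.ix_(rows, cols)] = 1

    upper = rng.random((config.n_tfs, config.n_tfs)) < config.ppi_density
    ppi = np.triu(upper, 1)
    ppi = (ppi | ppi.T).astype(np.int8)
    np.fill_diagonal(ppi, 1)

    gene_sets: dict[str, list[str]] = {}
    sizes: list[int] = []
    for i, mod in enumerate(config.modules):
        name = f"MODULE_{i}_{mod.sex}_{mod.tissue}".upper()
        gene_sets[name] = sorted(mod.gene_ids)
        sizes.append(len(mod.gene_ids))
    for j in range(config.n_decoy_sets):
        size = sizes[j % len(sizes)] if sizes else config.decoy_size
        members = rng.choice(config.n_genes, size=size, replace=False)
        gene_sets[f"DECOY_{j:03d}"] = sorted(genes[k] for k in members)

    return RegulatoryTruth(
        motif_prior=pd.DataFrame(prior, index=tfs, columns=genes),
        ppi=pd.DataFrame(ppi, index=tfs, columns=tfs),
        planted_modules=tuple(config.modules),
        gene_sets=gene_sets,
        de_genes=[],
        dv_genes=[],
        seed=config.seed,
    )


def simulate_study(
    seed: int,
    n_genes: int = 500,
    n_tfs: int = 50,
    n_female: int = 42,
    n_male: int = 84,
    tissues: tuple[str, ...] = ("sputum",),
    module_specs: Sequence[tuple[str, str, int, int, float]] = (("F", "sputum", 3, 30, 1.0),),
    prior_density: float = 0.05,
    ppi_density: float = 0.10,
    noise_sd: float = 1.0,
    n_decoy_sets: int = 20,
    n_mislabeled: int = 0,
) -> tuple[SyntheticCohort, RegulatoryTruth]:
    """Convenience wrapper tying a cohort and its regulatory truth together.

    ``module_specs`` entries are (sex, tissue, n_tfs, n_genes, coupling);
    member TFs/genes are drawn without replacement and without overlap
    between modules, so planted sets are disjoint.
    """
    ss = np.random.SeedSequence(seed)
    s_mod, s_truth, s_cohort = (int(s) & 0x7FFFFFFF for s in ss.generate_state(3))
    rng = np.random.default_rng(s_mod)
    free_tfs = list(range(n_tfs))
    free_genes = list(range(n_genes))
    modules = []
    for sex, tissue, k_tf, k_gene, coupling in module_specs:
        t_idx = rng.choice(len(free_tfs), size=k_tf, replace=False)
        chosen_t = sorted(free_tfs[i] for i in t_idx)
        free_tfs = [t for t in free_tfs if t not in set(chosen_t)]
        g_idx = rng.choice(len(free_genes), size=k_gene, replace=False)
        chosen_g = sorted(free_genes[i] for i in g_idx)
        free_genes = [g for g in free_genes if g not in set(chosen_g)]
        modules.append(PlantedModule(
            sex=sex, tissue=tissue,
            tf_ids=tuple(tf_id(i) for i in chosen_t),
            gene_ids=tuple(gene_id(i) for i in chosen_g),
            coupling=coupling,
        ))
    truth = generate_regulatory_truth(TruthConfig(
        n_tfs=n_tfs, n_genes=n_genes, prior_density=prior_density,
        ppi_density=ppi_density, modules=tuple(modules),
        n_decoy_sets=n_decoy_sets, seed=s_truth,
    ))
    cohort = generate_cohort(CohortConfig(
        n_female=n_female, n_male=n_male, n_genes=n_genes, tissues=tissues,
        noise_sd=noise_sd, modules=tuple(modules), n_mislabeled=n_mislabeled,
        seed=s_cohort,
    ))
    return cohort, truth


# ---------------------------------------------------------------------------
# promoter / PWM fixtures


@dataclass(frozen=True)
class SeqConfig:
    """Promoter fixture: i.i.d. background with consensus sites written in.

    Each record spans the promoter window [-750, +250) around a declared
    TSS, so record index 0 is position -750.
    """

    n_genes: int = 10
    n_pwms: int = 3
    promoter_length: int = 1000
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    n_planted_sites: int = 0
    planted_sites: tuple[tuple[str, str, int, str], ...] = ()  # (gene, tf, offset, strand)
    # length 10 keeps the consensus word rarer than 1e-5 under a uniform
    # background (0.25**10 < 1e-5), so planted consensus sites clear the
    # calibrated significance threshold
    pwm_length: int = 10
    pwm_consensus_prob: float = 0.97
    seed: int = 0


@dataclass
class PromoterFixture:
    promoters: dict[str, str]
    pwms: list
    sites: pd.DataFrame  # gene, tf, offset, strand
    tss_offset: int
    background: tuple[float, float, float, float]
    seed: int


_BASES = np.array(list("ACGT"))
_COMP = str.maketrans("ACGT", "TGCA")


def _random_pwm(rng: np.random.Generator, name: str, length: int, p: float):
    from .motifs import PWM  # local import to avoid a cycle at import time

    consensus = rng.integers(0, 4, size=length)
    mat = np.full((length, 4), (1.0 - p) / 3.0)
    mat[np.arange(length), consensus] = p
    return PWM(tf_name=name, matrix=mat)


def generate_promoter_fixtures(config: SeqConfig, pwms=None) -> PromoterFixture:
    """Background promoters with PWM-consensus subsequences planted.

    Site offsets are positions of the site start relative to the TSS
    (negative = upstream); planted offsets must keep the whole site in
    the [-750, +250) window.  Minus-strand sites are written as the
    reverse complement of the consensus.
    """
    bg = np.asarray(config.background, dtype=float)
    if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0, atol=1e-6) or (bg < 0).any():
        raise ValueError("background frequencies must be 4 non-negatives summing to 1")
    if config.promoter_length < 1000:
        raise ValueError("promoter length must be >= 1000 nt to cover [-750, +250)")
    rng = np.random.default_rng(config.seed)
    genes = [gene_id(i) for i in range(config.n_genes)]
    if pwms is None:
        pwms = [_random_pwm(rng, tf_id(i), config.pwm_length, config.pwm_consensus_prob)
                for i in range(config.n_pwms)]
    for pwm in pwms:
        if not np.allclose(pwm.matrix.sum(axis=1), 1.0, atol=1e-3):
            raise ValueError(f"PWM {pwm.tf_name} columns do not sum to ~1")
    pwm_by_name = {p.tf_name: p for p in pwms}
    tss_offset = 750

    seqs = {
        g: "".join(_BASES[rng.choice(4, size=config.promoter_length, p=bg)])
        for g in genes
    }

    planted = list(config.planted_sites)
    if config.n_planted_sites and not planted:
        for _ in range(config.n_planted_sites):
            g = genes[rng.integers(0, len(genes))]
            pwm = pwms[rng.integers(0, len(pwms))]
            offset = int(rng.integers(-750, 250 - pwm.length + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            planted.append((g, pwm.tf_name, offset, strand))

    rows = []
    for g, tf, offset, strand in planted:
        pwm = pwm_by_name[tf]
        if offset < -750 or offset + pwm.length > 250:
            raise ValueError(f"planted offset {offset} outside promoter window")
        site = pwm.consensus()
        if strand == "-":
            site = site.translate(_COMP)[::-1]
        start = offset + tss_offset
        s = seqs[g]
        seqs[g] = s[:start] + site + s[start + pwm.length:]
        rows.append((g, tf, offset, strand))
    sites = pd.DataFrame(rows, columns=["gene", "tf", "offset", "strand"])
    return PromoterFixture(promoters=seqs, pwms=list(pwms), sites=sites,
                           tss_offset=tss_offset, background=tuple(bg), seed=config.seed)


# ---------------------------------------------------------------------------
# writers


def write_cohort(cohort: SyntheticCohort, outdir: str | os.PathLike) -> None:
    os.makedirs(outdir, exist_ok=True)
    for tissue, df in cohort.expression_by_tissue.items():
        dio.write_expression_tsv(df, os.path.join(outdir, f"expression_{tissue}.tsv"))
    dio.write_metadata_tsv(cohort.metadata, os.path.join(outdir, "metadata.tsv"))
    with open(os.path.join(outdir, "marker_genes.txt"), "w") as fh:
        fh.write("\n".join(cohort.marker_genes) + "\n")


def write_truth(truth: RegulatoryTruth, outdir: str | os.PathLike) -> None:
    os.makedirs(outdir, exist_ok=True)
    dio.write_edge_list(truth.motif_prior, os.path.join(outdir, "motif_prior.tsv"))
    dio.write_edge_list(truth.ppi, os.path.join(outdir, "ppi.tsv"),
                        source_name="tf", target_name="tf2")
    dio.write_gmt(truth.gene_sets, os.path.join(outdir, "gene_sets.gmt"))


def write_fixture(fix: PromoterFixture, outdir: str | os.PathLike) -> None:
    os.makedirs(outdir, exist_ok=True)
    dio.write_fasta(fix.promoters, os.path.join(outdir, "promoters.fasta"))
    dio.write_pfms(fix.pwms, os.path.join(outdir, "motifs.pfm"))
    fix.sites.to_csv(os.path.join(outdir, "planted_sites.tsv"), sep="\t", index=False)
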