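"""PWM scanning of promoter windows against an empirical null.

A candidate window S is scored log2[P(S|M) / P(S|B)] under the motif M
and background B.  Significance is calibrated empirically by scoring a
large sample of background windows; sites passing p < 1e-5 inside the
[-750, +250) promoter window become edges of the binary motif prior.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

logger = logging.getLogger(__name__)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_PSEUDOCOUNT = 1e-3
PROMOTER_WINDOW = (-750, 250)


@dataclass
class PWM:
    """Position probability matrix.

    ``matrix`` is positions-by-4 (A, C, G, T); every row sums to 1 and
    all entries are strictly positive — a 1e-3 pseudocount is added on
    construction whenever a probability of zero would otherwise give a
    log score of -inf.
    """

    tf_name: str
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be positions-by-4")
        if (self.matrix <= 0).any():
            self.matrix = self.matrix + _PSEUDOCOUNT
        self.matrix = self.matrix / self.matrix.sum(axis=1, keepdims=True)

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(tf_name=self.tf_name, matrix=self.matrix[::-1, ::-1])

    def log_odds(self, background: Sequence[float]) -> np.ndarray:
        """Positions-by-5 log2 likelihood-ratio table; column 4 (N) is 0."""
        bg = _check_background(background)
        table = np.zeros((self.length, 5))
        table[:, :4] = np.log2(self.matrix / bg[None, :])
        return table


def _check_background(background: Sequence[float]) -> np.ndarray:
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0, atol=1e-6) or (bg <= 0).any():
        raise ValueError("background must be 4 positive frequencies summing to 1")
    return bg


def read_jaspar_pfms(path) -> list[PWM]:
    """JASPAR-style PFM text ('>name' then four count rows)."""
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "jaspar")
    pwms = []
    for m in parsed:
        counts = np.array([m.counts[b] for b in "ACGT"], dtype=float).T
        name = m.name or m.matrix_id
        pwms.append(PWM(tf_name=name, matrix=counts / counts.sum(axis=1, keepdims=True)))
    return pwms


def encode_sequence(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for base, idx in (("A", 0), ("C", 1), ("G", 2), ("T", 3)):
        out[arr == ord(base)] = idx
    return out


def score_pwm_match(window: str, pwm: PWM, background: Sequence[float]) -> float:
    """log2 P(window|M)/P(window|B); an N contributes 0 at its position."""
    if len(window) == 0:
        raise ValueError("empty window")
    if len(window) != pwm.length:
        raise ValueError(f"window length {len(window)} != PWM length {pwm.length}")
    table = pwm.log_odds(background)
    idx = encode_sequence(window)
    return float(table[np.arange(pwm.length), idx].sum())


def _score_windows(encoded: np.ndarray, table: np.ndarray) -> np.ndarray:
    """Scores of every window of len(table) in an encoded sequence."""
    L = table.shape[0]
    n = encoded.size - L + 1
    if n <= 0:
        return np.empty(0)
    win = np.lib.stride_tricks.sliding_window_view(encoded, L)
    return table[np.arange(L)[None, :], win].sum(axis=1)


def calibrate_empirical_null(
    pwm: PWM,
    background: Sequence[float] | str,
    n_samples: int = 10**6,
    seed: int = 0,
    p: float = 1e-5,
) -> tuple[float, np.ndarray]:
    """Empirical score threshold at significance ``p``.

    ``background`` is either a base-frequency vector (windows drawn
    i.i.d.) or a background sequence (windows sampled uniformly from
    it).  Returns ``(threshold, sorted null scores)``; a site is called
    when its score strictly exceeds the threshold, the empirical
    (1 - p) quantile of the null scores.
    """
    if n_samples < 10**5:
        raise ValueError("n_samples too small to resolve p = 1e-5 (need >= 1e5)")
    if n_samples < 10**6:
        warnings.warn("n_samples < 1e6: the p = 1e-5 tail is coarsely resolved",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    L = pwm.length
    if isinstance(background, str):
        enc = encode_sequence(background)
        freqs = np.bincount(enc[enc < 4], minlength=4).astype(float)
        bg = freqs / freqs.sum()
        table = pwm.log_odds(bg)
        starts = rng.integers(0, enc.size - L + 1, size=n_samples)
        idx = starts[:, None] + np.arange(L)[None, :]
        scores = table[np.arange(L)[None, :], enc[idx]].sum(axis=1)
    else:
        bg = _check_background(background)
        table = pwm.log_odds(bg)
        scores = np.empty(n_samples)
        chunk = 200_000
        for lo in range(0, n_samples, chunk):
            hi = min(lo + chunk, n_samples)
            draws = rng.choice(4, size=(hi - lo, L), p=bg)
            scores[lo:hi] = table[np.arange(L)[None, :], draws].sum(axis=1)
    scores.sort()
    threshold = float(np.quantile(scores, 1.0 - p, method="higher"))
    return threshold, scores


def scan_promoters(
    promoters: Mapping[str, str],
    pwms: Iterable[PWM],
    p_cutoff: float = 1e-5,
    background: Sequence[float] | None = None,
    null_samples: int = 10**6,
    seed: int = 0,
    tss_offset: int = 750,
    window: tuple[int, int] = PROMOTER_WINDOW,
    genes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Scan both strands of every promoter for significant PWM sites.

    Each promoter record is assumed to carry its TSS at ``tss_offset``
    (record index 0 = window[0] by default).  The per-PWM threshold is
    calibrated from ``null_samples`` background windows; by default the
    background is estimated from the promoter base composition.
    Returns a site table (gene, tf, offset, strand, score, p_empirical)
    with offsets relative to the TSS.
    """
    pwms = list(pwms)
    if genes is None:
        genes = list(promoters)
    missing = [g for g in genes if g not in promoters]
    for g in missing:
        logger.warning("gene %s has no promoter sequence; skipped", g)
    present = [g for g in genes if g in promoters]
    if background is None:
        counts = np.zeros(4)
        for g in present:
            enc = encode_sequence(promoters[g])
            counts += np.bincount(enc[enc < 4], minlength=4)
        background = counts / counts.sum() if counts.sum() else np.full(4, 0.25)
    bg = _check_background(background)

    encoded = {g: encode_sequence(promoters[g]) for g in present}
    rows = []
    ss = np.random.SeedSequence(seed)
    for pwm, child in zip(pwms, ss.spawn(max(len(pwms), 1))):
        pwm_seed = int(child.generate_state(1)[0]) & 0x7FFFFFFF
        threshold, null_scores = calibrate_empirical_null(
            pwm, bg, n_samples=null_samples, seed=pwm_seed, p=p_cutoff)
        tables = {"+": pwm.log_odds(bg), "-": pwm.reverse_complement().log_odds(bg)}
        L = pwm.length
        lo_start = window[0] + tss_offset
        hi_start = window[1] + tss_offset - L  # inclusive last valid start
        for g in present:
            enc = encoded[g]
            for strand, table in tables.items():
                scores = _score_windows(enc, table)
                starts = np.arange(scores.size)
                ok = (starts >= lo_start) & (starts <= hi_start) & (scores > threshold)
                for st in starts[ok]:
                    sc = scores[st]
                    p_emp = 1.0 - np.searchsorted(null_scores, sc, side="left") / null_scores.size
                    rows.append((g, pwm.tf_name, int(st - tss_offset), strand,
                                 float(sc), float(p_emp)))
    sites = pd.DataFrame(rows, columns=["gene", "tf", "offset", "strand",
                                        "score", "p_empirical"])
    if len(sites):
        sites = sites.sort_values(["tf", "gene", "offset", "strand"]).reset_index(drop=True)
    return sites


def extract_promoters(
    genome: Mapping[str, str],
    tss_table: pd.DataFrame,
    window: tuple[int, int] = PROMOTER_WINDOW,
) -> dict[str, str]:
    """Promoter windows from a genome and a BED-style TSS table.

    BED is 0-based half-open; the TSS of a + gene is ``start``, of a -
    gene ``end - 1``.  Minus-strand windows are reflected and
    reverse-complemented so every returned sequence reads 5'->3' in
    transcription orientation with the TSS at index ``-window[0]``.
    """
    comp = str.maketrans("ACGTN", "TGCAN")
    out: dict[str, str] = {}
    for row in tss_table.itertuples(index=False):
        if row.chrom not in genome:
            logger.warning("chromosome %s not in genome; gene %s skipped",
                           row.chrom, row.name)
            continue
        seq = genome[row.chrom]
        if row.strand == "-":
            tss = row.end - 1
            lo, hi = tss - window[1] + 1, tss - window[0] + 1
        else:
            tss = row.start
            lo, hi = tss + window[0], tss + window[1]
        if lo < 0 or hi > len(seq):
            logger.warning("promoter window for %s out of bounds; skipped", row.name)
            continue
        sub = seq[lo:hi].upper()
        if row.strand == "-":
            sub = sub.translate(comp)[::-1]
        out[row.name] = sub
    return out


@dataclass
class MotifPriorNetwork:
    """Binary TF-by-gene adjacency: 1 iff the TF has >= 1 passing site."""

    tfs: list[str]
    genes: list[str]
    adjacency: np.ndarray

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.adjacency, index=self.tfs, columns=self.genes)


def build_motif_prior(sites: pd.DataFrame, tfs: Sequence[str],
                      genes: Sequence[str]) -> MotifPriorNetwork:
    tfs = list(tfs)
    genes = list(genes)
    if len(set(tfs)) != len(tfs):
        raise ValueError("duplicate TF names")
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene names")
    tf_pos = {t: i for i, t in enumerate(tfs)}
    gene_pos = {g: i for i, g in enumerate(genes)}
    adj = np.zeros((len(tfs), len(genes)), dtype=np.int8)
    if len(sites):
        for t, g in sites[["tf", "gene"]].itertuples(index=False):
            if t in tf_pos and g in gene_pos:
                adj[tf_pos[t], gene_pos[g]] = 1
    return MotifPriorNetwork(tfs=tfs, genes=genes, adjacency=adj)
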