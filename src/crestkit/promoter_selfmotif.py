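"""Promoter self-motif discovery and dosage-sensitivity enrichment.

A transcription factor whose own promoter carries its binding motif can, in
principle, autoregulate — the candidate mechanism behind transcriptional
compensation. This module extracts +/-1 kb promoters, scans them with
position weight matrices under an exact p-value model, lists TF genes whose
promoters harbor their own motif, and tests the candidate set for enrichment
in dosage-sensitivity classes (haploinsufficient vs triplosensitive).

The scan scores each window by the log2 odds sum against a 0-order
background; its p-value is the exact probability, under that background,
that a random w-mer scores at least as high — computed by dynamic
programming over a discretized score distribution (default grid: 1/1000 of
the score range), the same construction FIMO uses.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .library_design import GenomeSequence, revcomp

__all__ = [
    "PromoterSequence",
    "PWM",
    "MotifHit",
    "extract_promoters",
    "estimate_background",
    "scan_pwm",
    "scan_pwm_detailed",
    "self_binding_tfs",
    "dosage_enrichment",
    "read_meme_motifs",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
DEFAULT_PSEUDOCOUNT = 0.01
DEFAULT_SCORE_BINS = 1000


@dataclass(frozen=True)
class PromoterSequence:
    gene: str
    chrom: str
    start: int
    end: int
    strand: str
    sequence: str  # 5'->3' relative to the gene
    clipped: bool = False


@dataclass(frozen=True)
class MotifHit:
    gene: str
    motif_id: str
    offset: int
    strand: str
    score: float
    p_value: float


class PWM:
    """Position weight matrix with log2-odds scoring and exact p-values."""

    def __init__(
        self,
        motif_id: str,
        probs: np.ndarray,
        tf_gene: str | None = None,
        background: np.ndarray | None = None,
    ):
        probs = np.asarray(probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4 or probs.shape[0] < 1:
            raise ValueError("probs must be (w, 4)")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PWM rows must sum to 1")
        self.motif_id = motif_id
        self.tf_gene = tf_gene if tf_gene is not None else motif_id
        self.probs = probs
        self.background = (np.full(4, 0.25) if background is None
                           else np.asarray(background, dtype=float))

    @property
    def width(self) -> int:
        return int(self.probs.shape[0])

    @classmethod
    def from_counts(
        cls,
        motif_id: str,
        counts: np.ndarray,
        tf_gene: str | None = None,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
        background: np.ndarray | None = None,
    ) -> "PWM":
        counts = np.asarray(counts, dtype=float) + pseudocount
        return cls(motif_id, counts / counts.sum(axis=1, keepdims=True),
                   tf_gene=tf_gene, background=background)

    def log_odds(self, background: np.ndarray | None = None) -> np.ndarray:
        bg = self.background if background is None else np.asarray(background, float)
        return np.log2(self.probs / bg[None, :])

    def score_distribution(
        self,
        background: np.ndarray | None = None,
        bins: int = DEFAULT_SCORE_BINS,
    ) -> tuple[np.ndarray, np.ndarray, float, float]:
        """Exact distribution of the integerized window score under the
        background model.

        Scores are mapped to an integer grid of step
        delta = (max score - min score) / bins, each column shifted so its
        minimum is 0. Returns (pmf over integer totals, tail p-values,
        delta, total offset) where ``tail[s] = P(score_int >= s)``.
        """
        bg = self.background if background is None else np.asarray(background, float)
        lod = self.log_odds(bg)
        col_min = lod.min(axis=1)
        col_max = lod.max(axis=1)
        score_range = float((col_max - col_min).sum())
        delta = score_range / bins if score_range > 0 else 1.0
        ints = np.rint((lod - col_min[:, None]) / delta).astype(np.int64)
        max_total = int(ints.max(axis=1).sum())
        pmf = np.zeros(max_total + 1)
        pmf[0] = 1.0
        for pos in range(self.width):
            nxt = np.zeros_like(pmf)
            for base in range(4):
                s = ints[pos, base]
                nxt[s:] += bg[base] * pmf[:len(pmf) - s if s else len(pmf)]
            pmf = nxt
        tail = np.cumsum(pmf[::-1])[::-1]
        return pmf, tail, delta, float(col_min.sum())

    def integer_score(self, window: str, delta: float, offset: float,
                      background: np.ndarray | None = None) -> int:
        lod = self.log_odds(background)
        col_min = lod.min(axis=1)
        ints = np.rint((lod - col_min[:, None]) / delta).astype(np.int64)
        return int(sum(ints[i, _BASE_INDEX[b]] for i, b in enumerate(window)))


def extract_promoters(
    annotation: pd.DataFrame,
    genome: GenomeSequence | Mapping[str, str],
    flank: int = 1000,
) -> list[PromoterSequence]:
    """Extract [TSS - flank, TSS + flank) promoter sequences per gene.

    ``annotation`` needs columns gene, chrom, tss, strand. Minus-strand
    promoters are reverse-complemented so sequences read 5'->3' relative to
    the gene; intervals clipped at contig ends are flagged. When several
    rows share a gene, the first-listed row anchors the promoter.
    """
    seqs: Mapping[str, str]
    if isinstance(genome, GenomeSequence):
        seqs = {genome.name: genome.sequence}
    else:
        seqs = genome
    promoters: list[PromoterSequence] = []
    seen: set[str] = set()
    for row in annotation.itertuples(index=False):
        if row.gene in seen:
            continue
        seen.add(row.gene)
        contig = seqs[row.chrom]
        start, end = row.tss - flank, row.tss + flank
        clipped = start < 0 or end > len(contig)
        start, end = max(start, 0), min(end, len(contig))
        seq = contig[start:end].upper()
        if row.strand == "-":
            seq = revcomp(seq)
        promoters.append(PromoterSequence(row.gene, row.chrom, start, end,
                                          row.strand, seq, clipped=clipped))
    return promoters


def estimate_background(sequences: Sequence[str]) -> np.ndarray:
    """0-order background from base frequencies over a sequence set."""
    counts = np.zeros(4)
    for seq in sequences:
        for base, idx in _BASE_INDEX.items():
            counts[idx] += seq.count(base)
    if counts.sum() == 0:
        return np.full(4, 0.25)
    return counts / counts.sum()


def scan_pwm_detailed(
    seq: str,
    pwm: PWM,
    p_threshold: float = 1e-4,
    background: np.ndarray | None = None,
    gene: str = "",
    bins: int = DEFAULT_SCORE_BINS,
) -> tuple[list[MotifHit], int]:
    """Scan both strands; returns (hits with p < p_threshold, skipped windows).

    Windows containing a non-ACGT base are skipped and counted. Offsets are
    positions in ``seq`` of the window start; minus-strand hits report the
    forward-coordinate window start.
    """
    seq = seq.upper()
    w = pwm.width
    if len(seq) < w:
        return [], 0
    bg = pwm.background if background is None else np.asarray(background, float)
    _pmf, tail, delta, _off = pwm.score_distribution(bg, bins=bins)
    lod = pwm.log_odds(bg)
    col_min = lod.min(axis=1)
    ints = np.rint((lod - col_min[:, None]) / delta).astype(np.int64)

    hits: list[MotifHit] = []
    skipped = 0
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for j in range(len(s) - w + 1):
            window = s[j:j + w]
            idx = [_BASE_INDEX.get(b) for b in window]
            if any(i is None for i in idx):
                skipped += 1
                continue
            int_score = int(sum(ints[i, b] for i, b in enumerate(idx)))
            p = float(tail[int_score]) if int_score < len(tail) else float(tail[-1])
            if p < p_threshold:
                score = float(sum(lod[i, b] for i, b in enumerate(idx)))
                offset = j if strand == "+" else len(seq) - j - w
                hits.append(MotifHit(gene, pwm.motif_id, offset, strand, score, p))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits, skipped


def scan_pwm(
    seq: str,
    pwm: PWM,
    p_threshold: float = 1e-4,
    background: np.ndarray | None = None,
    gene: str = "",
) -> list[MotifHit]:
    hits, _ = scan_pwm_detailed(seq, pwm, p_threshold, background, gene)
    return hits


def self_binding_tfs(
    promoters: Sequence[PromoterSequence],
    pwms: Sequence[PWM],
    motif_to_tf: Mapping[str, str] | None = None,
    p_threshold: float = 1e-4,
    background: np.ndarray | None = None,
) -> pd.DataFrame:
    """TF genes whose own promoter contains their own motif.

    A gene is listed iff at least one of its motifs hits its own promoter at
    the threshold; deduplicated per gene, keeping the best (lowest p) hit.
    The background defaults to the 0-order model estimated from the scanned
    promoter set.
    """
    if background is None:
        background = estimate_background([p.sequence for p in promoters])
    motif_to_tf = motif_to_tf or {p.motif_id: p.tf_gene for p in pwms}
    by_gene: dict[str, list[PWM]] = {}
    for pwm in pwms:
        tf = motif_to_tf.get(pwm.motif_id, pwm.tf_gene)
        by_gene.setdefault(tf, []).append(pwm)
    rows = []
    for prom in promoters:
        best: MotifHit | None = None
        for pwm in by_gene.get(prom.gene, []):
            hits = scan_pwm(prom.sequence, pwm, p_threshold, background,
                            gene=prom.gene)
            for h in hits:
                if best is None or h.p_value < best.p_value:
                    best = h
        if best is not None:
            rows.append({"gene": prom.gene, "motif_id": best.motif_id,
                         "offset": best.offset, "strand": best.strand,
                         "score": best.score, "p_value": best.p_value})
    return pd.DataFrame(rows, columns=["gene", "motif_id", "offset", "strand",
                                       "score", "p_value"])


def dosage_enrichment(
    candidates: Sequence[str],
    dosage_table: pd.DataFrame,
) -> pd.DataFrame:
    """Per-class 2x2 enrichment of candidate genes in dosage-sensitivity
    classes.

    ``dosage_table`` needs columns gene, dosage_class (values from
    {haploinsufficient, triplosensitive, neither}). For each class the 2x2
    table is candidate-vs-rest x class-vs-not; reported: sample odds ratio
    (cross-product), two-sided Fisher exact p, and the class percentage
    among candidates.
    """
    classes = [c for c in ("haploinsufficient", "triplosensitive")
               if c in set(dosage_table["dosage_class"])]
    if not classes:
        raise ValueError("dosage table contains neither sensitivity class")
    cand = set(candidates)
    genes = dosage_table["gene"]
    is_cand = genes.isin(cand).to_numpy()
    if is_cand.sum() == 0 or (~is_cand).sum() == 0:
        raise ValueError("empty margin: candidates must split the gene table")
    rows = []
    for cls in classes:
        in_cls = (dosage_table["dosage_class"] == cls).to_numpy()
        a = int((is_cand & in_cls).sum())
        b = int((is_cand & ~in_cls).sum())
        c = int((~is_cand & in_cls).sum())
        d = int((~is_cand & ~in_cls).sum())
        odds = (a * d) / (b * c) if b * c > 0 else float("inf")
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append({
            "dosage_class": cls,
            "n_candidates_in_class": a,
            "pct_of_candidates": 100.0 * a / (a + b),
            "odds_ratio": odds,
            "p_value": float(p),
        })
    return pd.DataFrame(rows)


def read_meme_motifs(path: str | Path) -> list[PWM]:
    """Read motifs from MEME minimal-format text (letter-probability
    matrices over the ACGT alphabet)."""
    text = Path(path).read_text()
    motifs: list[PWM] = []
    blocks = re.split(r"^MOTIF\s+", text, flags=re.M)[1:]
    for block in blocks:
        header = block.splitlines()[0].split()
        motif_id = header[0]
        m = re.search(
            r"letter-probability matrix[^\n]*\n((?:\s*[\d.eE+-]+(?:\s+[\d.eE+-]+){3}\s*\n)+)",
            block,
        )
        if not m:
            raise ValueError(f"{path}: motif {motif_id} has no probability matrix")
        rows = [[float(x) for x in line.split()]
                for line in m.group(1).strip().splitlines()]
        motifs.append(PWM(motif_id, np.array(rows)))
    return motifs
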