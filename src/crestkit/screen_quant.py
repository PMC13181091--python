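"""Quantification of pooled pgRNA screens from paired-end reads.

A read pair is counted for a pgRNA only when both extracted spacer regions
exactly match the designed sequences — mismatched pairs go to the unmatched
bin, so no aligner is needed. Downstream: per-million normalization, log2
fold change sorted/control, and an empirical-null enrichment statistic
computed against the non-targeting negative controls.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .simulate import ReadArchitecture

__all__ = [
    "PgRNAIndex",
    "CountTable",
    "build_index",
    "count_read_pairs",
    "normalize_cpm",
    "log2_fold_change",
    "empirical_enrichment",
]


@dataclass
class PgRNAIndex:
    """Exact-sequence lookup from (spacer1, spacer2) to pgRNA id."""

    lookup: dict[tuple[str, str], str]
    arch: ReadArchitecture
    spacer1_lengths: tuple[int, ...]
    spacer2_lengths: tuple[int, ...]
    ids: list[str]

    def __len__(self) -> int:
        return len(self.lookup)


@dataclass
class CountTable:
    pool: str
    counts: dict[str, int]
    total_read_pairs: int
    unmatched: int

    def __post_init__(self):
        matched = sum(self.counts.values())
        if matched + self.unmatched != self.total_read_pairs:
            raise ValueError(
                f"count conservation violated: {matched} matched + "
                f"{self.unmatched} unmatched != {self.total_read_pairs} total"
            )

    def vector(self, ids: Sequence[str]) -> np.ndarray:
        return np.array([self.counts.get(i, 0) for i in ids], dtype=np.int64)


def build_index(manifest: pd.DataFrame, arch: ReadArchitecture | None = None) -> PgRNAIndex:
    """Build the exact-match lookup from a library manifest.

    Duplicate (spacer1, spacer2) pairs are design collisions and raise an
    error listing the offending ids.
    """
    arch = arch or ReadArchitecture()
    lookup: dict[tuple[str, str], str] = {}
    collisions: dict[tuple[str, str], list[str]] = {}
    for row in manifest.itertuples(index=False):
        key = (row.spacer1, row.spacer2)
        if key in lookup:
            collisions.setdefault(key, [lookup[key]]).append(row.id)
        else:
            lookup[key] = row.id
    if collisions:
        detail = "; ".join(f"{k}: {v}" for k, v in collisions.items())
        raise ValueError(f"duplicate spacer pairs in manifest: {detail}")
    return PgRNAIndex(
        lookup=lookup,
        arch=arch,
        spacer1_lengths=tuple(sorted({len(k[0]) for k in lookup}, reverse=True)),
        spacer2_lengths=tuple(sorted({len(k[1]) for k in lookup}, reverse=True)),
        ids=list(manifest["id"]),
    )


def _open_maybe_gz(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _fastq_seqs(path: str | Path) -> Iterator[str]:
    with _open_maybe_gz(path) as fh:
        for _title, seq, _qual in FastqGeneralIterator(fh):
            yield seq.upper()


_RC = str.maketrans("ACGTN", "TGCAN")


def count_read_pairs(
    r1: str | Path | Iterable[str],
    r2: str | Path | Iterable[str],
    index: PgRNAIndex,
    pool: str = "pool",
) -> CountTable:
    """Count read pairs whose two spacer regions exactly match a designed pgRNA.

    ``r1``/``r2`` are FASTQ paths (optionally .gz) or synchronized iterables
    of sequences. Spacer regions are extracted at the architecture's fixed
    offsets; candidate lengths are tried longest-first (expressed spacers are
    20 or 21 nt). Any mismatch sends the pair to the unmatched bin.
    """
    arch = index.arch
    o1, o2 = len(arch.r1_prefix), len(arch.r2_prefix)
    seqs1 = _fastq_seqs(r1) if isinstance(r1, (str, Path)) else iter(r1)
    seqs2 = _fastq_seqs(r2) if isinstance(r2, (str, Path)) else iter(r2)

    counts: dict[str, int] = {}
    total = 0
    unmatched = 0
    sentinel = object()
    while True:
        s1 = next(seqs1, sentinel)
        s2 = next(seqs2, sentinel)
        if s1 is sentinel and s2 is sentinel:
            break
        if s1 is sentinel or s2 is sentinel:
            raise ValueError(f"desynchronized mates at read pair {total}")
        total += 1
        hit = None
        for L1 in index.spacer1_lengths:
            cand1 = s1[o1:o1 + L1]
            for L2 in index.spacer2_lengths:
                cand2 = s2[o2:o2 + L2]
                if arch.spacer2_revcomp:
                    cand2 = cand2.translate(_RC)[::-1]
                hit = index.lookup.get((cand1, cand2))
                if hit is not None:
                    break
            if hit is not None:
                break
        if hit is None:
            unmatched += 1
        else:
            counts[hit] = counts.get(hit, 0) + 1
    return CountTable(pool=pool, counts=counts, total_read_pairs=total,
                      unmatched=unmatched)


def normalize_cpm(counts: np.ndarray | Sequence[int]) -> np.ndarray:
    """Scale matched counts to counts-per-million (sums to 1e6)."""
    x = np.asarray(counts, dtype=float)
    total = x.sum()
    if total <= 0:
        raise ValueError("cannot normalize an all-zero count table")
    return x * (1e6 / total)


def log2_fold_change(
    sorted_norm: np.ndarray | Sequence[float],
    control_norm: np.ndarray | Sequence[float],
    pseudocount: float = 1.0,
) -> np.ndarray:
    """log2((sorted + pc) / (control + pc)) per pgRNA."""
    s = np.asarray(sorted_norm, dtype=float)
    c = np.asarray(control_norm, dtype=float)
    if s.shape != c.shape:
        raise ValueError(f"mismatched pgRNA universes: {s.shape} vs {c.shape}")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    return np.log2((s + pseudocount) / (c + pseudocount))


def empirical_enrichment(
    log2fc: Mapping[str, float] | pd.Series,
    negative_control_ids: Sequence[str],
) -> pd.DataFrame:
    """Enrichment z-scores and one-sided empirical p against the negative null.

    z = (x - mean_neg) / sd_neg; p = (r + 1) / (n + 1) where r is the number
    of negative controls with log2FC >= x. The empirical p is monotone
    decreasing in x and uniform when all pgRNAs are drawn from the null.
    Requires >= 20 negative controls.
    """
    series = pd.Series(log2fc, dtype=float)
    neg_ids = [i for i in negative_control_ids if i in series.index]
    if len(neg_ids) < 20:
        raise ValueError(f"need >= 20 negative controls, got {len(neg_ids)}")
    neg = series.loc[neg_ids].to_numpy()
    sd = neg.std(ddof=1)
    if sd == 0:
        raise ValueError("negative-control log2FC has zero variance")
    x = series.to_numpy()
    z = (x - neg.mean()) / sd
    neg_sorted = np.sort(neg)
    r = len(neg) - np.searchsorted(neg_sorted, x, side="left")
    p = (r + 1) / (len(neg) + 1)
    return pd.DataFrame({
        "id": series.index,
        "log2fc": x,
        "z": z,
        "p": p,
        "is_negative_control": series.index.isin(neg_ids),
    }).set_index("id")
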