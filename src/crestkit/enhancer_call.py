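"""Enhancer calling from per-segment functional scores.

Per-segment scores arrive either from an external screen-analysis model
(RELICS-scale, ingested from TSV) or from the internal z-scale scorer that
averages pgRNA enrichment z over each segment. Functional sequences (FS) are
segments above a threshold; maximal runs of adjacent FS are merged, and a
merged fragment is called an enhancer when its median score exceeds the
calling threshold and it contains at least two FS. Calls are then annotated
against gene TSS/body tables and arbitrary interval sets.

Thresholds: RELICS-scale ingested scores use median > 0.2; the internal
z-scale scorer uses z > 2 — the two scales are not comparable and each
carries its own default.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .library_design import PairedGuide

__all__ = [
    "SegmentScore",
    "FunctionalSequence",
    "EnhancerCall",
    "RELICS_MEDIAN_THRESHOLD",
    "INTERNAL_Z_THRESHOLD",
    "score_segments_internal",
    "load_external_scores",
    "identify_functional_sequences",
    "merge_and_call",
    "annotate_tss",
    "overlap_summary",
    "calls_to_frame",
]

RELICS_MEDIAN_THRESHOLD = 0.2
INTERNAL_Z_THRESHOLD = 2.0


@dataclass(frozen=True)
class SegmentScore:
    chrom: str
    start: int
    end: int
    score: float  # NaN = no data
    source: str = "internal"  # "internal" or "external"


@dataclass(frozen=True)
class FunctionalSequence:
    chrom: str
    start: int
    end: int
    score: float


@dataclass(frozen=True)
class EnhancerCall:
    chrom: str
    start: int
    end: int
    median_score: float
    n_functional_sequences: int
    members: tuple[FunctionalSequence, ...] = ()

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


def score_segments_internal(
    pairs: Sequence[PairedGuide],
    z: Mapping[str, float],
    window_start: int,
    window_end: int,
    segment_size: int = 100,
    chrom: str = "chrS",
) -> list[SegmentScore]:
    """Tile the window into segments and score each as the mean pgRNA z.

    A pgRNA contributes to every segment its deletion interval overlaps.
    Segments with no overlapping pgRNA are scored NaN (missing), not zero.
    """
    if segment_size <= 0:
        raise ValueError("segment_size must be positive")
    edges = np.arange(window_start, window_end + segment_size, segment_size)
    edges[-1] = max(edges[-1], window_end)
    n_seg = len(edges) - 1
    sums = np.zeros(n_seg)
    counts = np.zeros(n_seg, dtype=np.int64)
    any_overlap = False
    for p in pairs:
        if p.id not in z:
            continue
        a, b = p.deletion
        a, b = max(a, window_start), min(b, window_end)
        if b <= a:
            continue
        any_overlap = True
        first = int((a - window_start) // segment_size)
        last = int((b - 1 - window_start) // segment_size)
        sums[first:last + 1] += z[p.id]
        counts[first:last + 1] += 1
    if not any_overlap:
        raise ValueError("no pgRNA deletion overlaps the analysis window")
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return [
        SegmentScore(chrom, int(edges[i]), int(min(edges[i + 1], window_end)),
                     float(means[i]), source="internal")
        for i in range(n_seg)
    ]


def load_external_scores(path: str | Path) -> list[SegmentScore]:
    """Load per-segment scores (chrom/start/end/score TSV), validating tiling.

    Rows must be sorted and non-overlapping within each chromosome; the
    offending row index is named on failure.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "score"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    segments: list[SegmentScore] = []
    last_end: dict[str, int] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        if row.end <= row.start:
            raise ValueError(f"{path} row {i}: empty or inverted interval")
        prev = last_end.get(row.chrom)
        if prev is not None and row.start < prev:
            raise ValueError(f"{path} row {i}: overlaps or is out of order")
        last_end[row.chrom] = row.end
        segments.append(SegmentScore(str(row.chrom), int(row.start), int(row.end),
                                     float(row.score), source="external"))
    return segments


def identify_functional_sequences(
    scores: Sequence[SegmentScore],
    threshold: float,
) -> list[FunctionalSequence]:
    """Segments with score strictly above threshold, order preserved."""
    return [FunctionalSequence(s.chrom, s.start, s.end, s.score)
            for s in scores
            if not np.isnan(s.score) and s.score > threshold]


def merge_and_call(
    fs: Sequence[FunctionalSequence],
    median_threshold: float = RELICS_MEDIAN_THRESHOLD,
    min_fs: int = 2,
    gap_tolerance: int = 0,
) -> list[EnhancerCall]:
    """Merge maximal runs of adjacent FS and apply the enhancer-calling rule.

    Adjacency means the next FS starts within ``gap_tolerance`` bp of the
    previous end (default 0 = abutting segments). A merged run is called an
    enhancer iff median(member scores) > median_threshold and it contains at
    least ``min_fs`` members. The median of an even-sized set is the mean of
    the two middle values.
    """
    calls: list[EnhancerCall] = []
    run: list[FunctionalSequence] = []

    def flush():
        if not run:
            return
        med = float(np.median([m.score for m in run]))
        if med > median_threshold and len(run) >= min_fs:
            calls.append(EnhancerCall(
                chrom=run[0].chrom, start=run[0].start, end=run[-1].end,
                median_score=med, n_functional_sequences=len(run),
                members=tuple(run),
            ))

    for seg in fs:
        if run and (seg.chrom != run[-1].chrom
                    or seg.start > run[-1].end + gap_tolerance
                    or seg.start < run[-1].end):
            flush()
            run = []
        run.append(seg)
    flush()
    return calls


def annotate_tss(
    calls: Sequence[EnhancerCall],
    gene_table: pd.DataFrame,
    target_gene: str,
) -> pd.DataFrame:
    """Distance of each call midpoint to the target gene's TSS, and gene-body
    overlap flag (half-open intervals; abutting does not overlap).

    ``gene_table`` needs columns gene, chrom, tss, body_start, body_end.
    """
    rows = gene_table.loc[gene_table["gene"] == target_gene]
    if rows.empty:
        raise KeyError(f"unknown target gene: {target_gene}")
    g = rows.iloc[0]
    out = []
    for c in calls:
        signed = c.midpoint - float(g["tss"])
        in_body = (c.chrom == g["chrom"]
                   and c.start < int(g["body_end"]) and int(g["body_start"]) < c.end)
        out.append({
            "chrom": c.chrom, "start": c.start, "end": c.end,
            "tss_distance": abs(signed), "tss_distance_signed": signed,
            "in_gene_body": bool(in_body),
        })
    return pd.DataFrame(out, columns=["chrom", "start", "end", "tss_distance",
                                      "tss_distance_signed", "in_gene_body"])


def _any_overlap(call: EnhancerCall, intervals: Sequence[tuple[str, int, int]]) -> bool:
    return any(c == call.chrom and call.start < e and s < call.end
               for c, s, e in intervals)


def overlap_summary(
    calls: Sequence[EnhancerCall],
    annotation_sets: Mapping[str, Sequence[tuple[str, int, int]]],
) -> tuple[pd.DataFrame, dict[tuple[str, ...], int]]:
    """Per-call membership matrix over named interval sets plus upset-style
    combination counts.

    Membership is any base-pair overlap. The empty combination () collects
    calls overlapping no set — the "hidden enhancer" class. Combination
    counts always sum to the number of calls.
    """
    if not annotation_sets:
        raise ValueError("need at least one annotation set")
    names = list(annotation_sets)
    rows = []
    combos: dict[tuple[str, ...], int] = {}
    for c in calls:
        membership = {n: _any_overlap(c, annotation_sets[n]) for n in names}
        rows.append({"chrom": c.chrom, "start": c.start, "end": c.end, **membership})
        key = tuple(n for n in names if membership[n])
        combos[key] = combos.get(key, 0) + 1
    matrix = pd.DataFrame(rows, columns=["chrom", "start", "end", *names])
    return matrix, combos


def calls_to_frame(calls: Sequence[EnhancerCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"chrom": c.chrom, "start": c.start, "end": c.end,
          "median_score": c.median_score,
          "n_functional_sequences": c.n_functional_sequences}
         for c in calls],
        columns=["chrom", "start", "end", "median_score", "n_functional_sequences"],
    )
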