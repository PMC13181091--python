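"""Allele-specific expression and allelic compensation effect (ACE) analysis.

Allele counting assigns each amplicon read to one allele of a biallelic SNP
by exact containment of a k-mer window (default 21 bp) centered on the SNP,
in either orientation. The compensation index (CI) is the compensating
allele's reporter signal in an enhancer-deletion clone relative to control
cells (CI = 1: no compensation). ACE kinetics come from per-adjacent-
timepoint slopes of compensation-allele change against deletion-allele
change, and from a logarithmic trend fit y = a*ln(x) + b.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy import stats
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .library_design import revcomp

__all__ = [
    "SNPLocus",
    "AlleleCounts",
    "TimeCourse",
    "CompensationResult",
    "build_allele_kmers",
    "count_alleles",
    "allelic_ratio",
    "compensation_index",
    "adjacent_slopes",
    "adjacent_slopes_vs_time",
    "log_trend_fit",
]


@dataclass(frozen=True)
class SNPLocus:
    """A biallelic SNP with enough flanking context to build allele windows.

    ``context`` is genomic sequence containing the SNP position;
    ``snp_offset`` is the SNP's index within it. The base stored in the
    context at that offset is ignored — the alleles substitute it.
    """

    chrom: str
    position: int  # 0-based genomic coordinate
    ref_allele: str
    alt_allele: str
    context: str
    snp_offset: int

    def __post_init__(self):
        if self.ref_allele == self.alt_allele:
            raise ValueError("alleles must differ")
        for a in (self.ref_allele, self.alt_allele):
            if len(a) != 1 or a not in "ACGT":
                raise ValueError(f"allele must be a single ACGT base, got {a!r}")
        if not 0 <= self.snp_offset < len(self.context):
            raise ValueError("snp_offset outside context")


@dataclass(frozen=True)
class AlleleCounts:
    count_allele1: int
    count_allele2: int
    count_unassigned: int
    k: int = 21

    @property
    def assigned(self) -> int:
        return self.count_allele1 + self.count_allele2


@dataclass(frozen=True)
class TimeCourse:
    """Dual-reporter intensities over time, normalized so wild type = 1."""

    times: np.ndarray
    deletion_signal: np.ndarray
    compensation_signal: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        for name in ("deletion_signal", "compensation_signal"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != t.shape:
                raise ValueError(f"{name} length mismatch")
            if np.any(v < 0):
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class CompensationResult:
    ci: float
    slopes: np.ndarray
    log_fit: tuple[float, float, float]  # (a, b, r_squared)


def build_allele_kmers(locus: SNPLocus, k: int = 21) -> dict[str, tuple[str, str]]:
    """Build the two allele k-mers (SNP at the center) and their reverse
    complements.

    Returns {"allele1": (kmer, revcomp), "allele2": (kmer, revcomp)} where
    allele1 carries the ref base and allele2 the alt base at index (k-1)/2.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd so the SNP sits at the center")
    half = (k - 1) // 2
    off = locus.snp_offset
    if off < half or off + half >= len(locus.context):
        raise ValueError(
            f"insufficient context: need {half} bases each side of the SNP"
        )
    left = locus.context[off - half:off].upper()
    right = locus.context[off + 1:off + half + 1].upper()
    out = {}
    for name, base in (("allele1", locus.ref_allele), ("allele2", locus.alt_allele)):
        kmer = left + base + right
        out[name] = (kmer, revcomp(kmer))
    return out


def _read_stream(reads: str | Path | Iterable[str]) -> Iterable[str]:
    if isinstance(reads, (str, Path)):
        with open(reads) as fh:
            for _t, seq, _q in FastqGeneralIterator(fh):
                yield seq.upper()
    else:
        for seq in reads:
            yield seq.upper()


def count_alleles(
    reads: str | Path | Iterable[str],
    kmers: dict[str, tuple[str, str]],
) -> AlleleCounts:
    """Assign each read to an allele by exact k-mer containment.

    A read counts for allele i iff it contains allele i's window (either
    orientation) and not the other's; reads containing neither or both are
    unassigned.
    """
    k1_f, k1_r = kmers["allele1"]
    k2_f, k2_r = kmers["allele2"]
    n1 = n2 = un = 0
    for seq in _read_stream(reads):
        has1 = k1_f in seq or k1_r in seq
        has2 = k2_f in seq or k2_r in seq
        if has1 and not has2:
            n1 += 1
        elif has2 and not has1:
            n2 += 1
        else:
            un += 1
    return AlleleCounts(n1, n2, un, k=len(k1_f))


def allelic_ratio(
    counts: AlleleCounts,
    ci_level: float = 0.95,
) -> dict[str, float | tuple[float, float]]:
    """Allele fractions over assigned reads with an exact binomial CI.

    The CI (Clopper-Pearson) is for allele 1's fraction.
    """
    n = counts.assigned
    if n == 0:
        raise ValueError("no assigned reads")
    f1 = counts.count_allele1 / n
    ci = stats.binomtest(counts.count_allele1, n).proportion_ci(
        confidence_level=ci_level, method="exact"
    )
    return {
        "fraction_allele1": f1,
        "fraction_allele2": 1 - f1,
        "ci_allele1": (float(ci.low), float(ci.high)),
        "n_assigned": n,
    }


def compensation_index(clone_signal, control_signal):
    """CI = clone / control; elementwise over replicate clones.

    CI = 1 means no compensation; CI > 1 means the intact allele is
    upregulated relative to control cells.
    """
    clone = np.asarray(clone_signal, dtype=float)
    control = np.asarray(control_signal, dtype=float)
    if np.any(control <= 0):
        raise ValueError("control signal must be positive")
    return clone / control


def adjacent_slopes(tc: TimeCourse) -> np.ndarray:
    """Slope of compensation-allele change vs deletion-allele change between
    consecutive timepoints; NaN flags a zero denominator.
    """
    if len(tc.times) < 2:
        raise ValueError("need at least 2 timepoints")
    dx = np.diff(tc.deletion_signal)
    dy = np.diff(tc.compensation_signal)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(dx != 0, dy / dx, np.nan)


def adjacent_slopes_vs_time(tc: TimeCourse) -> np.ndarray:
    """Time-indexed variant: compensation-allele change per day."""
    if len(tc.times) < 2:
        raise ValueError("need at least 2 timepoints")
    return np.diff(tc.compensation_signal) / np.diff(tc.times)


def log_trend_fit(x, y) -> tuple[float, float, float]:
    """Least-squares fit of y = a*ln(x) + b; returns (a, b, R^2).

    R^2 = 1 - SS_res/SS_tot, reported as NaN when SS_tot = 0 (constant y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.any(x <= 0):
        raise ValueError("x must be positive for a logarithmic fit")
    design = np.column_stack([np.log(x), np.ones_like(x)])
    (a, b), *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - (a * np.log(x) + b)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return float(a), float(b), r2
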