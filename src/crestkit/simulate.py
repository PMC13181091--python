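"""Seeded synthetic data with known ground truth.

Generators for random genomes, pooled-screen count data / FASTQ, allelic
amplicon reads, and dual-reporter allelic-compensation time courses. Every
generator is a pure function of its parameters and seed and returns a truth
record alongside the data, so downstream modules can be tested end to end
without any external downloads.

The screen simulator mirrors the structure of a FACS-sorted deletion screen:
cells carry one pgRNA each, reporter expression per cell is log-normal,
pgRNAs whose deletion overlaps a planted enhancer shift expression down by
the effect size, and the sorted pool is the empirical bottom quantile
(default 1%) of the expression mixture. Counts are overdispersed via a
gamma-mixed Poisson (negative binomial).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .library_design import GenomeSequence, PairedGuide, revcomp

__all__ = [
    "SimulationTruth",
    "make_genome",
    "simulate_screen",
    "ReadArchitecture",
    "write_fastq_pair",
    "simulate_amplicon",
    "simulate_ace_timecourse",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationTruth:
    """Ground truth emitted by a generator run."""

    seed: int
    planted_enhancers: list[tuple[int, int, float]] = field(default_factory=list)
    planted_features: dict = field(default_factory=dict)
    abundances: dict[str, float] = field(default_factory=dict)
    expected_counts: dict[str, dict[str, float]] = field(default_factory=dict)
    allele_ratio: float | None = None
    ace_params: dict | None = None


def make_genome(
    length: int,
    gc: float = 0.41,
    seed: int = 0,
    name: str = "chrS",
    planted_motifs: Sequence[tuple[int, str]] = (),
) -> tuple[GenomeSequence, SimulationTruth]:
    """Generate an i.i.d. random genome at the requested GC content.

    ``planted_motifs`` is a list of (offset, sequence) insertions overwritten
    onto the random background; they are recorded in the truth table.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    seq = rng.choice(_BASES, size=length, p=p)
    for offset, motif in planted_motifs:
        if offset < 0 or offset + len(motif) > length:
            raise ValueError(f"planted motif at {offset} outside genome")
        seq[offset:offset + len(motif)] = list(motif.upper())
    truth = SimulationTruth(seed=seed,
                            planted_features={"motifs": list(planted_motifs)})
    return GenomeSequence(name, "".join(seq)), truth


@dataclass(frozen=True)
class ReadArchitecture:
    """Where each expressed spacer sits in the paired-end reads.

    R1 carries spacer1 and R2 carries spacer2, each after a constant
    vector-derived prefix; ``spacer2_revcomp`` indicates whether R2 reads the
    cassette from the opposite strand.
    """

    r1_prefix: str = "TTGTGGAAAGGACGAAACACCG"[-8:]
    r2_prefix: str = "TTCTAGCTCTAAAACG"[-8:]
    spacer2_revcomp: bool = False
    read_length: int = 50


def _overlaps(interval: tuple[int, int], enhancers: Sequence[tuple[int, int, float]]) -> float:
    """Largest planted effect whose interval overlaps ``interval`` (0 if none)."""
    a, b = interval
    effect = 0.0
    for ea, eb, eff in enhancers:
        if a < eb and ea < b:
            effect = max(effect, eff)
    return effect


def simulate_screen(
    pairs: Sequence[PairedGuide],
    planted_enhancers: Sequence[tuple[int, int, float]],
    depth: int = 1_000_000,
    sorted_fraction: float = 0.01,
    dispersion: float = 0.2,
    expression_sd: float = 1.0,
    seed: int = 0,
    controls: Sequence = (),
) -> tuple[dict[str, np.ndarray], list[str], SimulationTruth]:
    """Simulate control and sorted pgRNA count vectors.

    Each pgRNA i has a latent abundance a_i ~ Gamma(1/dispersion, dispersion)
    (mean 1, CV^2 = dispersion). Reporter expression of cells carrying i is
    Normal(mu_i, expression_sd) on the log scale, with mu_i = -effect for
    pgRNAs whose deletion overlaps a planted enhancer, mu_i = -6 sd for
    reporter-targeting positive controls (expression abolished), and 0
    otherwise. The FACS gate is the ``sorted_fraction`` quantile of the
    abundance-weighted expression mixture; the sorted pool re-weights each
    pgRNA by its probability of falling below the gate. Counts in each pool
    are Poisson draws at the given depth (gamma mixing supplies the
    overdispersion).

    ``controls`` are :class:`~crestkit.library_design.ControlPair` entries
    appended to the library: negative controls leave expression unshifted,
    positive (reporter-targeting) controls abolish it (-6 sd).

    Returns ({"control": counts, "sorted": counts}, ids, truth).
    """
    if not pairs:
        raise ValueError("empty design")
    rng = np.random.default_rng(seed)
    ids = [p.id for p in pairs] + [c.id for c in controls]
    n = len(ids)
    mu = np.zeros(n)
    for i, p in enumerate(pairs):
        mu[i] = -_overlaps(p.deletion, planted_enhancers)
    for j, c in enumerate(controls):
        mu[len(pairs) + j] = -6.0 * expression_sd if c.kind == "positive" else 0.0

    shape = 1.0 / dispersion if dispersion > 0 else None
    if shape is not None:
        abundance = rng.gamma(shape, dispersion, size=n)
    else:
        abundance = np.ones(n)
    w = abundance / abundance.sum()

    # FACS gate: sorted_fraction quantile of the normal mixture, by bisection
    def mixture_cdf(t: float) -> float:
        return float(np.sum(w * stats.norm.cdf((t - mu) / expression_sd)))

    lo, hi = mu.min() - 8 * expression_sd, mu.max() + 8 * expression_sd
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if mixture_cdf(mid) < sorted_fraction:
            lo = mid
        else:
            hi = mid
    gate = 0.5 * (lo + hi)
    p_sorted = stats.norm.cdf((gate - mu) / expression_sd)
    w_sorted = w * p_sorted
    w_sorted = w_sorted / w_sorted.sum()

    if depth < 10 * n:
        import warnings
        warnings.warn(f"depth {depth} low for library of {n} pgRNAs")
    counts = {
        "control": rng.poisson(depth * w),
        "sorted": rng.poisson(depth * w_sorted),
    }
    truth = SimulationTruth(
        seed=seed,
        planted_enhancers=list(planted_enhancers),
        abundances=dict(zip(ids, w)),
        expected_counts={
            "control": dict(zip(ids, depth * w)),
            "sorted": dict(zip(ids, depth * w_sorted)),
        },
    )
    return counts, ids, truth


def reads_for_pair(spacer1: str, spacer2: str, arch: ReadArchitecture) -> tuple[str, str]:
    """The (R1, R2) read sequences produced by one cassette under ``arch``."""
    s2 = revcomp(spacer2) if arch.spacer2_revcomp else spacer2
    pad = "ACGT" * (arch.read_length // 4 + 4)
    r1 = (arch.r1_prefix + spacer1 + pad)[:arch.read_length]
    r2 = (arch.r2_prefix + s2 + pad)[:arch.read_length]
    return r1, r2


def write_fastq_pair(
    counts: Mapping[str, int],
    spacers: Mapping[str, tuple[str, str]],
    arch: ReadArchitecture,
    r1_path: str | Path,
    r2_path: str | Path,
    seed: int = 0,
) -> None:
    """Write deterministic R1/R2 FASTQ files with the given per-pgRNA counts.

    Read-pair order is a seeded shuffle so the files look like a sequencer's
    output rather than sorted blocks.
    """
    rng = np.random.default_rng(seed)
    records: list[tuple[str, str, str]] = []
    for pid, n in counts.items():
        s1, s2 = spacers[pid]
        r1, r2 = reads_for_pair(s1, s2, arch)
        records.extend((pid, r1, r2) for _ in range(int(n)))
    order = rng.permutation(len(records))
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for k, idx in enumerate(order):
            pid, r1, r2 = records[idx]
            q1 = "I" * len(r1)
            q2 = "I" * len(r2)
            f1.write(f"@read{k}/{pid}\n{r1}\n+\n{q1}\n")
            f2.write(f"@read{k}/{pid}\n{r2}\n+\n{q2}\n")


def simulate_amplicon(
    kmer_allele1: str,
    kmer_allele2: str,
    ratio: float,
    n_reads: int,
    error_rate: float = 0.0,
    read_length: int = 75,
    seed: int = 0,
) -> tuple[list[str], SimulationTruth]:
    """Simulate amplicon reads over a biallelic SNP.

    Each read carries allele 1's window with probability ``ratio`` and
    allele 2's otherwise, embedded in shared flanking sequence; uniform
    substitution errors at ``error_rate`` per base.
    """
    if not 0 <= ratio <= 1:
        raise ValueError("ratio must be in [0, 1]")
    if error_rate >= 0.05:
        raise ValueError("error_rate must be < 0.05")
    rng = np.random.default_rng(seed)
    k = len(kmer_allele1)
    flank_len = max((read_length - k) // 2, 0)
    left = "".join(rng.choice(_BASES, size=flank_len))
    right = "".join(rng.choice(_BASES, size=flank_len))
    templates = [left + kmer_allele1 + right, left + kmer_allele2 + right]
    picks = rng.random(n_reads) >= ratio  # False -> allele 1
    reads: list[str] = []
    for pick in picks:
        read = np.array(list(templates[int(pick)]))
        if error_rate > 0:
            err = rng.random(len(read)) < error_rate
            if err.any():
                shift = rng.integers(1, 4, size=int(err.sum()))
                base_idx = np.searchsorted(_BASES, read[err])
                read[err] = _BASES[(base_idx + shift) % 4]
        reads.append("".join(read))
    truth = SimulationTruth(seed=seed, allele_ratio=ratio)
    return reads, truth


def simulate_ace_timecourse(
    timepoints: Sequence[float],
    onset_day: float = 2.0,
    floor: float = 0.4,
    decay_rate: float = 0.35,
    compensation_gain: float = 1.0,
    noise_sd: float = 0.0,
    conserve_total: bool = False,
    seed: int = 0,
):
    """Simulate a dual-reporter allelic-compensation time course.

    The deletion allele decays exponentially from 1 toward ``floor`` after
    ``onset_day``; the compensation allele rises above 1 with the configured
    gain. With ``conserve_total`` the compensating allele is defined as
    2 - deletion signal (pre-noise), so the two alleles sum exactly to the
    wild-type total and every compensation-vs-loss slope is -1.

    Returns a :class:`crestkit.allelic_ace.TimeCourse`.
    """
    from .allelic_ace import TimeCourse

    t = np.asarray(timepoints, dtype=float)
    if t.ndim != 1 or len(t) == 0:
        raise ValueError("timepoints required")
    rng = np.random.default_rng(seed)
    elapsed = np.clip(t - onset_day, 0.0, None)
    deletion = floor + (1.0 - floor) * np.exp(-decay_rate * elapsed)
    if conserve_total:
        compensation = 2.0 - deletion
    else:
        compensation = 1.0 + compensation_gain * (1.0 - deletion)
    if noise_sd > 0:
        deletion = deletion + rng.normal(0, noise_sd, size=len(t))
        compensation = compensation + rng.normal(0, noise_sd, size=len(t))
    tc = TimeCourse(times=t, deletion_signal=np.clip(deletion, 0, None),
                    compensation_signal=np.clip(compensation, 0, None))
    truth = SimulationTruth(seed=seed, ace_params={
        "onset_day": onset_day, "floor": floor, "decay_rate": decay_rate,
        "compensation_gain": compensation_gain, "noise_sd": noise_sd,
        "conserve_total": conserve_total,
    })
    return tc, truth
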