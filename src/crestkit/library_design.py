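"""Design of paired-guide (pgRNA) tiling-deletion libraries.

A pgRNA expresses two SpCas9 sgRNAs from one construct; the two blunt cuts
excise the genomic segment between them. A tiling library pairs guide sites
sequentially across a multi-megabase window so that every nucleotide is
covered by a target number of deletions (typically 15x or 20x), with
deletion sizes in a configured band (2,000-3,500 bp for targeting pairs).

Coordinates are 0-based half-open throughout. The SpCas9 cut is placed 3 bp
5' of the NGG PAM (between protospacer positions 17/18), the canonical blunt
cut; a pair's deletion interval is [upstream cut, downstream cut).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomeSequence",
    "TargetWindow",
    "GuideSite",
    "PairedGuide",
    "ControlPair",
    "OligoRecord",
    "DesignConfig",
    "LibraryDesign",
    "CoverageUnattainableError",
    "OligoAssemblyError",
    "scan_guide_sites",
    "normalize_spacer",
    "filter_spacers",
    "normalize_and_filter",
    "design_library",
    "design_to_manifest",
    "pair_sequential",
    "coverage_profile",
    "design_negative_controls",
    "design_positive_controls",
    "assemble_oligo",
    "assemble_oligos",
    "export_library",
    "read_manifest",
    "OLIGO_TEMPLATES",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Motifs that may not appear in an expressed spacer: Pol III terminators and
# the BsmBI recognition site (both orientations), which would be cut during
# two-step Golden-Gate cloning.
SPACER_FORBIDDEN_MOTIFS = ("AATAAA", "TTTTT", "TTTTTT", "CGTCTC", "GAGACG")

# Stricter set applied to non-targeting negative-control sequences; TTNTT
# matches N = any single base.
CONTROL_FORBIDDEN_MOTIFS = ("TTT", "TTNTT", "TTTTTT", "AATAAA", "AAAAA", "CGTCTC", "GAGACG")

# Synthesis templates for the dual-sgRNA oligo. Template A is used for the
# APP/FMR1/SIN3A libraries, template B for MECP2. Each is a 5-segment
# concatenation: fixed5 + spacer1 + linker1 + barcode + linker2 + spacer2 +
# fixed3, where linker1/linker2 carry the two BsmBI sites of the cloning
# scheme.
OLIGO_TEMPLATES: Mapping[str, tuple[str, str, str, str]] = {
    "A": ("CTTGGAGAAAAGCCTTGTTT", "GTTTAGAGACG", "CGTCTCACACC", "GTTTTAGAGCTAGAAATAGCAAGTT"),
    "B": ("TGTGGAAAGGACGAAACACC", "GTTTAAGAGACG", "CGTCTCTTGTTT", "GTTTTAGAGCTAGAAATAGCAAGTT"),
}

_BSMBI = ("CGTCTC", "GAGACG")

MANIFEST_COLUMNS = [
    "id", "kind", "spacer1", "spacer2", "chrom",
    "del_start", "del_end", "barcode", "template",
]


class CoverageUnattainableError(ValueError):
    """Raised when the available guide sites cannot reach the coverage target."""

    def __init__(self, achieved: float, target: float):
        self.achieved = achieved
        self.target = target
        super().__init__(
            f"coverage unattainable: achieved {achieved:.2f}x of target {target:.2f}x"
        )


class OligoAssemblyError(ValueError):
    pass


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _validate_dna(seq: str, *, what: str = "sequence", allow_n: bool = False) -> str:
    seq = seq.upper()
    alphabet = "ACGTN" if allow_n else "ACGT"
    if not seq or any(b not in alphabet for b in seq):
        raise ValueError(f"invalid {what}: must be non-empty over {{{alphabet}}}")
    return seq


@dataclass(frozen=True)
class GenomeSequence:
    name: str
    sequence: str

    def __post_init__(self):
        object.__setattr__(self, "sequence", _validate_dna(self.sequence, what="genome", allow_n=True))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TargetWindow:
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.end <= self.start or self.start < 0:
            raise ValueError(f"invalid window [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GuideSite:
    spacer: str               # genome-matching 20-mer
    expressed_spacer: str     # after the 5'-G rule (20 or 21 nt)
    strand: str               # "+" or "-"
    pam_start: int            # genome coordinate of the PAM's first base
    cut_site: int             # blunt-cut coordinate, 3 bp 5' of the PAM


@dataclass(frozen=True)
class PairedGuide:
    id: str
    guide1: GuideSite
    guide2: GuideSite
    chrom: str
    barcode: str = ""
    clipped: bool = False

    @property
    def deletion(self) -> tuple[int, int]:
        a, b = self.guide1.cut_site, self.guide2.cut_site
        return (a, b) if a < b else (b, a)

    @property
    def deletion_length(self) -> int:
        a, b = self.deletion
        return b - a


@dataclass(frozen=True)
class ControlPair:
    id: str
    kind: str                 # "negative" or "positive"
    seq1: str
    seq2: str
    target: str = "none"      # "none", "EGFP" or "mCherry"


@dataclass(frozen=True)
class OligoRecord:
    id: str
    full_sequence: str
    template_id: str


@dataclass(frozen=True)
class DesignConfig:
    target_coverage: float = 15.0
    deletion_size_window: tuple[int, int] = (2000, 3500)
    control_distance_window: tuple[int, int] = (1500, 2000)
    forbidden_spacer_motifs: tuple[str, ...] = SPACER_FORBIDDEN_MOTIFS
    forbidden_control_motifs: tuple[str, ...] = CONTROL_FORBIDDEN_MOTIFS
    seed: int = 0

    def __post_init__(self):
        if self.target_coverage < 1:
            raise ValueError("coverage must be >= 1")
        lo, hi = self.deletion_size_window
        if not (0 < lo <= hi):
            raise ValueError("invalid deletion size window")


@dataclass
class LibraryDesign:
    """A complete designed library: targeting pairs, controls, and oligos."""

    window: TargetWindow
    pairs: list[PairedGuide] = field(default_factory=list)
    controls: list[ControlPair] = field(default_factory=list)
    oligos: list[OligoRecord] = field(default_factory=list)
    template_id: str = "A"
    refused: list[str] = field(default_factory=list)  # ids dropped at oligo assembly


# ---------------------------------------------------------------------------
# guide-site discovery and spacer processing

_PLUS_SITE = re.compile(r"(?=([ACGT]{20})[ACGT]GG)")
_MINUS_SITE = re.compile(r"(?=CC[ACGT]([ACGT]{20}))")


def scan_guide_sites(genome: GenomeSequence, window: TargetWindow) -> list[GuideSite]:
    """Find every SpCas9 protospacer (20 nt + NGG PAM) on both strands.

    Only sites whose protospacer and PAM lie entirely inside ``window`` are
    returned, sorted by cut site. The expressed spacer field is left equal to
    the genomic spacer; apply :func:`normalize_spacer` / :func:`filter_spacers`
    downstream.
    """
    if window.start < 0 or window.end > len(genome):
        raise ValueError(
            f"window [{window.start}, {window.end}) outside genome of length {len(genome)}"
        )
    seq = genome.sequence[window.start:window.end]
    sites: list[GuideSite] = []
    for m in _PLUS_SITE.finditer(seq):
        spacer = m.group(1)
        pam_start = window.start + m.start() + 20
        sites.append(GuideSite(spacer, spacer, "+", pam_start, pam_start - 3))
    for m in _MINUS_SITE.finditer(seq):
        spacer = revcomp(m.group(1))
        pam_start = window.start + m.start()  # forward coord of the CCN triplet
        sites.append(GuideSite(spacer, spacer, "-", pam_start, pam_start + 6))
    sites.sort(key=lambda s: (s.cut_site, s.strand, s.pam_start))
    return sites


def normalize_spacer(spacer: str) -> str:
    """Apply the 5'-G rule: prepend a G to spacers that do not start with G.

    The human U6 promoter initiates transcription on G, so non-G spacers get
    a G added, yielding a 21-nt expressed spacer; the genome-matching 20-mer
    is kept separately for coordinates.
    """
    spacer = _validate_dna(spacer, what="spacer")
    if len(spacer) != 20:
        raise ValueError(f"spacer must be 20 nt, got {len(spacer)}")
    return spacer if spacer.startswith("G") else "G" + spacer


def _contains_motif(seq: str, motifs: Iterable[str]) -> bool:
    for motif in motifs:
        if "N" in motif:
            if re.search(motif.replace("N", "[ACGT]"), seq):
                return True
        elif motif in seq:
            return True
    return False


def filter_spacers(sites: Sequence[GuideSite], cfg: DesignConfig) -> list[GuideSite]:
    """Drop sites whose expressed spacer contains a terminator or BsmBI motif.

    The filter runs on the expressed spacer (after the G rule); order is
    preserved.
    """
    return [s for s in sites
            if not _contains_motif(s.expressed_spacer, cfg.forbidden_spacer_motifs)]


def normalize_and_filter(sites: Sequence[GuideSite], cfg: DesignConfig) -> list[GuideSite]:
    """Convenience: apply the G rule then the motif filter."""
    normalized = [replace(s, expressed_spacer=normalize_spacer(s.spacer)) for s in sites]
    return filter_spacers(normalized, cfg)


# ---------------------------------------------------------------------------
# sequential pairing

def pair_sequential(
    sites: Sequence[GuideSite],
    window: TargetWindow,
    cfg: DesignConfig,
) -> list[PairedGuide]:
    """Pair guide sites sequentially into tiling deletions.

    Deterministic tiling: sites sorted by cut site are walked in passes. In a
    pass, the leftmost unused site at or beyond the cursor becomes an anchor;
    its partner is the nearest downstream site whose cut-site distance lies in
    the deletion-size window (ties toward the smaller distance, then the
    leftmost). The cursor then advances by that pair's deletion length, so a
    full pass adds roughly 1x per-nucleotide coverage; each subsequent pass
    starts with a small phase offset. Passes repeat until the mean per-base
    coverage over the window reaches ``cfg.target_coverage``.

    Raises :class:`CoverageUnattainableError` (carrying the achieved
    coverage) when the sites are exhausted first.
    """
    if len(sites) < 2:
        raise CoverageUnattainableError(0.0, cfg.target_coverage)
    sites = sorted(sites, key=lambda s: s.cut_site)
    cuts = np.array([s.cut_site for s in sites])
    dmin, dmax = cfg.deletion_size_window
    used = np.zeros(len(sites), dtype=bool)
    window_len = len(window)

    pairs: list[PairedGuide] = []
    total_deleted = 0
    n_passes_est = max(int(np.ceil(cfg.target_coverage)), 1)
    phase_step = dmin / max(n_passes_est, 1)
    pass_no = 0
    while total_deleted < cfg.target_coverage * window_len:
        made_pair = False
        cursor = window.start + (pass_no * phase_step) % dmin
        pass_no += 1
        # leftmost unused site index at or beyond cursor, maintained lazily
        while True:
            start_idx = int(np.searchsorted(cuts, cursor, side="left"))
            idx = start_idx
            while idx < len(sites) and used[idx]:
                idx += 1
            if idx >= len(sites):
                break
            anchor = sites[idx]
            lo = int(np.searchsorted(cuts, anchor.cut_site + dmin, side="left"))
            hi = int(np.searchsorted(cuts, anchor.cut_site + dmax, side="right"))
            used[idx] = True
            if lo >= hi:
                # no partner in range (window edge); skip this anchor
                cursor = anchor.cut_site + 1
                continue
            partner = sites[lo]  # nearest downstream in range; leftmost on ties
            pair = PairedGuide(
                id=f"pg{len(pairs):06d}",
                guide1=anchor,
                guide2=partner,
                chrom=window.chrom,
                clipped=partner.cut_site > window.end or anchor.cut_site < window.start,
            )
            pairs.append(pair)
            a, b = pair.deletion
            total_deleted += min(b, window.end) - max(a, window.start)
            made_pair = True
            cursor = anchor.cut_site + pair.deletion_length
            if total_deleted >= cfg.target_coverage * window_len:
                break
        if not made_pair:
            achieved = total_deleted / window_len
            raise CoverageUnattainableError(achieved, cfg.target_coverage)
    return pairs


def coverage_profile(
    pairs: Sequence[PairedGuide], window: TargetWindow
) -> tuple[np.ndarray, dict[str, float]]:
    """Per-base deletion coverage over the window, plus (mean, min, max).

    The mean satisfies the exact identity
    ``mean * window_length == sum of clipped deletion lengths``.
    """
    profile = np.zeros(len(window), dtype=np.int64)
    for p in pairs:
        a, b = p.deletion
        a = max(a, window.start) - window.start
        b = min(b, window.end) - window.start
        if b > a:
            profile[a] += 1
            if b < len(profile):
                profile[b] -= 1
    profile = np.cumsum(profile)
    summary = {
        "mean": float(profile.mean()) if len(profile) else 0.0,
        "min": float(profile.min()) if len(profile) else 0.0,
        "max": float(profile.max()) if len(profile) else 0.0,
    }
    return profile, summary


# ---------------------------------------------------------------------------
# controls

def _kmer_occurrences(genome_seq: str, k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for strand_seq in (genome_seq, revcomp(genome_seq)):
        for i in range(len(strand_seq) - k + 1):
            kmer = strand_seq[i:i + k]
            counts[kmer] = counts.get(kmer, 0) + 1
    return counts


def design_negative_controls(
    genome: GenomeSequence,
    n_pairs: int,
    cfg: DesignConfig,
) -> list[ControlPair]:
    """Design non-targeting negative-control pairs.

    Eligible sequences are 20-mers that occur exactly once in the genome
    (uniqueness pooled over both strands), are not followed by an NGG PAM at
    their occurrence, start with G after the G rule, and contain none of the
    control-forbidden motifs. Eligible sequences are paired so the intra-pair
    genomic distance falls in ``cfg.control_distance_window``.
    """
    seq = genome.sequence
    # occurrences pooled over both strands: counting the k-mer on the forward
    # sequence and on its reverse complement makes counts[kmer] the total
    # number of genomic occurrences on either strand.
    occurrences = _kmer_occurrences(seq, 20)
    eligible: list[tuple[int, str]] = []  # (position, expressed sequence)
    for i in range(len(seq) - 20):
        kmer = seq[i:i + 20]
        if "N" in kmer or occurrences.get(kmer, 0) != 1:
            continue
        nxt = seq[i + 20:i + 23]
        if len(nxt) == 3 and nxt[1:] == "GG":
            continue
        expressed = kmer if kmer.startswith("G") else "G" + kmer
        if _contains_motif(expressed, cfg.forbidden_control_motifs):
            continue
        eligible.append((i, expressed))

    dmin, dmax = cfg.control_distance_window
    pairs: list[ControlPair] = []
    used = [False] * len(eligible)
    positions = [p for p, _ in eligible]
    for i, (pos, expr) in enumerate(eligible):
        if len(pairs) >= n_pairs:
            break
        if used[i]:
            continue
        lo = int(np.searchsorted(positions, pos + dmin, side="left"))
        hi = int(np.searchsorted(positions, pos + dmax, side="right"))
        partner_idx = next((j for j in range(lo, hi) if not used[j]), None)
        if partner_idx is None:
            continue
        used[i] = used[partner_idx] = True
        pairs.append(ControlPair(
            id=f"neg{len(pairs):04d}",
            kind="negative",
            seq1=expr,
            seq2=eligible[partner_idx][1],
        ))
        if len(pairs) >= n_pairs:
            break
    if len(pairs) < n_pairs:
        raise ValueError(
            f"insufficient eligible negative-control sequences: needed {n_pairs} "
            f"pairs, found {len(pairs)} from {len(eligible)} eligible 20-mers"
        )
    return pairs


def design_positive_controls(
    reporter_seqs: Mapping[str, str],
    cfg: DesignConfig | None = None,
) -> list[ControlPair]:
    """Design reporter-targeting positive controls.

    For each reporter coding sequence (EGFP, mCherry), the first 10 valid,
    filter-passing guide sites numbered 5'->3' are paired by the fixed index
    scheme (1,6), (2,7), (3,8), (4,9), (5,10).
    """
    cfg = cfg or DesignConfig()
    pairs: list[ControlPair] = []
    for target, seq in reporter_seqs.items():
        genome = GenomeSequence(target, seq)
        window = TargetWindow(target, 0, len(seq))
        sites = normalize_and_filter(scan_guide_sites(genome, window), cfg)
        # number sites 1..n by position along the coding sequence
        sites = sorted(sites, key=lambda s: s.cut_site)
        if len(sites) < 10:
            raise ValueError(
                f"reporter {target}: only {len(sites)} eligible guide sites, need 10"
            )
        chosen = sites[:10]
        for i in range(5):
            pairs.append(ControlPair(
                id=f"pos_{target}_{i + 1}_{i + 6}",
                kind="positive",
                seq1=chosen[i].expressed_spacer,
                seq2=chosen[i + 5].expressed_spacer,
                target=target,
            ))
    return pairs


# ---------------------------------------------------------------------------
# oligo assembly

def _template_bsmbi_count(template_id: str) -> int:
    fixed = "".join(OLIGO_TEMPLATES[template_id])
    return sum(fixed.count(site) for site in _BSMBI)


def _count_bsmbi(seq: str) -> int:
    return sum(seq.count(site) for site in _BSMBI)


def _barcode_introduces_motif(
    linker1: str, barcode: str, linker2: str, motifs: Iterable[str]
) -> bool:
    """True if any forbidden motif occurrence overlaps the barcode itself.

    Motifs wholly inside the flanking linkers belong to the template (the
    linkers carry the cloning scheme's BsmBI sites) and are not the
    barcode's fault.
    """
    s = linker1 + barcode + linker2
    b0, b1 = len(linker1), len(linker1) + len(barcode)
    for motif in motifs:
        start = 0
        while True:
            i = s.find(motif, start)
            if i == -1:
                break
            if i < b1 and i + len(motif) > b0:
                return True
            start = i + 1
    return False


def _draw_barcode(rng: np.random.Generator) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=10))


def assemble_oligo(
    item: PairedGuide | ControlPair,
    template_id: str,
    rng: np.random.Generator,
    used_barcodes: set[str] | None = None,
    cfg: DesignConfig | None = None,
    max_draws: int = 1000,
) -> tuple[OligoRecord, str]:
    """Assemble one synthesis oligo; returns (record, barcode).

    The 10-nt barcode is resampled until the full oligo carries exactly the
    template's own BsmBI occurrences, the barcode introduces no forbidden
    spacer motif, and the barcode is unique within ``used_barcodes``.
    Spacers that would themselves create an extra BsmBI site at a template
    junction cannot be rescued and raise :class:`OligoAssemblyError`.
    """
    cfg = cfg or DesignConfig()
    if isinstance(item, PairedGuide):
        s1, s2 = item.guide1.expressed_spacer, item.guide2.expressed_spacer
    else:
        s1, s2 = item.seq1, item.seq2
    for s in (s1, s2):
        if _count_bsmbi(s):
            raise OligoAssemblyError(f"{item.id}: spacer contains a BsmBI site")
    fixed5, linker1, linker2, fixed3 = OLIGO_TEMPLATES[template_id]
    expected_bsmbi = _template_bsmbi_count(template_id)
    # junction check with a motif-free placeholder barcode
    probe = fixed5 + s1 + linker1 + "ACACACACAC" + linker2 + s2 + fixed3
    if _count_bsmbi(probe) != expected_bsmbi:
        raise OligoAssemblyError(
            f"{item.id}: spacer/template junction creates an extra BsmBI site"
        )
    used_barcodes = used_barcodes if used_barcodes is not None else set()
    for _ in range(max_draws):
        barcode = _draw_barcode(rng)
        if barcode in used_barcodes:
            continue
        full = fixed5 + s1 + linker1 + barcode + linker2 + s2 + fixed3
        if _count_bsmbi(full) != expected_bsmbi:
            continue
        if _barcode_introduces_motif(linker1, barcode, linker2,
                                     cfg.forbidden_spacer_motifs):
            continue
        used_barcodes.add(barcode)
        return OligoRecord(item.id, full, template_id), barcode
    raise OligoAssemblyError(f"{item.id}: no acceptable barcode in {max_draws} draws")


def assemble_oligos(
    items: Sequence[PairedGuide | ControlPair],
    template_id: str,
    rng: np.random.Generator,
    cfg: DesignConfig | None = None,
) -> tuple[list[OligoRecord], dict[str, str]]:
    """Assemble oligos for a whole library with library-wide unique barcodes."""
    used: set[str] = set()
    records: list[OligoRecord] = []
    barcodes: dict[str, str] = {}
    for item in items:
        rec, bc = assemble_oligo(item, template_id, rng, used, cfg)
        records.append(rec)
        barcodes[item.id] = bc
    return records, barcodes


# ---------------------------------------------------------------------------
# whole-library driver and I/O

def design_library(
    genome: GenomeSequence,
    window: TargetWindow,
    cfg: DesignConfig,
    n_negative: int = 0,
    reporter_seqs: Mapping[str, str] | None = None,
    template_id: str = "A",
) -> LibraryDesign:
    """Run the full design: scan, G rule, filter, pair, controls, oligos."""
    sites = normalize_and_filter(scan_guide_sites(genome, window), cfg)
    pairs = pair_sequential(sites, window, cfg)
    controls: list[ControlPair] = []
    if n_negative:
        controls.extend(design_negative_controls(genome, n_negative, cfg))
    if reporter_seqs:
        controls.extend(design_positive_controls(reporter_seqs, cfg))
    rng = np.random.default_rng(cfg.seed)
    # a rare spacer can form a BsmBI site at a template junction; such pairs
    # cannot be synthesized under this cloning scheme and are dropped
    records: list[OligoRecord] = []
    barcodes: dict[str, str] = {}
    refused: list[str] = []
    used: set[str] = set()
    for item in [*pairs, *controls]:
        try:
            rec, bc = assemble_oligo(item, template_id, rng, used, cfg)
        except OligoAssemblyError:
            refused.append(item.id)
            continue
        records.append(rec)
        barcodes[item.id] = bc
    pairs = [replace(p, barcode=barcodes[p.id]) for p in pairs
             if p.id not in set(refused)]
    controls = [c for c in controls if c.id not in set(refused)]
    return LibraryDesign(window=window, pairs=pairs, controls=controls,
                         oligos=records, template_id=template_id,
                         refused=refused)


def design_to_manifest(design: LibraryDesign) -> pd.DataFrame:
    rows = []
    for p in design.pairs:
        a, b = p.deletion
        rows.append({
            "id": p.id, "kind": "targeting",
            "spacer1": p.guide1.expressed_spacer, "spacer2": p.guide2.expressed_spacer,
            "chrom": p.chrom, "del_start": a, "del_end": b,
            "barcode": p.barcode, "template": design.template_id,
        })
    for c in design.controls:
        rows.append({
            "id": c.id, "kind": c.kind,
            "spacer1": c.seq1, "spacer2": c.seq2,
            "chrom": "", "del_start": -1, "del_end": -1,
            "barcode": "", "template": design.template_id,
        })
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def export_library(design: LibraryDesign, out_prefix: str | Path) -> dict[str, Path]:
    """Write oligo FASTA, manifest TSV, and deletion BED (0-based half-open)."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out_prefix.with_suffix(".oligos.fa"),
        "manifest": out_prefix.with_suffix(".manifest.tsv"),
        "bed": out_prefix.with_suffix(".deletions.bed"),
    }
    with open(paths["fasta"], "w") as fh:
        for rec in design.oligos:
            fh.write(f">{rec.id}\n{rec.full_sequence}\n")
    manifest = design_to_manifest(design)
    manifest.to_csv(paths["manifest"], sep="\t", index=False)
    with open(paths["bed"], "w") as fh:
        for p in design.pairs:
            a, b = p.deletion
            fh.write(f"{p.chrom}\t{a}\t{b}\t{p.id}\n")
    return paths


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "barcode": str,
                                            "spacer1": str, "spacer2": str},
                     keep_default_na=False)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns: {sorted(missing)}")
    return df[MANIFEST_COLUMNS]
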