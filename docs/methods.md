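# Methods

crestkit re-implements the computational lifecycle of a paired-guide (pgRNA)
tiling-deletion CRISPR enhancer screen read out by reporter-based FACS:
library design, screen quantification, enhancer calling, allele-specific
expression and allelic-compensation (ACE) analysis, and promoter self-motif
discovery. This note records the models, the parameters that matter, and the
places where the design was genuinely open.

## Coordinates and sequence conventions

All intervals are 0-based half-open; BED on disk; 1-based coordinates appear
only in human-readable reports. The SpCas9 blunt cut is placed 3 bp 5' of
the NGG PAM (between protospacer positions 17/18). A pgRNA's deletion
interval is [upstream cut, downstream cut).

## Library design

**Guide discovery.** Both strands of the target window are scanned for
20-nt protospacers immediately 5' of an NGG PAM. Sites are sorted by cut
coordinate.

**5'-G rule.** U6-driven transcription initiates on G, so spacers not
starting with G get a G *prepended*, yielding a 21-nt expressed spacer; the
genome-matching 20-mer is kept separately for coordinates. Prepending (vs
substituting position 1) was an open choice — both appear in the field; we
read "add" literally and keep the perfect genomic match intact.

**Spacer filters.** Run on the expressed spacer, after the G rule. Spacers
containing Pol III terminators (AATAAA, TTTTT, TTTTTT) or BsmBI sites
(CGTCTC, GAGACG) are removed: terminators truncate the sgRNA, and stray
BsmBI sites are cut during the two-step Golden-Gate cloning.

**Sequential pairing.** Only "pair sequentially" is specified by the
protocol this emulates, so the algorithm here is one deterministic reading:
sites sorted by cut coordinate are walked in passes. Within a pass, the
leftmost unused site at or beyond the cursor anchors a pair; its partner is
the nearest downstream site whose cut-site distance lies in the
deletion-size window (ties: smaller distance, then leftmost), and the
cursor advances by the formed deletion's length, so one pass lays an
approximately contiguous 1x tile over the window. Subsequent passes start
with a small phase offset (del_min / ceil(coverage) per pass) to
decorrelate tile boundaries. Passes repeat until mean per-base coverage
reaches the target; exhaustion first raises a coverage-unattainable error
carrying the achieved coverage. Anchors are consumed; partners are
reusable.

Because partners are the *nearest* admissible site and guide sites are
dense (one per ~12 bp of random sequence), deletion lengths concentrate
just above the window minimum: a [2000, 3500] bp window yields mean
deletions of ~2,010 bp and a 2.0-Mb, 15x design yields ~15,000 pairs
(coverage x length / mean deletion). Defaults: coverage 15x, deletion
window 2,000–3,500 bp for targeting pairs.

**Coverage identity.** Mean per-base coverage x window length equals the
sum of window-clipped deletion lengths exactly; the per-base profile is a
difference-array cumsum and tests verify it against per-base counting.

**Negative controls.** Non-targeting pairs are built from 20-mers that (i)
occur exactly once in the genome with occurrences pooled over both strands,
(ii) are not followed by NGG at their occurrence, (iii) start with G after
the G rule, and (iv) contain none of TTT, TTNTT (N = any base), TTTTTT,
AATAAA, AAAAA, CGTCTC, GAGACG. Eligible sequences are paired at 1,500–2,000
bp spacing. For real genomes exact whole-genome uniqueness is expensive;
uniqueness is evaluated over the supplied sequence (target window plus
flank), which callers should note in output metadata.

**Positive controls.** The first ten filter-passing guide sites along each
reporter CDS (EGFP, mCherry), numbered 5'→3', paired by the fixed scheme
(1,6), (2,7), (3,8), (4,9), (5,10) — five pairs per reporter.

**Oligo assembly.** Two synthesis templates are supported (A for
APP/FMR1/SIN3A-style libraries, 117 nt with 20-nt spacers; B for
MECP2-style, 119 nt). The 10-nt barcode is uniform over ACGT and resampled
(cap 1,000 draws) until the oligo carries exactly the template's own two
BsmBI occurrences, no forbidden motif overlaps the barcode, and the barcode
is library-unique. A spacer that would create an extra BsmBI site at a
template junction (e.g. ending in GAGAC before a G) cannot be rescued by
resampling and is refused with an explicit error.

## Screen quantification

**Counting.** A read pair increments exactly one pgRNA iff both spacer
regions, extracted at fixed offsets given by the configured read
architecture, exactly match a designed pair; any mismatch sends the pair to
the unmatched bin. The exact-match rule makes an aligner unnecessary and
subsumes quality filtering. The read architecture (which mate carries which
spacer, constant-prefix offsets, R2 orientation) is a configuration object
because it is vector-specific; candidate spacer lengths (21 then 20 nt) are
tried longest-first, deterministically. Matched + unmatched == total on
every run.

**Normalization and fold change.** Matched counts are scaled to
counts-per-million; log2 fold change is log2((sorted+pc)/(control+pc)) with
pseudocount default 1 (counts scale), configurable.

**Empirical enrichment.** In place of a model-based per-guide test, each
pgRNA's log2FC is compared with the non-targeting negative-control null:
z = (x − mean_neg)/sd_neg and one-sided empirical p = (r+1)/(n+1), r the
number of negative controls ≥ x. At least 20 negatives are required; p is
monotone in x and uniform under the null. Note the p floor is 1/(n+1), so
small control sets bound attainable significance, and all p-values share
one negative sample — calibration tests keep the negative pool large
relative to the test set so the shared sample's CDF wobble (~1/sqrt(n))
does not masquerade as miscalibration.

## Enhancer calling

Scores arrive per tiling segment either from an external screen-analysis
model (RELICS-scale, ingested from TSV and validated as sorted,
non-overlapping) or from the internal scorer: mean enrichment z over all
pgRNAs whose deletion overlaps the segment (segments with no overlapping
pgRNA are missing, not zero). Segment size defaults to 100 bp
(configurable; the external model's segmentation is not printed).

Functional sequences are segments with score strictly above threshold.
Maximal runs of adjacent FS are merged — adjacency means abutting segments,
with a configurable gap tolerance (default 0) since adjacency across
unscored segments was an open question. A merged fragment is called an
enhancer iff its median member score exceeds the calling threshold *and* it
has at least two members. Medians of even-sized sets are the mean of the two
middle values. Thresholds: 0.2 on the RELICS scale for ingested scores; the
internal z scale is not comparable and uses z > 2.

Annotation: enhancer–TSS distance uses the call midpoint (the reference
point behind published distance summaries is not defined; midpoint is the
symmetric choice), with the signed version also reported; gene-body
membership and annotation-set membership are any base-pair overlap under
half-open intervals (abutting does not overlap). Upset-style combination
counts include the empty combination — the "hidden enhancer" class lacking
every examined chromatin signature.

**Resolution.** A deletion screen localizes to ~deletion size: every pgRNA
overlapping an enhancer carries the signal across its whole 2–3.5 kb
deletion, so call boundaries extend up to one deletion span beyond the true
element. Tests therefore count a call as a false positive only when it lies
wholly outside every planted region padded by one segment, and check that
boundaries stay within one deletion span of the planted element.

## Allelic analysis

**Allele counting.** Two k-mers (k = 21, odd, SNP base at the center
position (k−1)/2) represent the alleles. A read is assigned to an allele
iff it contains that allele's k-mer in either orientation and not the
other's; neither or both (possible only for k = 1 or chimeric reads) means
unassigned, and both-containing reads are counted rather than silently
dropped. Fractions over assigned reads carry exact (Clopper–Pearson)
binomial intervals.

**Compensation index.** CI = compensating-allele signal in the deletion
clone / the same signal in control cells, after normalizing all intensities
to the matched wild-type mean (CI = 1: no compensation). Flow-cytometry
inputs are pre-summarized per-sample intensities in TSV; raw cytometry file
parsing is out of scope.

**Kinetics.** Adjacent-timepoint slopes are Δ(compensation signal) /
Δ(deletion-allele signal) between consecutive timepoints — compensation
gained per unit lost — with zero denominators flagged NaN; a time-indexed
variant (per day) is also exposed, since either reading of "slope between
adjacent time points" is defensible. The trend fit is least squares of
y = a·ln(x) + b (natural log; base changes only a), with R² = 1 −
SS_res/SS_tot, NaN when y is constant. When the two alleles' sum is
conserved, every adjacent slope is −1 — the signature of exact
transcriptional compensation.

## Promoter self-motif discovery

Promoters are [TSS − 1 kb, TSS + 1 kb), minus-strand sequences
reverse-complemented to read 5'→3' with the gene; contig-edge clipping is
flagged. When a gene has several transcripts the first-listed row anchors
the promoter (the original analysis's transcript choice is unknowable).

PWMs come from count matrices with pseudocount 0.01, scored as
Σ log2(p_pos(base)/bg(base)) against a 0-order background estimated from
the scanned sequence set (richer backgrounds exist; 0-order is declared and
fixed). The exact p-value of a window score under the background is
computed by dynamic programming over the discretized score distribution:
per-column scores are mapped to an integer grid of step (score range)/1000
(configurable), convolved column by column with background weights, and the
tail sum gives P(score ≥ s). Tests verify the DP equals full 4^w
enumeration on the same grid for w ≤ 8, that the distribution sums to 1,
and that p is monotone in score. Both strands are scanned; windows
containing non-ACGT bases are skipped and counted. Default hit threshold
p < 1e-4.

A TF gene is a self-binding candidate iff at least one of its own motifs
hits its own promoter at threshold (deduplicated per gene; best hit
reported). Dosage enrichment builds, per sensitivity class
(haploinsufficient, triplosensitive), the 2x2 table candidate-vs-rest x
class-vs-not, reporting the sample (cross-product) odds ratio, two-sided
Fisher exact p, and class percentages among candidates.
Activator/repressor identities are consumed as an input table — curation is
data, not computation.

## Synthetic data

Generators are pure functions of (parameters, seed) — byte-identical across
runs — and return a truth record the test suite consumes.

**Genomes** are i.i.d. bases at a requested GC (default 0.41, a typical
human-locus value), with optional planted motif insertions recorded in the
truth table.

**Screens.** Each pgRNA's latent abundance is Gamma(1/φ, φ) (mean 1,
CV² = φ, default dispersion φ = 0.2), giving gamma-mixed-Poisson (negative
binomial) counts — a standard overdispersion model for pooled screens,
since no count-noise model is printed for the original data. Per-cell
reporter expression is log-normal (sd 1 on the log scale); pgRNAs deleting
a planted enhancer shift the log mean down by the effect size (3 "sd" in
the recovery tests), reporter-targeting positive controls by 6 sd, negative
controls not at all. The FACS gate is the abundance-weighted mixture's
bottom quantile (default 1%, matching a bottom-1% sort), found by
bisection; the sorted pool reweights each pgRNA by its probability of
falling below the gate. FASTQ emission places each expressed spacer after a
constant prefix per the configured read architecture, with a seeded shuffle
of read order.

What the simulator does not model: sequencing errors and indels in screen
reads, PCR jackpotting beyond gamma dispersion, cell-population dynamics
during differentiation, and survival selection. Passing recovery tests
therefore show the analysis chain is correct under a clean, explicitly
stated noise model — not that real screens of this depth always yield
zero false negatives.

**Amplicons** draw each read's allele Bernoulli(ratio) and apply uniform
substitution errors (< 5%); a read becomes unassignable when any of the 21
window bases is hit, so the unassigned fraction follows 1 − (1−e)^21,
which tests check.

**ACE trajectories.** The deletion allele decays exponentially from 1
toward a floor (default 0.4) after an onset day (default 2); the
compensation allele rises with a configurable gain, or, with the
conservation flag, is defined as 2 − deletion signal so the two alleles sum
exactly to the wild-type total pre-noise. Gaussian noise is optional.

## Problem sizes used in tests and the acceptance script

The acceptance script designs on a 2.0-Mb synthetic genome (the smallest
target-region size the emulated screens used) at 15x, and a 500-kb genome
for the deletion-size check; end-to-end recovery tests use 200-kb windows
at 15x and depth 1e6 with two planted enhancers of effect 3 sd — sizes
chosen so the full suite runs on a laptop-class single core in well under
a minute per test while preserving the screen's density regime (guide site
per ~12 bp, ~1,500 pairs per 200 kb).

## Known limitations

- The sequential-pairing stride rule is one deterministic reading of an
  underspecified protocol step; pair counts match the published scale but
  individual pairs will differ from any other reading.
- The internal z-scale segment scorer is a transparent substitute for a
  hierarchical-model scorer and does not deconvolve overlapping deletions;
  calls inherit ~deletion-size boundary resolution.
- Negative-control uniqueness is exact-match only (no near-match
  off-target screening) and restricted to the supplied sequence.
- The empirical-null p has resolution 1/(n_controls + 1).
- The PWM scan's 0-order background and 1/1000 discretization are fixed,
  declared simplifications of richer scanner defaults.
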