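"""Call enhancers end to end from a simulated screen.

Designs a 15x library over 200 kb with two planted enhancers, simulates the
sorted/control pools, scores 100-bp segments by mean enrichment z, and
applies the calling rule: merge adjacent functional sequences, keep merged
fragments with median score above threshold and at least two members.
"""

from crestkit.enhancer_call import (
    INTERNAL_Z_THRESHOLD,
    annotate_tss,
    identify_functional_sequences,
    merge_and_call,
    score_segments_internal,
)
from crestkit.library_design import (
    DesignConfig,
    TargetWindow,
    design_negative_controls,
    normalize_and_filter,
    pair_sequential,
    scan_guide_sites,
)
from crestkit.screen_quant import empirical_enrichment, log2_fold_change, normalize_cpm
from crestkit.simulate import make_genome, simulate_screen

import pandas as pd

LENGTH = 200_000
PLANTED = [(60_000, 61_500, 3.0), (140_000, 141_000, 3.0)]

genome, _ = make_genome(LENGTH, seed=3)
window = TargetWindow(genome.name, 0, LENGTH)
cfg = DesignConfig(target_coverage=15, deletion_size_window=(2000, 3500), seed=3)
sites = normalize_and_filter(scan_guide_sites(genome, window), cfg)
pairs = pair_sequential(sites, window, cfg)
negatives = design_negative_controls(genome, 30, cfg)

counts, ids, _ = simulate_screen(pairs, PLANTED, depth=1_000_000, seed=3,
                                 controls=negatives)
lfc = log2_fold_change(normalize_cpm(counts["sorted"]),
                       normalize_cpm(counts["control"]))
z = empirical_enrichment(dict(zip(ids, lfc)),
                         [c.id for c in negatives])["z"].to_dict()

segments = score_segments_internal(pairs, {p.id: z[p.id] for p in pairs},
                                   0, LENGTH, segment_size=100)
fs = identify_functional_sequences(segments, INTERNAL_Z_THRESHOLD)
calls = merge_and_call(fs, median_threshold=INTERNAL_Z_THRESHOLD, min_fs=2)

print(f"planted enhancers : {[(s, e) for s, e, _ in PLANTED]}")
print(f"enhancer calls    : {len(calls)}")
for c in calls:
    print(f"  [{c.start:>7,}, {c.end:>7,})  median z = {c.median_score:5.1f}  "
          f"n_FS = {c.n_functional_sequences}")

genes = pd.DataFrame({"gene": ["TARGET"], "chrom": [genome.name],
                      "tss": [100_000], "body_start": [100_000],
                      "body_end": [120_000]})
ann = annotate_tss(calls, genes, "TARGET")
print()
print(ann[["start", "end", "tss_distance", "in_gene_body"]].to_string(index=False))
print()
print("Each call spans the planted enhancer to within roughly one deletion "
      "size -- the physical resolution of a tiling-deletion screen. "
      "TSS distances use the call midpoint.")
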