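"""Design an MPRA library: 270 bp cores, shuffled negatives, assembly.

Selects a core window from an oversized enhancer using feature-set overlap
and motif-hit counts, builds shuffled negative controls, and assembles a
labelled library.
"""

import mpramix as mx

# a 1.2 kb candidate enhancer; evidence: one peak set and two motif hits
region = mx.GenomicInterval("chr7", 10_000, 11_200)
peaks = mx.FeatureSet("p300", [mx.GenomicInterval("chr7", 10_650, 10_800)])
motifs = [
    mx.GenomicInterval("chr7", 10_700, 10_715),
    mx.GenomicInterval("chr7", 10_740, 10_752),
]
core = mx.select_core_region(region, [peaks], motifs, target_len=270)
print(f"core region: {core.chrom}:{core.start}-{core.end} "
      f"({core.end - core.start} bp)")
# the window covers the peak and both motifs: evidence-dense core

design = mx.make_synthetic_library(
    n_candidates=500, n_positives=50, n_negatives=75, seed=1
)
print("library composition:", design.category_counts())
# counts partition the library; negatives are nucleotide shuffles of
# randomly chosen candidates, so they match candidate base composition

neg = design.by_category("negative_control")[0]
cand_seqs = {e.sequence for e in design.by_category("candidate")}
print("negative is a shuffle (same letters, new order):",
      sorted(neg.sequence) in [sorted(s) for s in cand_seqs])
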