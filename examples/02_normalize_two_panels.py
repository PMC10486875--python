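"""Housekeeping normalization, panel merge and detection filtering.

Ranks housekeeping candidates with the geNorm stability measure M, scales
samples to equalize housekeeping geometric means, merges the two panels on
their shared genes, and applies the limit-of-detection rule (negative
controls' mean + 2 SD, detection required in more than half the profiles).
"""

import immunopair as ip

cfg = ip.CohortConfig.desk_scale(seed=1)
panels, meta, truth = ip.simulate_cohort(cfg)

gres = ip.genorm(panels["IP"].gene_counts("housekeeping"), n_select=8)
print("least stable housekeeping candidates (eliminated first):",
      gres.elimination_order[:3])
print("most stable M values:",
      {g: round(float(gres.stability[g]), 3) for g in gres.selected[:4]})

expr, report = ip.normalize_cohort(panels, hk_n=8)
print(f"LOD threshold: {report['lod_threshold']:.2f} log2 counts")
print(f"genes in merged matrix: {report['n_genes']}, "
      f"detected above LOD: {report['n_genes_detected']}")
# A gene is kept only if it exceeds the background threshold in >50% of
# profiles; the merged matrix holds each gene once, averaging the shared
# genes after per-sample cross-panel rescaling.
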