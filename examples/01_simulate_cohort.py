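"""Simulate a paired two-panel cohort and inspect its structure.

Generates the scaled-down default cohort (12 patients, two panels of 120
endogenous + 16 housekeeping probes, 80 shared genes) with the default
planted treatment program: myeloid genes up, lymphocyte and MHC-II genes
down, flow lymphocyte counts up.
"""

import immunopair as ip

cfg = ip.CohortConfig.desk_scale(seed=1)
panels, meta, truth = ip.simulate_cohort(cfg)
flow = ip.simulate_flow_counts(cfg, truth)

for name, pcm in sorted(panels.items()):
    classes = pcm.probe_info["probe_class"].value_counts().to_dict()
    print(f"panel {name}: {pcm.counts.shape[0]} probes x "
          f"{pcm.counts.shape[1]} samples, classes = {classes}")
print(f"metadata: {meta['patient_id'].nunique()} patients, "
      f"{meta['sample_id'].nunique()} biological samples")
print(f"flow table: {flow.shape[0]} samples x {flow.shape[1]} columns "
      f"(18 populations + CBC)")
groups = truth.gene_group.value_counts().to_dict()
print(f"planted gene groups: {groups}")
print("planted log2 fold changes:", cfg.effect_table)
# Each probe count is negative-binomial around its gene's baseline times the
# sample's library factor; the group fold changes act only on post samples.
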