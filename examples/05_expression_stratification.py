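"""Expression of promoter-bound vs unbound genes (boxplot-style analysis).

Filters genes (<200 bp, rRNA, chrY), computes replicate-averaged FPKM
from the simulated count table, labels genes nonbound / dual / A_only /
B_only by promoter-window overlap with the final peak lists, and runs
two-sided Welch t tests on log2(FPKM+1) between the groups.
"""

from collections import Counter

from peakscape import (
    PipelineConfig,
    assign_groups,
    bound_genes,
    compare_groups,
    consensus_pipeline,
    filter_genes,
    fpkm,
)
from peakscape.simulate import SimConfig, simulate_dataset

ds = simulate_dataset(SimConfig(), seed=7, with_tags=False)
cfg = PipelineConfig()
finals = {
    f: consensus_pipeline(ds.peaks[f][0], ds.peaks[f][1:], ds.blacklist, cfg)[0]
    for f in ("A", "B")
}

filtered, removed = filter_genes(ds.annotation.genes, cfg)
print(f"gene filter removed {removed} of {len(ds.annotation.genes)} genes")
universe = [g.gene_id for g in filtered]
records = fpkm(ds.counts.loc[universe], filtered, cfg)
ba = bound_genes(finals["A"], filtered, cfg)
bb = bound_genes(finals["B"], filtered, cfg)
assign_groups(records, ba, bb, universe)
print("group sizes:", dict(Counter(r.group for r in records)))

for c in compare_groups(records, cfg=cfg):
    print(
        f"{c.group_a} vs {c.group_b}: t = {c.statistic:.2f}, "
        f"df = {c.degrees_of_freedom:.1f}, p = {c.p_value:.3g}"
    )
# Bound groups (dual, A_only) are far more highly expressed than nonbound
# genes (the simulation plants a log2 fold change of 2), while dual vs
# A_only shows no planted difference.
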