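"""Weighted-median intensity cells and DEG-identity Venn partitions.

The intensity statistic summarizes each comparison x category x
direction as the weighted median of five equal-width |log2FC| bins;
the Venn partition counts shared vs unique DEG identities across
comparison groups.
"""

import degpool as dp
from degpool import intensity, venn

cfg = dp.default_config(seed=1)
counts, design, _ = dp.simulate_counts(cfg)
annotation = dp.simulate_annotation(cfg)
filtered, _ = dp.filter_genes(counts)
fpkm = dp.fpkm(filtered, dp.tmm_factors(filtered))

results = []
for group in design.contrast_groups:
    results += dp.run_contrast_group(design, fpkm, group)

cells = dp.build_intensity_matrix(results, annotation, design)
shown = 0
for cell in cells:
    if not cell.excluded and shown < 6:
        print(
            f"{cell.label} [{cell.category} {cell.direction}]: n={cell.n}, "
            f"range {cell.value_range[0]:.2f}-{cell.value_range[1]:.2f}, "
            f"intensity {cell.value:.2f}"
        )
        shown += 1
print(f"... {sum(c.excluded for c in cells)} of {len(cells)} cells excluded (n <= 1)")

pooled = {}
for group in design.contrast_groups:
    group_results = [r for r in results if r.group == group]
    pooled[group] = venn.group_deg_union(group_results, annotation)
partition = dp.venn_partition(pooled)
print(f"\n4-way Venn over {partition.union_size} DEG identities:")
frame = partition.to_frame()
print(frame[frame["count"] > 0][["region", "count"]].to_string(index=False))
# Region 'A&B' counts genes differentially expressed in both comparison
# groups A and B but in no other group.
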