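"""Two-criterion DEG calls for one pairwise contrast.

A gene is differentially expressed when the absolute difference of
median-scaled group mean FPKM exceeds 1 AND |adjusted log2FC| >= 1;
genes absent from either group are not evaluable (no pseudocounts).
"""

import degpool as dp

cfg = dp.default_config(seed=1)
counts, design, truth = dp.simulate_counts(cfg)
filtered, _ = dp.filter_genes(counts)
fpkm = dp.fpkm(filtered, dp.tmm_factors(filtered))

contrast = design.contrast("citrus_vs_legume_head")
result = dp.call_degs(fpkm, contrast)

print(f"contrast: {contrast.label}  (group1={contrast.group1}, group2={contrast.group2})")
print(result.table["call"].value_counts().to_string())
# up_in_g1 genes are higher in citrus-feeding heads: the planted
# detoxification response shows up here.
top = result.degs("up_in_g1").nlargest(5, "adj_log2fc")
print("\nstrongest citrus-side DEGs (gene, dFPKM, adjusted log2FC):")
for gene, row in top.iterrows():
    print(f"  {gene}: dFPKM={row.dfpkm:.1f}, log2FC={row.adj_log2fc:.2f}")
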