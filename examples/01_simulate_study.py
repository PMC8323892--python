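"""Generate the bundled synthetic study and write its input files.

Creates a 20-sample, 5000-gene pooled RNA-seq design over three host
plants (with host-switch treatments), planted targeted-category effects,
and a ground-truth table, then writes everything as TSV/GMT/YAML.
"""

import degpool as dp
from degpool import io

cfg = dp.default_config(seed=1)
counts, design, truth = dp.simulate_counts(cfg)
annotation = dp.simulate_annotation(cfg)
gene_sets = dp.simulate_gene_sets(annotation, n_sets=30, seed=1)

paths = io.write_study(counts, design, annotation, gene_sets, truth, "scratch/example_study")

print(f"genes: {counts.n_genes}, samples: {counts.n_samples}")
print(f"contrasts: {len(design.contrasts)} in {len(design.contrast_groups)} groups")
print(f"planted effects: {len(truth)} gene x condition rows")
for name, path in paths.items():
    print(f"  {name}: {path}")
# The truth table is what parameter-recovery tests compare DEG calls against.
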