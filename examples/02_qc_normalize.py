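"""Quality filters and TMM/FPKM normalization on the synthetic study.

Shows the three gene filters (max-count < 2, >= 10 in one sample,
CPM >= 1 in two samples), the sample dominance flags, and the TMM scale
factors whose geometric mean is 1.
"""

import numpy as np

import degpool as dp

cfg = dp.default_config(seed=1)
counts, design, _ = dp.simulate_counts(cfg)

filtered, report = dp.filter_genes(counts)
print(report.to_frame().to_string(index=False))
# Each row: genes before/removed/after one filter rule, in applied order.

flags = dp.flag_outlier_samples(counts)
print(f"flagged samples: {sorted(flags.flagged_samples) or 'none'}")

factors = dp.tmm_factors(filtered)
print(f"TMM reference: {factors.reference}")
print(f"factor range: {factors.factors.min():.3f} - {factors.factors.max():.3f}")
print(f"geometric mean: {np.exp(np.mean(np.log(factors.factors))):.6f}  (always 1)")

fpkm = dp.fpkm(filtered, factors)
print(f"FPKM matrix: {fpkm.values.shape}, median FPKM {fpkm.values.stack().median():.2f}")
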