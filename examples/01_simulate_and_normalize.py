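"""Simulate a three-study benchmark and normalize it onto one common scale.

The generator draws negative-binomial counts for four cell sources
(PHH/liver controls, a hepatocyte-derived model, fibroblasts, fetal
hepatocytes) across three studies with batch effects and library-size
variation.  Normalization runs median-of-ratios size factors, the
closed-form variance-stabilizing transformation from a fitted
dispersion-mean trend, then quantile normalization.
"""

import numpy as np

import hlcbench as hb

config = hb.SimulationConfig(seed=1)
counts, metadata, truth = hb.simulate_multistudy_counts(config)
print(f"simulated {counts.shape[0]} genes x {counts.shape[1]} samples "
      f"across {metadata.table['study'].nunique()} studies")

normalized, reference = hb.normalize_counts(counts)
trend = reference.trend
print(f"dispersion trend: alpha(mu) = {trend.a1:.3f}/mu + {trend.alpha_inf:.3f} "
      f"(fit on {trend.n_genes_used} genes)")

values = normalized.data.to_numpy()
sorted_cols = np.sort(values, axis=0)
spread = np.abs(sorted_cols - sorted_cols[:, [0]]).max()
print(f"value range after normalization: [{values.min():.2f}, {values.max():.2f}] "
      f"(approximately log2 counts)")
print(f"max cross-column deviation of sorted values: {spread:.2e} "
      "(residual tie-averaging of repeated integer counts; exactly 0 for "
      "tie-free columns)")
print("-> every sample now shares one marginal distribution; differences "
      "between samples are rank (biology) driven")
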