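"""Cell QC, gene filtering and log-normalization on a simulated dataset.

The default thresholds (>= 2000 UMIs, 1000-8000 detected genes, <= 30%
mitochondrial counts) assume a full ~30k-gene transcriptome; the simulation
covers 2000 genes, so the detected-gene bounds are rescaled accordingly while
the library-size and mitochondrial rules keep their defaults.
"""

import cardioforest as cf

matrix, _ = cf.simulate_reference(cf.default_simulation_config(seed=3))

thresholds = cf.QCThresholds(min_genes=300, max_genes=1800)
filtered, report = cf.qc_filter_cells(matrix, thresholds)
print("cell QC:", report.summary())

kept = cf.filter_genes(filtered, min_cells=5)
print(f"gene filter: {filtered.n_genes} -> {kept.n_genes} genes (>=1 count in >=5 cells)")

cf.log_normalize(kept)
lognorm = kept.layers["lognorm"]
print(f"lognorm layer: shape {lognorm.shape}, max {lognorm.max():.2f}")
print("Values are log1p counts divided by per-cell library-size factors,")
print("the substrate for feature selection and classifier training.")
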