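"""Spike-in size factors and the expressed-gene filter.

Spike-in rows have identical expectations across samples, so per-sample
median-of-ratios over the spikes recovers each sample's global scaling.
Counts divided by the factor give normalized values; genes with
baseMean > 32 are called expressed. Gene intervals can be extended by
10% of their length at both ends before counting (the DRIP-seq
convention for signal bordering transcripts).
"""

import numpy as np
import pandas as pd

import trcmap as t

cfg = t.SimConfig(seed=1)
_, genes, _, _ = t.make_genome_and_annotation(cfg)

true_factors = {"mock": 1.0, "treated": 2.5}
counts = t.simulate_counts(genes, true_factors, n_spike=200, config=cfg)
factors = t.spikein_size_factors(counts)
print("recovered size factors (geometric mean 1):")
print(factors.round(4).to_string())
print(f"treated/mock ratio: {factors['treated'] / factors['mock']:.3f} "
      f"(truth: 2.5)")

normalized, expressed = t.normalize_and_filter(counts, factors, base_mean_min=32)
host = ~counts.index.str.startswith("spike_")
print(f"expressed host genes (baseMean > 32): "
      f"{int(expressed[host].sum())}/{int(host.sum())}")

extended = t.extend_gene_intervals(genes.head(1), fraction=0.10)
g0, e0 = genes.iloc[0], extended.iloc[0]
print(f"gene interval [{g0.Start}, {g0.End}) -> extended "
      f"[{e0.Start}, {e0.End})")

# downstream differential labels operate on an external DE table
de = pd.DataFrame({"padj": np.linspace(0.001, 1.0, 1000),
                   "log2FoldChange": np.tile([1.0, -1.0], 500)},
                  index=[f"g{i}" for i in range(1000)])
labels = t.label_deg(de)
controls = t.select_control_genes(de, n=100, padj_floor=0.5, seed=1)
print(f"DEG labels: {labels.value_counts().to_dict()}; "
      f"control set: {len(controls)} genes with padj > 0.5")
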