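"""Build a synthetic DSB study with known ground truth.

Two 1 Mb chromosomes carry 50 stranded genes and 8 early-replicated
regions (ERRs); 20 break hotspots are planted at promoters inside ERRs,
so each has a known fork direction and head-on / co-directional class.
"""

import trcmap as t

cfg = t.SimConfig(seed=1)
chrom_sizes, genes, errs, truth = t.make_genome_and_annotation(cfg)
reads, truth = t.simulate_bliss_reads(genes, errs, truth, cfg)

print(f"chromosomes : {chrom_sizes}")
print(f"genes       : {len(genes)} (strand balance "
      f"{(genes.Strand == '+').mean():.2f} '+')")
print(f"ERRs        : {len(errs)}, origins at interval midpoints")
print(f"hotspots    : {len(truth.hotspots)} planted, classes "
      f"{truth.hotspots.trc_class.value_counts().to_dict()}")
print(f"break reads : {len(reads)} "
      f"({int(reads.is_duplicate.sum())} PCR duplicates, "
      f"{(reads.mapq < 30).mean():.1%} below MAPQ 30)")
# Each read row mimics an aligned sBLISS read: position, strand, MAPQ
# and the 16 nt UMI+barcode prefix the lab protocol attaches.
print(reads.head(3).to_string(index=False))
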