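"""Call BLISS+ regions: down-sample, bin, threshold, merge, union.

Samples are equalised to the smallest library (down-sampling by UMI),
the genome is tiled in 2 kb bins, bins with more than 22 UMIs are
positive, positive bins within 2 kb merge into regions, and replicate
regions are unioned per condition.
"""

import trcmap as t

cfg = t.SimConfig(seed=1)
chrom_sizes, genes, errs, truth = t.make_genome_and_annotation(cfg)
reads, truth = t.simulate_bliss_reads(genes, errs, truth, cfg)
events = t.deduplicate(t.filter_mapq(reads))

by = {s: g.drop(columns="sample_id").reset_index(drop=True)
      for s, g in events.groupby("sample_id")}
print("UMIs per sample  :", {s: int(d.umi_count.sum()) for s, d in by.items()})
by = t.downsample(by, seed=1)
print("after down-sample:", {s: int(d.umi_count.sum()) for s, d in by.items()})

region_sets = {}
for s, ev in by.items():
    bins = t.bin_coverage(ev, chrom_sizes, bin_size=2000)
    pos = t.call_positive_bins(bins, threshold=22)
    region_sets[s] = t.merge_bins(pos, max_gap=2000)
    print(f"{s}: {len(pos)} positive bins -> {len(region_sets[s])} regions")

union = t.union_regions(list(region_sets.values()))
print(f"union of replicates: {len(union)} BLISS+ regions")

hs = truth.hotspots
hit = sum(
    any((r.Chromosome == h.Chromosome and h.Start < r.End and r.Start < h.End)
        for r in union.itertuples())
    for h in hs.itertuples()
)
print(f"planted hotspots recovered: {hit}/{len(hs)}")
print("replicate overlap matrix (fraction of rows' regions hit):")
print(t.overlap_matrix(region_sets).round(2).to_string())
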