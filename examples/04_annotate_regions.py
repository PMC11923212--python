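"""Annotate called regions against genes and early-replicated regions.

Each region is promoter / intragenic / extragenic (promoter = strand-
aware TSS window, default -2000/+500 bp), flagged for >=1 bp overlap
with ERRs and expressed transcripts, clustered by the two flags, and
profiled against the EdU-HU replication signal.
"""

import trcmap as t

cfg = t.SimConfig(seed=1)
chrom_sizes, genes, errs, truth = t.make_genome_and_annotation(cfg)
edu_hu, eu = t.make_signal_tracks(genes, errs, step=1000, config=cfg)
reads, truth = t.simulate_bliss_reads(genes, errs, truth, cfg)
events = t.deduplicate(t.filter_mapq(reads))
bins = t.bin_coverage(events.drop(columns="sample_id"), chrom_sizes)
regions = t.merge_bins(t.call_positive_bins(bins))

cat = t.annotate_category(regions, genes)
print("genomic categories:", cat.value_counts().to_dict())

flags, fractions = t.flag_overlaps(regions, errs, genes[genes.expressed])
print(f"fraction overlapping an ERR        : {fractions['err_fraction']:.2f}")
print(f"fraction overlapping a transcript  : {fractions['transcript_fraction']:.2f}")

clusters = t.assign_cluster(flags)
print("clusters (1=transcript&ERR, 2=ERR only, 3=transcript only):",
      clusters.value_counts().to_dict())

profile = t.metagene_profile(edu_hu, regions, flank=50_000, n_points=11,
                             clusters=clusters)
print("mean EdU-HU metagene profile around region centers, by cluster:")
print(profile.round(3).to_string())
# Cluster-1 regions sit inside ERRs, so their profile rises toward the
# center; the replication signal is what makes these sites conflict-prone.
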