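"""Head-on vs co-directional classification of DSB regions.

The replication origin of each ERR is the smoothed maximum of the
EdU-HU signal; forks move outward, so positions past the origin see a
rightward fork. A region near an expressed gene is head-on when fork
and transcription approach each other, co-directional when they agree.
"""

import trcmap as t

cfg = t.SimConfig(seed=1)
chrom_sizes, genes, errs, truth = t.make_genome_and_annotation(cfg)
edu_hu, _ = t.make_signal_tracks(genes, errs, step=1000, config=cfg)

err = errs.iloc[0]
origin = t.locate_origin(edu_hu, err, smooth_bins=5)
print(f"{err.err_id} {err.Chromosome}:{err.Start}-{err.End} -> "
      f"origin located at {origin} (truth: {err.origin})")
print(f"fork direction 5 kb past the origin: "
      f"{t.fork_direction_at(origin + 5000, origin)}")

planted = truth.hotspots[truth.hotspots.trc_class != "none"]
regions = planted[["Chromosome", "Start", "End"]].reset_index(drop=True)
calls = t.classify_trc(regions, errs, edu_hu, genes, assoc_window=10_000)
agree = (calls.trc_class.to_numpy()
         == planted.trc_class.to_numpy())[calls.trc_class != "unclassified"]
print(f"planted hotspot windows classified: "
      f"{(calls.trc_class != 'unclassified').sum()}/{len(calls)}; "
      f"agreement with planted classes: {agree.mean():.0%}")
print(t.summarize_trc(calls).to_string(index=False))
# head_on + co_directional fractions are over classified calls only.
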