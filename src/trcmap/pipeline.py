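"""End-to-end orchestration: break table -> BLISS+ regions -> annotation
-> TRC classes, from a single validated configuration.

Stages run in a fixed order (MAPQ filter -> dedup -> down-sample ->
bin/call/merge per sample -> replicate union per condition -> annotate
-> TRC -> summaries). Every stage is a pure function of its inputs and
the configuration, so identical config + inputs give byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from trcmap import annotation, hotspots, io, reads as reads_mod, spikein, trc
from trcmap.tracks import SignalTrack

log = logging.getLogger("trcmap")

_POSITIVE_INT = (
    "bin_size",
    "track_step",
)
_NONNEG_INT = (
    "min_mapq",
    "pos_window",
    "umi_mismatch",
    "threshold",
    "max_gap",
    "promoter_upstream",
    "promoter_downstream",
    "assoc_window",
    "proximal_distance",
    "n_control_genes",
)


@dataclass
class RunConfig:
    """All stage parameters plus input paths; every analysis constant is
    a named field with its conventional default."""

    breaks: str | None = None
    chrom_sizes: str | None = None
    genes: str | None = None
    errs: str | None = None
    edu_hu: str | None = None
    counts: str | None = None
    condition_map: dict[str, str] = field(default_factory=dict)

    min_mapq: int = 30
    pos_window: int = 10
    umi_mismatch: int = 1
    bin_size: int = 2000
    threshold: int = 22
    max_gap: int = 2000
    promoter_upstream: int = 2000
    promoter_downstream: int = 500
    proximal_distance: int = 0
    assoc_window: int = 10_000
    smooth_bins: int = 5
    track_step: int = 1000
    base_mean_min: float = 32.0
    extend_fraction: float = 0.10
    padj_max: float = 0.05
    padj_floor: float = 0.5
    n_control_genes: int = 500
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def validate_config(config) -> list[str]:
    """Domain checks; returns a list of violations (empty = ok).

    Accepts a RunConfig or a plain dict (unknown keys are violations,
    not exceptions).
    """
    if isinstance(config, dict):
        try:
            config = RunConfig.from_dict(config)
        except (ValueError, TypeError) as exc:
            return [str(exc)]
    v: list[str] = []
    for name in _POSITIVE_INT:
        if getattr(config, name) <= 0:
            v.append(f"{name} must be positive, got {getattr(config, name)}")
    for name in _NONNEG_INT:
        if getattr(config, name) < 0:
            v.append(f"{name} must be >= 0, got {getattr(config, name)}")
    if config.smooth_bins < 1:
        v.append(f"smooth_bins must be >= 1, got {config.smooth_bins}")
    for name in ("padj_max", "padj_floor"):
        val = getattr(config, name)
        if not 0.0 <= val <= 1.0:
            v.append(f"{name} must be in [0, 1], got {val}")
    if config.base_mean_min < 0:
        v.append(f"base_mean_min must be >= 0, got {config.base_mean_min}")
    if config.extend_fraction < 0:
        v.append(f"extend_fraction must be >= 0, got {config.extend_fraction}")
    return v


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run every stage and write regions, annotation, TRC calls and a
    machine-readable summary under ``outdir``. Returns the summary."""
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    chrom_sizes = io.read_chrom_sizes(config.chrom_sizes)
    genes = io.read_genes_bed(config.genes)
    errs = io.read_errs_bed(config.errs)
    edu_hu = SignalTrack.from_bedgraph(config.edu_hu, chrom_sizes, config.track_step)
    breaks = io.read_breaks(config.breaks)
    summary: dict = {"config": config.to_dict(), "stages": {}}

    def stage(name, **counts):
        log.info("stage %s: %s", name, counts)
        summary["stages"][name] = counts

    stage("input", reads=len(breaks))
    kept = reads_mod.filter_mapq(breaks, config.min_mapq)
    stage("filter_mapq", reads_in=len(breaks), reads_out=len(kept))

    if kept.empty:
        events_by_sample: dict[str, pd.DataFrame] = {}
    else:
        events = reads_mod.deduplicate(
            kept, pos_window=config.pos_window, max_umi_mismatch=config.umi_mismatch
        )
        events_by_sample = {
            s: g.drop(columns=["sample_id"]).reset_index(drop=True)
            for s, g in events.groupby("sample_id")
        }
    stage(
        "dedup",
        events={s: len(df) for s, df in sorted(events_by_sample.items())},
        umis={s: int(df["umi_count"].sum()) for s, df in sorted(events_by_sample.items())},
    )

    if events_by_sample:
        events_by_sample = hotspots.downsample(events_by_sample, seed=config.seed)
    stage(
        "downsample",
        umis={s: int(df["umi_count"].sum()) for s, df in sorted(events_by_sample.items())},
    )

    regions_by_sample = {}
    for s, ev in sorted(events_by_sample.items()):
        bins = hotspots.bin_coverage(ev, chrom_sizes, config.bin_size)
        pos = hotspots.call_positive_bins(bins, config.threshold)
        regions_by_sample[s] = hotspots.merge_bins(pos, config.max_gap)
    stage("call", regions={s: len(r) for s, r in sorted(regions_by_sample.items())})

    conditions = sorted(set(config.condition_map.values())) or ["all"]
    cond_samples = {
        c: [s for s, cc in sorted(config.condition_map.items()) if cc == c]
        for c in conditions
    }
    if not config.condition_map:
        cond_samples = {"all": sorted(regions_by_sample)}
    regions_by_condition = {}
    for c in conditions:
        sets = [regions_by_sample[s] for s in cond_samples[c] if s in regions_by_sample]
        merged = (
            hotspots.union_regions(sets)
            if sets
            else pd.DataFrame(columns=["Chromosome", "Start", "End"])
        )
        regions_by_condition[c] = merged
        io.write_regions_bed(merged, outdir / f"regions_{c}.bed")
    stage("union", regions={c: len(r) for c, r in sorted(regions_by_condition.items())})

    # expressed-gene flags: from spike-normalized counts when provided
    genes = genes.copy()
    if config.counts:
        counts = pd.read_csv(config.counts, sep="\t", index_col=0)
        factors = spikein.spikein_size_factors(counts)
        _, expressed = spikein.normalize_and_filter(
            counts, factors, config.base_mean_min
        )
        genes["expressed"] = (
            genes["gene_id"].map(expressed).fillna(False).astype(bool)
        )
        factors.to_csv(outdir / "size_factors.tsv", sep="\t")
    else:
        genes["expressed"] = True
    transcripts = genes[genes["expressed"]]

    annotated_frames = {}
    for c, regs in sorted(regions_by_condition.items()):
        cat = annotation.annotate_category(
            regs, genes, config.promoter_upstream, config.promoter_downstream
        )
        flags, fractions = annotation.flag_overlaps(
            regs, errs, transcripts, config.proximal_distance
        )
        clusters = annotation.assign_cluster(flags)
        ann = regs.copy()
        ann["category"] = cat
        ann["overlaps_err"] = flags["overlaps_err"]
        ann["overlaps_transcript"] = flags["overlaps_transcript"]
        ann["cluster"] = clusters
        ann.to_csv(outdir / f"annotated_{c}.tsv", sep="\t", index=False)
        annotated_frames[c] = (ann, clusters)
        n = len(regs)
        summary["stages"].setdefault("annotate", {})[c] = {
            "category_fractions": {
                k: (int((cat == k).sum()) / n if n else 0.0)
                for k in ("promoter", "intragenic", "extragenic")
            },
            **fractions,
        }

    for c, (ann, clusters) in sorted(annotated_frames.items()):
        calls = trc.classify_trc(
            ann,
            errs,
            edu_hu,
            genes,
            assoc_window=config.assoc_window,
            smooth_bins=config.smooth_bins,
            fallback_midpoint=True,
        )
        calls.to_csv(outdir / f"trc_{c}.tsv", sep="\t", index=False)
        overall = trc.summarize_trc(calls)
        summary["stages"].setdefault("trc", {})[c] = {
            "head_on": int(overall["head_on"].iloc[0]) if len(overall) else 0,
            "co_directional": (
                int(overall["co_directional"].iloc[0]) if len(overall) else 0
            ),
            "unclassified": int(overall["unclassified"].iloc[0]) if len(overall) else 0,
        }

    if len(regions_by_condition) >= 2:
        mat = hotspots.overlap_matrix(regions_by_condition)
        mat.to_csv(outdir / "overlap_matrix.tsv", sep="\t")
        summary["stages"]["overlap_matrix"] = {
            a: {b: float(mat.loc[a, b]) for b in mat.columns} for a in mat.index
        }

    summary["manifest"] = sorted(
        p.name for p in outdir.iterdir() if p.is_file() and p.name != "summary.json"
    )
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary
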