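"""Plain-text interchange: chrom.sizes, BED, bedGraph, TSV tables.

All coordinates are 0-based half-open (BED convention) on disk and in
memory.
"""

from __future__ import annotations

import pandas as pd


def read_chrom_sizes(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"], df["size"].astype(int)))


def write_chrom_sizes(chrom_sizes: dict[str, int], path) -> None:
    pd.DataFrame(sorted(chrom_sizes.items())).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_genes_bed(path) -> pd.DataFrame:
    """BED6: name = gene id, strand in column 6; score ignored."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["Chromosome", "Start", "End", "gene_id", "score", "Strand"],
    )
    return df.drop(columns=["score"])


def write_genes_bed(genes: pd.DataFrame, path) -> None:
    out = genes[["Chromosome", "Start", "End", "gene_id"]].copy()
    out["score"] = 0
    out["Strand"] = genes["Strand"].values
    out.to_csv(path, sep="\t", header=False, index=False)


def read_errs_bed(path) -> pd.DataFrame:
    """BED with name = ERR id and score = origin position."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["Chromosome", "Start", "End", "err_id", "origin"],
    )
    df["origin"] = df["origin"].astype(int)
    return df


def write_errs_bed(errs: pd.DataFrame, path) -> None:
    errs[["Chromosome", "Start", "End", "err_id", "origin"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_breaks(path) -> pd.DataFrame:
    """Break-read table: chrom, pos, strand, mapq, umi[, barcode,
    sample_id, ...] with a header line."""
    return pd.read_csv(path, sep="\t")


def write_breaks(reads: pd.DataFrame, path) -> None:
    reads.to_csv(path, sep="\t", index=False)


def write_events_bed(events: pd.DataFrame, path) -> None:
    """Unique DSB locations as BED: chrom, pos, pos+1, umi_count."""
    out = pd.DataFrame(
        {
            "chrom": events["chrom"],
            "start": events["pos"],
            "end": events["pos"] + 1,
            "umi_count": events["umi_count"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_events_bed(path, sample_id: str | None = None) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "pos", "end", "umi_count"]
    )
    df = df.drop(columns=["end"])
    if sample_id is not None:
        df["sample_id"] = sample_id
    return df


def write_regions_bed(regions: pd.DataFrame, path) -> None:
    cols = [c for c in ["Chromosome", "Start", "End", "n_bins", "total_coverage"]
            if c in regions.columns]
    regions[cols].to_csv(path, sep="\t", header=False, index=False)


def read_regions_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None)
    names = ["Chromosome", "Start", "End", "n_bins", "total_coverage"]
    df.columns = names[: df.shape[1]]
    return df
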