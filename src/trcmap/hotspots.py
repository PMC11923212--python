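"""BLISS+ hotspot calling: library down-sampling, fixed-bin coverage,
thresholding, gap merging, replicate union and overlap matrices.

The genome is tiled with fixed-width bins (2 kb by default) anchored at
coordinate 0 of each chromosome; per-bin coverage is the number of
unique BLISS UMIs falling in the bin. Bins with coverage strictly above
the threshold (22 by default) are called positive, and positive bins
separated by at most ``max_gap`` bp (2 kb by default) are merged into
BLISS+ regions. Replicate region sets are combined by interval union
per condition.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pyranges as pr

REGION_COLUMNS = ["Chromosome", "Start", "End", "n_bins", "total_coverage"]


def downsample(
    events_by_sample: dict[str, pd.DataFrame], seed: int
) -> dict[str, pd.DataFrame]:
    """Down-sample every sample to the smallest total UMI count.

    The sampling unit is the individual UMI: an event with
    ``umi_count = k`` contributes k units, drawn uniformly without
    replacement. Deterministic for a given seed regardless of dict
    order (per-sample streams are derived in sorted sample order).
    """
    if not events_by_sample:
        raise ValueError("need at least one sample")
    totals = {s: int(df["umi_count"].sum()) for s, df in events_by_sample.items()}
    target = min(totals.values())
    names = sorted(events_by_sample)
    streams = dict(
        zip(names, np.random.SeedSequence(seed).spawn(len(names)))
    )
    out = {}
    for s in names:
        df = events_by_sample[s]
        if totals[s] == target:
            out[s] = df.reset_index(drop=True)
            continue
        rng = np.random.default_rng(streams[s])
        units = np.repeat(np.arange(len(df)), df["umi_count"].to_numpy())
        keep = rng.choice(len(units), size=target, replace=False)
        new_counts = np.bincount(units[keep], minlength=len(df))
        kept = df.loc[new_counts > 0].copy()
        kept["umi_count"] = new_counts[new_counts > 0]
        out[s] = kept.reset_index(drop=True)
    return out


def bin_coverage(
    events: pd.DataFrame, chrom_sizes: dict[str, int], bin_size: int = 2000
) -> pd.DataFrame:
    """Tile each chromosome with fixed bins and count UMIs per bin.

    An event at position p lands in bin floor(p / bin_size); the last
    bin may be shorter than ``bin_size``. Events outside chromosome
    bounds raise with the offending record named.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    rows = []
    by_chrom = dict(tuple(events.groupby("chrom"))) if len(events) else {}
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        n_bins = -(-size // bin_size)
        cov = np.zeros(n_bins, dtype=int)
        if chrom in by_chrom:
            grp = by_chrom.pop(chrom)
            pos = grp["pos"].to_numpy()
            bad = (pos < 0) | (pos >= size)
            if bad.any():
                rec = grp[bad].iloc[0]
                raise ValueError(
                    f"event at {rec['chrom']}:{rec['pos']} is outside the "
                    f"chromosome (size {size})"
                )
            cov = np.bincount(
                pos // bin_size, weights=grp["umi_count"].to_numpy(), minlength=n_bins
            ).astype(int)
        for i in range(n_bins):
            rows.append(
                (chrom, i, i * bin_size, min((i + 1) * bin_size, size), cov[i])
            )
    if by_chrom:
        chrom, grp = next(iter(by_chrom.items()))
        rec = grp.iloc[0]
        raise ValueError(
            f"event at {rec['chrom']}:{rec['pos']} is on a chromosome absent "
            "from the sizes table"
        )
    return pd.DataFrame(
        rows, columns=["Chromosome", "bin_index", "Start", "End", "coverage"]
    )


def call_positive_bins(
    bins: pd.DataFrame, threshold: int = 22, strict: bool = True
) -> pd.DataFrame:
    """Bins with coverage above the threshold (strictly, by default)."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    mask = (
        bins["coverage"] > threshold if strict else bins["coverage"] >= threshold
    )
    return bins[mask].reset_index(drop=True)


def merge_bins(pos_bins: pd.DataFrame, max_gap: int = 2000) -> pd.DataFrame:
    """Collapse positive bins into regions, bridging gaps up to max_gap bp.

    Two consecutive positive bins on one chromosome join the same region
    iff next.Start - prev.End <= max_gap. Regions span their member
    bins and carry ``n_bins`` and ``total_coverage``.
    """
    rows = []
    for chrom, grp in pos_bins.groupby("Chromosome", sort=True):
        grp = grp.sort_values("Start")
        cur = None
        for b in grp.itertuples():
            if cur is not None and b.Start - cur[1] <= max_gap:
                cur = (cur[0], b.End, cur[2] + 1, cur[3] + b.coverage)
            else:
                if cur is not None:
                    rows.append((chrom, *cur))
                cur = (b.Start, b.End, 1, b.coverage)
        if cur is not None:
            rows.append((chrom, *cur))
    return pd.DataFrame(rows, columns=REGION_COLUMNS)


def union_regions(replicate_region_sets: list[pd.DataFrame]) -> pd.DataFrame:
    """Interval union across replicates: overlapping or book-ended
    intervals coalesce; output is sorted and disjoint."""
    if not replicate_region_sets:
        raise ValueError("need at least one region set")
    frames = [df[["Chromosome", "Start", "End"]] for df in replicate_region_sets]
    cat = pd.concat(frames, ignore_index=True)
    if cat.empty:
        return pd.DataFrame(columns=["Chromosome", "Start", "End"])
    merged = pr.PyRanges(cat).merge(slack=0).df
    return (
        merged.sort_values(["Chromosome", "Start"])
        .reset_index(drop=True)[["Chromosome", "Start", "End"]]
    )


def overlap_matrix(region_sets: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Pairwise overlap fractions between condition region sets.

    Entry (A, B) is the fraction of A's regions that overlap at least
    one B region by >= 1 bp. The diagonal is 1 for non-empty sets; an
    empty set yields a zero row with a warning.
    """
    if len(region_sets) < 2:
        raise ValueError("need at least two conditions")
    names = list(region_sets)
    mat = pd.DataFrame(0.0, index=names, columns=names)
    grs = {}
    for name, df in region_sets.items():
        if df.empty:
            warnings.warn(f"condition {name!r} has no regions; its row is 0")
            grs[name] = None
        else:
            grs[name] = pr.PyRanges(df[["Chromosome", "Start", "End"]])
    for a in names:
        if grs[a] is None:
            continue
        n_a = len(region_sets[a])
        for b in names:
            if grs[b] is None:
                mat.loc[a, b] = 0.0
            else:
                mat.loc[a, b] = len(grs[a].overlap(grs[b])) / n_a
    return mat
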