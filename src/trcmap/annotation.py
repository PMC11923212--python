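"""Genomic annotation of BLISS+ regions.

Regions are labelled promoter / intragenic / extragenic against a gene
model (promoter wins over intragenic), flagged for overlap with
early-replicated regions (ERRs) and with S-phase-transcribed genes, and
assigned to clusters defined by those two flags. Metagene profiles
average a signal track over center-anchored windows per cluster.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pyranges as pr

from trcmap.tracks import SignalTrack

# (overlaps_transcript, overlaps_err) -> cluster label; None = unclustered.
# The split of the transcript&ERR class into two sub-clusters (labels 1
# and 4) is a reporting choice with no fixed rule; pass ``split_both`` to
# assign_cluster to move a subset of that class to label 4.
DEFAULT_CLUSTER_MAP = {
    (True, True): 1,
    (False, True): 2,
    (True, False): 3,
    (False, False): None,
}


def promoter_windows(
    genes: pd.DataFrame, upstream: int = 2000, downstream: int = 500
) -> pd.DataFrame:
    """Strand-aware TSS windows: [TSS-upstream, TSS+downstream) on '+',
    mirrored on '-'. Clipped at 0."""
    if upstream < 0 or downstream < 0:
        raise ValueError("promoter window sizes must be >= 0")
    plus = genes["Strand"] == "+"
    tss = np.where(plus, genes["Start"], genes["End"])
    start = np.where(plus, tss - upstream, tss - downstream)
    end = np.where(plus, tss + downstream, tss + upstream)
    return pd.DataFrame(
        {
            "Chromosome": genes["Chromosome"],
            "Start": np.maximum(start, 0),
            "End": end,
            "gene_id": genes["gene_id"],
        }
    )


def _overlap_mask(regions: pd.DataFrame, features: pd.DataFrame) -> np.ndarray:
    """Boolean per region: overlaps >= 1 bp with any feature interval."""
    if regions.empty or features.empty:
        return np.zeros(len(regions), dtype=bool)
    r = regions[["Chromosome", "Start", "End"]].copy()
    r["__idx"] = np.arange(len(r))
    hit = pr.PyRanges(r).overlap(pr.PyRanges(features[["Chromosome", "Start", "End"]]))
    mask = np.zeros(len(regions), dtype=bool)
    if len(hit) > 0:
        mask[hit.df["__idx"].to_numpy()] = True
    return mask


def annotate_category(
    regions: pd.DataFrame,
    genes: pd.DataFrame,
    promoter_upstream: int = 2000,
    promoter_downstream: int = 500,
) -> pd.Series:
    """Label each region promoter / intragenic / extragenic.

    A region overlapping any strand-aware TSS window is a promoter
    region; otherwise a region overlapping a gene body is intragenic;
    anything else is extragenic (precedence promoter > intragenic).
    """
    if genes.empty:
        return pd.Series(["extragenic"] * len(regions), index=regions.index)
    prom = _overlap_mask(
        regions, promoter_windows(genes, promoter_upstream, promoter_downstream)
    )
    body = _overlap_mask(regions, genes)
    cat = np.where(prom, "promoter", np.where(body, "intragenic", "extragenic"))
    return pd.Series(cat, index=regions.index)


def flag_overlaps(
    regions: pd.DataFrame,
    errs: pd.DataFrame,
    transcripts: pd.DataFrame,
    proximal_distance: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Per-region ERR / transcript overlap flags and summary fractions.

    Overlap means >= 1 bp shared; ``proximal_distance`` > 0 additionally
    counts regions within that many bp of a feature (the features are
    padded by the slack before intersection).
    """

    def pad(df):
        if proximal_distance <= 0 or df.empty:
            return df
        out = df.copy()
        out["Start"] = np.maximum(out["Start"] - proximal_distance, 0)
        out["End"] = out["End"] + proximal_distance
        return out

    flags = pd.DataFrame(index=regions.index)
    flags["overlaps_err"] = _overlap_mask(regions, pad(errs))
    flags["overlaps_transcript"] = _overlap_mask(regions, pad(transcripts))
    n = len(regions)
    summary = {
        "err_fraction": float(flags["overlaps_err"].mean()) if n else 0.0,
        "transcript_fraction": (
            float(flags["overlaps_transcript"].mean()) if n else 0.0
        ),
    }
    return flags, summary


def assign_cluster(
    flags: pd.DataFrame,
    cluster_map: dict | None = None,
    split_both: pd.Series | None = None,
) -> pd.Series:
    """Map (overlaps_transcript, overlaps_err) flag pairs to cluster labels.

    ``cluster_map`` overrides :data:`DEFAULT_CLUSTER_MAP`. ``split_both``
    is an optional boolean mask over the regions; where True and the
    region is in the transcript&ERR class, the label becomes 4. Regions
    whose mapping is None are left unclustered (pd.NA).
    """
    cmap = DEFAULT_CLUSTER_MAP if cluster_map is None else cluster_map
    keys = list(
        zip(flags["overlaps_transcript"].astype(bool), flags["overlaps_err"].astype(bool))
    )
    labels = pd.Series([cmap[k] for k in keys], index=flags.index, dtype="object")
    if split_both is not None:
        both = flags["overlaps_transcript"] & flags["overlaps_err"]
        labels[both & split_both.astype(bool)] = 4
    return labels.astype("Int64") if labels.notna().any() else labels


def metagene_profile(
    track: SignalTrack,
    regions: pd.DataFrame,
    flank: int,
    n_points: int,
    clusters: pd.Series | None = None,
) -> pd.DataFrame:
    """Mean center-anchored signal profile, one column per cluster.

    Each region contributes the track over [center-flank, center+flank)
    resampled to ``n_points``; positions beyond chromosome ends count as
    0. With ``clusters`` None, a single column "all" is returned.
    Clusters with no members are omitted.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    if clusters is None:
        clusters = pd.Series(["all"] * len(regions), index=regions.index)
    profiles: dict = {}
    counts: dict = {}
    for (idx, reg), label in zip(regions.iterrows(), clusters):
        if pd.isna(label):
            continue
        center = (int(reg["Start"]) + int(reg["End"])) // 2
        w = track.window(reg["Chromosome"], center - flank, center + flank, n_points)
        if label not in profiles:
            profiles[label] = np.zeros(n_points)
            counts[label] = 0
        profiles[label] += w
        counts[label] += 1
    return pd.DataFrame(
        {label: profiles[label] / counts[label] for label in sorted(profiles, key=str)}
    )
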