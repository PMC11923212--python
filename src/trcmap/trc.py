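"""Transcription-replication conflict (TRC) classification.

Replication forks move outward from an origin, so the fork direction at
a position inside an early-replicated region (ERR) is "right" beyond the
origin and "left" before it. The origin is read from the EdU-HU signal
as the smoothed maximum inside the ERR. A DSB region associated with a
nearby ERR and a nearby expressed gene is head-on when the fork and
transcription move toward each other — fork right into a '-' gene or
fork left into a '+' gene — and co-directional when they agree.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from trcmap.tracks import SignalTrack


class DegenerateOrigin(ValueError):
    """Position coincides with the replication origin."""


class NoSignal(ValueError):
    """ERR contains no EdU-HU signal to locate an origin."""


def locate_origin(
    edu_hu: SignalTrack,
    err,
    smooth_bins: int = 5,
    fallback_midpoint: bool = False,
) -> int:
    """Origin position = argmax of the smoothed EdU-HU signal in the ERR.

    The signal over the ERR's track windows is smoothed with a centered
    moving average of ``smooth_bins`` windows; ties at the maximum
    resolve to the midpoint of the tied plateau. An all-zero ERR raises
    :class:`NoSignal` unless ``fallback_midpoint`` is set, in which case
    the ERR midpoint is returned.
    """
    chrom, start, end = err["Chromosome"], int(err["Start"]), int(err["End"])
    step = edu_hu.step
    first, last = start // step, (end - 1) // step
    v = edu_hu.values.get(chrom, np.zeros(0))
    seg = v[max(first, 0) : last + 1]
    if seg.size == 0 or not np.any(seg > 0):
        if fallback_midpoint:
            return (start + end) // 2
        raise NoSignal(f"no EdU-HU signal inside ERR {chrom}:{start}-{end}")
    if smooth_bins > 1:
        kernel = np.ones(smooth_bins) / smooth_bins
        sm = np.convolve(seg, kernel, mode="same")
    else:
        sm = seg
    tied = np.flatnonzero(sm == sm.max())
    mid_idx = (tied[0] + tied[-1]) / 2.0
    return int((max(first, 0) + mid_idx) * step + step / 2)


def fork_direction_at(position: int, origin_pos: int) -> str:
    """"right" past the origin, "left" before it; the origin itself is
    degenerate and raises."""
    if position == origin_pos:
        raise DegenerateOrigin(f"position {position} equals the origin")
    return "right" if position > origin_pos else "left"


def trc_class(fork_direction: str, gene_strand: str) -> str:
    """Head-on when fork and transcription oppose, co-directional when
    they agree: (right, +) / (left, -) are co-directional."""
    if fork_direction not in ("left", "right"):
        raise ValueError(f"bad fork direction {fork_direction!r}")
    if gene_strand not in ("+", "-"):
        raise ValueError(f"bad strand {gene_strand!r}")
    same = (fork_direction == "right") == (gene_strand == "+")
    return "co_directional" if same else "head_on"


def _nearest(midpoint: int, chrom: str, features: pd.DataFrame) -> tuple[int, float]:
    """Index and distance of the nearest feature interval on chrom
    (distance 0 when the midpoint falls inside)."""
    best, best_d = -1, np.inf
    for idx, f in features.iterrows():
        if f["Chromosome"] != chrom:
            continue
        if f["Start"] <= midpoint < f["End"]:
            d = 0.0
        else:
            d = min(abs(midpoint - f["Start"]), abs(midpoint - (f["End"] - 1)))
        if d < best_d:
            best, best_d = idx, d
    return best, best_d


def classify_trc(
    regions: pd.DataFrame,
    errs: pd.DataFrame,
    edu_hu: SignalTrack,
    genes: pd.DataFrame,
    assoc_window: int = 10_000,
    smooth_bins: int = 5,
    fallback_midpoint: bool = False,
) -> pd.DataFrame:
    """Classify each region as head_on / co_directional / unclassified.

    A region is associated with the nearest ERR and the nearest
    expressed gene within ``assoc_window`` bp of its midpoint; failing
    either association, or spanning the inferred origin, leaves it
    unclassified. Fork direction is evaluated at the region midpoint.
    """
    expressed = genes[genes["expressed"]] if "expressed" in genes.columns else genes
    origin_cache: dict = {}
    rows = []
    for _, reg in regions.iterrows():
        mid = (int(reg["Start"]) + int(reg["End"])) // 2
        e_idx, e_d = _nearest(mid, reg["Chromosome"], errs)
        g_idx, g_d = _nearest(mid, reg["Chromosome"], expressed)
        rec = {
            "Chromosome": reg["Chromosome"],
            "Start": int(reg["Start"]),
            "End": int(reg["End"]),
            "err_id": None,
            "gene_id": None,
            "gene_strand": None,
            "fork_direction": None,
            "trc_class": "unclassified",
        }
        if e_idx >= 0 and e_d <= assoc_window and g_idx >= 0 and g_d <= assoc_window:
            err = errs.loc[e_idx]
            gene = expressed.loc[g_idx]
            rec["err_id"] = err.get("err_id", str(e_idx))
            rec["gene_id"] = gene["gene_id"]
            rec["gene_strand"] = gene["Strand"]
            if e_idx not in origin_cache:
                origin_cache[e_idx] = locate_origin(
                    edu_hu, err, smooth_bins, fallback_midpoint
                )
            origin = origin_cache[e_idx]
            spans_origin = int(reg["Start"]) <= origin < int(reg["End"])
            if not spans_origin and mid != origin:
                fork = fork_direction_at(mid, origin)
                rec["fork_direction"] = fork
                rec["trc_class"] = trc_class(fork, gene["Strand"])
        rows.append(rec)
    return pd.DataFrame(rows)


def summarize_trc(
    calls: pd.DataFrame, clusters: pd.Series | None = None
) -> pd.DataFrame:
    """Per-cluster counts and fractions of head-on vs co-directional.

    Fractions are over classified calls only and sum to 1 within each
    non-empty cluster; empty clusters report n=0 with NaN fractions.
    """
    if clusters is None:
        clusters = pd.Series(["all"] * len(calls), index=calls.index)
    rows = []
    for label in sorted(clusters.dropna().unique(), key=str):
        sub = calls[clusters == label]
        ho = int((sub["trc_class"] == "head_on").sum())
        cd = int((sub["trc_class"] == "co_directional").sum())
        un = int((sub["trc_class"] == "unclassified").sum())
        n_class = ho + cd
        rows.append(
            {
                "cluster": label,
                "n": len(sub),
                "head_on": ho,
                "co_directional": cd,
                "unclassified": un,
                "head_on_fraction": ho / n_class if n_class else np.nan,
                "co_directional_fraction": cd / n_class if n_class else np.nan,
            }
        )
    return pd.DataFrame(rows)
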