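"""Spike-in normalization of EU-seq / DRIP-seq count tables.

Size factors are computed by median-of-ratios restricted to spike-in
rows: for each sample the factor is the median over spike genes of the
count divided by that gene's geometric mean across samples (rows with
any zero are excluded from the reference). Counts divided by their
sample's factor give normalized values; a gene is called expressed when
its baseMean — the mean normalized count across samples — strictly
exceeds the threshold (32 by default). Differential labels (padj-based)
and the null control-gene sample operate on an externally computed
differential table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def extend_gene_intervals(
    genes: pd.DataFrame,
    fraction: float = 0.10,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Extend each gene by ``fraction`` of its length at both ends.

    The extension is strand-independent (before the TSS and after the
    TES alike) and clipped to chromosome bounds when sizes are given.
    The per-gene extension is round(fraction x length) bp.
    """
    if fraction < 0:
        raise ValueError("fraction must be >= 0")
    out = genes.copy()
    ext = np.rint(fraction * (out["End"] - out["Start"])).astype(int)
    out["Start"] = np.maximum(out["Start"] - ext, 0)
    out["End"] = out["End"] + ext
    if chrom_sizes is not None:
        limits = out["Chromosome"].map(chrom_sizes)
        out["End"] = np.minimum(out["End"], limits)
    return out


def spikein_size_factors(
    counts: pd.DataFrame, spike_prefix: str = "spike_", spike_ids=None
) -> pd.Series:
    """Per-sample size factors from spike-in rows (median-of-ratios).

    Spike rows are selected by id prefix or an explicit ``spike_ids``
    list. Rows containing any zero are excluded from the geometric-mean
    reference; if no usable spike row remains, raises.
    """
    if spike_ids is not None:
        spikes = counts.loc[counts.index.isin(set(spike_ids))]
    else:
        spikes = counts.loc[counts.index.str.startswith(spike_prefix)]
    if spikes.empty:
        raise ValueError("no spike-in rows found")
    usable = spikes[(spikes > 0).all(axis=1)]
    if usable.empty:
        raise ValueError("every spike-in row contains a zero count")
    logs = np.log(usable.to_numpy(dtype=float))
    log_ratios = logs - logs.mean(axis=1)[:, None]
    # median on the log scale (the DESeq2 convention), then exponentiate
    factors = np.exp(np.median(log_ratios, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_and_filter(
    counts: pd.DataFrame, factors: pd.Series, base_mean_min: float = 32.0
) -> tuple[pd.DataFrame, pd.Series]:
    """Divide counts by size factors and flag expressed genes.

    baseMean is the mean normalized count across samples; expressed
    means baseMean strictly greater than ``base_mean_min``.
    """
    if (factors <= 0).any():
        raise ValueError("size factors must be positive")
    normalized = counts / factors
    base_mean = normalized.mean(axis=1)
    expressed = base_mean > base_mean_min
    expressed.name = "expressed"
    return normalized, expressed


def label_deg(
    de_table: pd.DataFrame,
    padj_max: float = 0.05,
    lfc_col: str = "log2FoldChange",
    padj_col: str = "padj",
) -> pd.Series:
    """Label rows of a differential table as up / down / ns.

    A pure filter on an externally computed table: padj < ``padj_max``
    makes a gene differential; the direction is the sign of the fold
    change. NaN padj is non-significant.
    """
    padj = de_table[padj_col]
    sig = padj.notna() & (padj < padj_max)
    up = sig & (de_table[lfc_col] > 0)
    down = sig & (de_table[lfc_col] < 0)
    out = pd.Series("ns", index=de_table.index, name="deg")
    out[up] = "up"
    out[down] = "down"
    return out


def select_control_genes(
    de_table: pd.DataFrame,
    n: int = 500,
    padj_floor: float = 0.5,
    seed: int = 0,
    padj_col: str = "padj",
) -> list:
    """Uniform sample of ``n`` unchanged genes (padj > ``padj_floor``).

    Deterministic under the seed; raises if fewer than ``n`` genes are
    eligible.
    """
    padj = de_table[padj_col]
    eligible = de_table.index[padj.notna() & (padj > padj_floor)]
    if len(eligible) < n:
        raise ValueError(
            f"only {len(eligible)} genes have padj > {padj_floor}, need {n}"
        )
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(eligible), size=n, replace=False)
    return list(eligible[np.sort(pick)])
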