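"""sBLISS break-read processing: prefix parsing, quality filtering and
UMI-aware removal of PCR duplicates.

Each sBLISS read starts with an 8 nt unique molecular identifier (UMI)
followed by an 8 nt sample barcode. After alignment, reads below the
mapping-quality cutoff are dropped and PCR duplicates are collapsed:
reads on the same chromosome at most ``pos_window`` bp apart whose UMIs
differ by at most ``max_umi_mismatch`` substitutions are considered
copies of one molecule. Duplicate grouping is transitive
(single-linkage), so chains of adjacent near-identical reads collapse
into one event. The result is the list of unique DSB locations with the
number of unique UMIs observed at each.
"""

from __future__ import annotations

import pandas as pd


class ShortRead(ValueError):
    """Read too short to contain the UMI + barcode prefix."""


class AmbiguousBarcode(ValueError):
    """Two whitelist barcodes are equidistant within tolerance."""


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def parse_prefix(
    read_sequence: str,
    barcode_whitelist,
    max_bc_mismatch: int = 1,
    umi_length: int = 8,
    barcode_length: int = 8,
):
    """Split off the UMI + sample-barcode prefix of a raw read.

    ``barcode_whitelist`` is either a sequence of barcodes (the barcode
    itself then serves as sample id) or a mapping barcode -> sample id.
    Returns ``(umi, sample_id, clipped_sequence)`` or ``None`` if the
    observed barcode is farther than ``max_bc_mismatch`` from every
    whitelist entry. Raises :class:`ShortRead` for reads shorter than
    the prefix and :class:`AmbiguousBarcode` when two whitelist entries
    are tied within tolerance.
    """
    prefix_len = umi_length + barcode_length
    if len(read_sequence) < prefix_len:
        raise ShortRead(
            f"read of length {len(read_sequence)} is shorter than the "
            f"{prefix_len} nt prefix"
        )
    if isinstance(barcode_whitelist, dict):
        mapping = dict(barcode_whitelist)
    else:
        mapping = {bc: bc for bc in barcode_whitelist}
    umi = read_sequence[:umi_length]
    observed = read_sequence[umi_length:prefix_len]

    best = sorted((hamming(observed, bc), bc) for bc in mapping)
    if not best or best[0][0] > max_bc_mismatch:
        return None
    if len(best) > 1 and best[1][0] <= max_bc_mismatch and best[1][0] == best[0][0]:
        raise AmbiguousBarcode(
            f"barcode {observed} matches {best[0][1]} and {best[1][1]} "
            f"at distance {best[0][0]}"
        )
    return umi, mapping[best[0][1]], read_sequence[prefix_len:]


def filter_mapq(records: pd.DataFrame, min_mapq: int = 30) -> pd.DataFrame:
    """Keep records with ``mapq >= min_mapq``; order is preserved."""
    return records[records["mapq"] >= min_mapq].reset_index(drop=True)


class _DisjointSet:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def deduplicate(
    records: pd.DataFrame,
    pos_window: int = 10,
    max_umi_mismatch: int = 1,
    strand_aware: bool = False,
) -> pd.DataFrame:
    """Collapse PCR duplicates into unique DSB locations with UMI counts.

    Single-linkage clustering per chromosome (and per sample, if a
    ``sample_id`` column is present): two reads are linked iff their
    positions differ by at most ``pos_window`` bp and their UMIs by at
    most ``max_umi_mismatch`` substitutions. Each cluster is reported at
    its representative position — the smallest position in the cluster —
    and the output has one row per (chrom, position) with ``umi_count``
    equal to the number of clusters represented there.

    The sweep over position-sorted reads only compares pairs within
    ``pos_window``, which is exactly the edge set of the single-linkage
    graph, so the result is independent of input order.
    """
    cols = ["chrom", "pos", "umi_count"]
    group_cols = ["chrom"]
    if "sample_id" in records.columns:
        group_cols = ["sample_id", "chrom"]
        cols = ["chrom", "pos", "umi_count", "sample_id"]
    if strand_aware:
        group_cols.append("strand")

    out_rows = []
    for key, grp in records.groupby(group_cols, sort=True):
        grp = grp.sort_values(["pos", "umi"], kind="mergesort").reset_index(drop=True)
        pos = grp["pos"].to_numpy()
        umi = grp["umi"].to_numpy()
        n = len(grp)
        ds = _DisjointSet(n)
        lo = 0
        for i in range(n):
            while pos[i] - pos[lo] > pos_window:
                lo += 1
            for j in range(lo, i):
                if _umi_close(umi[i], umi[j], max_umi_mismatch):
                    ds.union(i, j)
        reps: dict[int, int] = {}
        for i in range(n):
            r = ds.find(i)
            # reads are sorted by (pos, umi); the first member is the
            # representative: smallest position, lexicographic UMI tie-break
            if r not in reps:
                reps[r] = i
        counts: dict[int, int] = {}
        for i in reps.values():
            p = int(pos[i])
            counts[p] = counts.get(p, 0) + 1
        key = key if isinstance(key, tuple) else (key,)
        info = dict(zip(group_cols, key))
        for p in sorted(counts):
            row = {"chrom": info["chrom"], "pos": p, "umi_count": counts[p]}
            if "sample_id" in info:
                row["sample_id"] = info["sample_id"]
            out_rows.append(row)
    return pd.DataFrame(out_rows, columns=cols)


def _umi_close(a: str, b: str, max_mismatch: int) -> bool:
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > max_mismatch:
                return False
    return True
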