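import numpy as np
import pandas as pd
import pytest

import trcmap as t


@pytest.fixture(scope="session")
def sim_config():
    return t.SimConfig(seed=11)


@pytest.fixture(scope="session")
def genome(sim_config):
    """Default synthetic genome: chrom sizes, genes, ERRs, ground truth."""
    return t.make_genome_and_annotation(sim_config)


@pytest.fixture(scope="session")
def tracks(genome, sim_config):
    _, genes, errs, _ = genome
    return t.make_signal_tracks(genes, errs, 1000, sim_config)


@pytest.fixture(scope="session")
def bliss_reads(genome, sim_config):
    _, genes, errs, truth = genome
    return t.simulate_bliss_reads(genes, errs, truth, sim_config)


def random_break_table(rng, n, span=300, umi_pool=6, chroms=("chr1", "chr2")):
    """Small random break table designed to provoke UMI/position clashes."""
    umis = ["".join(rng.choice(list("ACGT"), 8)) for _ in range(umi_pool)]
    mutated = []
    for u in umis:
        i = rng.integers(8)
        alt = rng.choice([b for b in "ACGT" if b != u[i]])
        mutated.append(u[:i] + alt + u[i + 1:])
    pool = umis + mutated
    return pd.DataFrame(
        {
            "chrom": rng.choice(chroms, n),
            "pos": rng.integers(0, span, n),
            "strand": rng.choice(["+", "-"], n),
            "mapq": rng.integers(0, 61, n),
            "umi": rng.choice(pool, n),
        }
    )


def dedup_oracle(records, pos_window=10, max_umi_mismatch=1):
    """O(n^2) single-linkage reference: explicit edge set + components.

    Returns {(chrom, representative_pos): n_clusters} like deduplicate.
    """
    df = records.reset_index(drop=True)
    n = len(df)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if df.chrom[i] != df.chrom[j]:
                continue
            if abs(int(df.pos[i]) - int(df.pos[j])) > pos_window:
                continue
            if sum(a != b for a, b in zip(df.umi[i], df.umi[j])) > max_umi_mismatch:
                continue
            parent[find(i)] = find(j)
    comps = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    out = {}
    for members in comps.values():
        rep = min(members, key=lambda i: (int(df.pos[i]), df.umi[i]))
        key = (df.chrom[rep], int(df.pos[rep]))
        out[key] = out.get(key, 0) + 1
    return out


def events_to_dict(events):
    return {
        (r.chrom, int(r.pos)): int(r.umi_count) for r in events.itertuples()
    }


def bitmap_union(region_sets, genome_size=100_000, chroms=("chr1",)):
    """Base-pair bitmap union reference on a toy genome."""
    out = []
    for chrom in chroms:
        bits = np.zeros(genome_size, dtype=bool)
        for df in region_sets:
            for r in df.itertuples():
                if r.Chromosome == chrom:
                    bits[int(r.Start): int(r.End)] = True
        padded = np.concatenate([[False], bits, [False]])
        diff = np.diff(padded.astype(int))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)
        out += [(chrom, int(s), int(e)) for s, e in zip(starts, ends)]
    return out
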