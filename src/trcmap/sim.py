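"""Synthetic genomes, break reads, signal tracks and count matrices.

The generator emulates the statistical structure the downstream analysis
assumes, with exported ground truth so every stage can be checked for
recovery:

* a multi-chromosome genome with non-overlapping stranded genes and
  independently placed early-replicated regions (ERRs), each ERR
  recording a replication origin at its midpoint;
* fork-symmetric EdU-HU signal decaying linearly from each origin to the
  ERR edges, and constant per-gene EU (nascent transcription) signal;
* BLISS break reads: Poisson-uniform background breaks plus planted
  promoter-proximal hotspots inside ERRs, PCR duplicates with bounded
  positional jitter, single-substitution UMI/barcode errors, and a
  two-component MAPQ mixture around the quality filter boundary;
* spike-in count matrices with known per-sample scale factors.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from trcmap.tracks import SignalTrack

BASES = np.array(list("ACGT"))

# independent deterministic RNG streams per generator stage
_STREAM_GENOME = 1
_STREAM_READS = 2
_STREAM_COUNTS = 3


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Rates are probabilities in [0, 1]; lengths are base pairs.
    ``background_break_rate`` is expected unique breaks per bp;
    ``hotspot_rate_multiplier`` scales it inside planted hotspot windows.
    """

    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 50
    gene_length_range: tuple[int, int] = (5_000, 20_000)
    n_errs: int = 8
    err_length_range: tuple[int, int] = (40_000, 80_000)
    background_break_rate: float = 1e-3
    hotspot_rate_multiplier: float = 150.0
    n_hotspots: int = 20
    hotspot_width: int = 2_000
    pcr_duplication_rate: float = 0.3
    umi_error_rate: float = 0.1
    barcode_error_rate: float = 0.05
    pos_jitter_max: int = 10
    umi_length: int = 8
    barcode_length: int = 8
    mapq_fail_rate: float = 0.1
    n_samples: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "pcr_duplication_rate",
            "umi_error_rate",
            "barcode_error_rate",
            "mapq_fail_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("chrom_length", "umi_length", "barcode_length", "hotspot_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_chroms", "n_samples"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("n_genes", "n_errs", "n_hotspots", "pos_jitter_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.hotspot_rate_multiplier < 1:
            raise ValueError("hotspot_rate_multiplier must be >= 1")
        if self.background_break_rate < 0:
            raise ValueError("background_break_rate must be >= 0")
        for name in ("gene_length_range", "err_length_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ValueError(f"{name} must satisfy 0 < lo <= hi")


@dataclass
class TruthTable:
    """Simulator ground truth used by recovery tests.

    ``hotspots`` carries one row per planted hotspot window with its
    planted break rate, associated gene/ERR (if any), the constructed
    fork direction at the window and the implied TRC class.
    """

    hotspots: pd.DataFrame
    origins: dict[str, tuple[str, int]]  # err_id -> (chrom, origin position)
    barcode_by_sample: dict[str, str] = field(default_factory=dict)
    true_scale_factors: dict[str, float] = field(default_factory=dict)

    def fork_direction_at(self, err_id: str, pos: int) -> str:
        """Ground-truth fork direction: forks move outward from the origin."""
        _, origin = self.origins[err_id]
        if pos == origin:
            raise ValueError("position coincides with the origin")
        return "right" if pos > origin else "left"

    def to_json(self, path) -> None:
        obj = {
            "hotspots": self.hotspots.to_dict(orient="records"),
            "origins": {k: list(v) for k, v in self.origins.items()},
            "barcode_by_sample": self.barcode_by_sample,
            "true_scale_factors": self.true_scale_factors,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1, sort_keys=True)


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def _place_nonoverlapping(rng, chroms, chrom_length, lengths, taken, max_tries=200):
    """Place intervals of the given lengths uniformly, rejecting overlaps.

    ``taken`` maps chrom -> list of (start, end) already occupied; it is
    updated in place. Raises if an interval cannot be placed.
    """
    placed = []
    for L in lengths:
        for _ in range(max_tries):
            chrom = chroms[rng.integers(len(chroms))]
            if L > chrom_length:
                continue
            start = int(rng.integers(0, chrom_length - L + 1))
            end = start + L
            if all(end <= s or start >= e for s, e in taken.setdefault(chrom, [])):
                taken[chrom].append((start, end))
                placed.append((chrom, start, end))
                break
        else:
            raise ValueError(
                f"could not place an interval of length {L} without overlap "
                f"after {max_tries} tries; reduce feature count or size"
            )
    return placed


def make_genome_and_annotation(
    config: SimConfig,
) -> tuple[dict[str, int], pd.DataFrame, pd.DataFrame, TruthTable]:
    """Build chromosome sizes, gene and ERR annotation, and ground truth.

    Genes are pairwise disjoint with random strands; ERRs are placed
    independently of genes (they may overlap genes, not each other) and
    record their origin at the interval midpoint. ``n_hotspots`` genes are
    anchored with their TSS inside an ERR, off-origin, so each planted
    hotspot has a well-defined fork direction and hence a ground-truth
    head-on / co-directional class.
    """
    rng = _rng(config, _STREAM_GENOME)
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    chrom_sizes = {c: config.chrom_length for c in chroms}

    err_lengths = rng.integers(
        config.err_length_range[0], config.err_length_range[1] + 1, config.n_errs
    )
    err_taken: dict[str, list] = {}
    err_rows = []
    for i, (chrom, start, end) in enumerate(
        _place_nonoverlapping(rng, chroms, config.chrom_length, err_lengths, err_taken)
    ):
        err_rows.append((chrom, start, end, f"ERR_{i + 1}", (start + end) // 2))
    errs = pd.DataFrame(
        err_rows, columns=["Chromosome", "Start", "End", "err_id", "origin"]
    )

    gene_taken: dict[str, list] = {}
    gene_rows = []
    hotspot_rows = []
    hw = config.hotspot_width
    n_conflict = min(config.n_hotspots, config.n_genes) if len(errs) else 0

    # conflict genes: TSS planted inside an ERR, at least one hotspot
    # half-width away from the origin so fork direction is uniform over
    # the hotspot window
    for i in range(n_conflict):
        for attempt in range(200):
            err = errs.iloc[int(rng.integers(len(errs)))]
            # keep the whole hotspot window clear of the origin by at
            # least half a window, so signal-estimated origins with
            # sub-window error cannot land inside it
            margin = hw
            side = "left" if rng.random() < 0.5 else "right"
            if side == "left":
                lo, hi = err.Start + hw // 2, err.origin - margin
            else:
                lo, hi = err.origin + margin, err.End - hw // 2
            if hi <= lo:
                continue
            tss = int(rng.integers(lo, hi))
            L = int(rng.integers(*_pair_hi(config.gene_length_range)))
            strand = "+" if rng.random() < 0.5 else "-"
            gs, ge = (tss, tss + L) if strand == "+" else (tss - L, tss)
            if gs < 0 or ge > config.chrom_length:
                continue
            if not all(
                ge <= s or gs >= e for s, e in gene_taken.setdefault(err.Chromosome, [])
            ):
                continue
            hs, he = tss - hw // 2, tss - hw // 2 + hw
            prev = [(r[1], r[2]) for r in hotspot_rows if r[0] == err.Chromosome]
            if not all(he <= s or hs >= e for s, e in prev):
                continue
            gene_taken[err.Chromosome].append((gs, ge))
            gid = f"gene_{len(gene_rows) + 1}"
            gene_rows.append((err.Chromosome, gs, ge, strand, gid))
            fork = "right" if tss > err.origin else "left"
            klass = (
                "head_on"
                if (fork == "right") == (strand == "-")
                else "co_directional"
            )
            hotspot_rows.append(
                (
                    err.Chromosome,
                    hs,
                    he,
                    config.background_break_rate * config.hotspot_rate_multiplier,
                    gid,
                    err.err_id,
                    fork,
                    klass,
                )
            )
            break
        else:
            raise ValueError(
                "could not place a conflict gene inside an ERR; "
                "ERRs may be too small for the hotspot width"
            )

    # remaining genes: uniform, disjoint from all genes
    n_rest = config.n_genes - len(gene_rows)
    lengths = rng.integers(
        config.gene_length_range[0], config.gene_length_range[1] + 1, n_rest
    )
    for chrom, start, end in _place_nonoverlapping(
        rng, chroms, config.chrom_length, lengths, gene_taken
    ):
        gid = f"gene_{len(gene_rows) + 1}"
        strand = "+" if rng.random() < 0.5 else "-"
        gene_rows.append((chrom, start, end, strand, gid))

    # hotspots beyond the available genes: background-anchored, class none
    for i in range(config.n_hotspots - n_conflict):
        for attempt in range(200):
            chrom = chroms[int(rng.integers(len(chroms)))]
            hs = int(rng.integers(0, config.chrom_length - hw + 1))
            he = hs + hw
            prev = [(r[1], r[2]) for r in hotspot_rows if r[0] == chrom]
            if all(he <= s or hs >= e for s, e in prev):
                hotspot_rows.append(
                    (
                        chrom,
                        hs,
                        he,
                        config.background_break_rate * config.hotspot_rate_multiplier,
                        None,
                        None,
                        None,
                        "none",
                    )
                )
                break
        else:
            raise ValueError("could not place a background hotspot")

    genes = pd.DataFrame(
        gene_rows, columns=["Chromosome", "Start", "End", "Strand", "gene_id"]
    )
    genes["eu_level"] = (
        rng.lognormal(3.0, 0.5, len(genes)) if len(genes) else np.array([])
    )
    genes["expressed"] = True
    hotspots = pd.DataFrame(
        hotspot_rows,
        columns=[
            "Chromosome",
            "Start",
            "End",
            "planted_rate",
            "gene_id",
            "err_id",
            "fork_direction",
            "trc_class",
        ],
    )
    truth = TruthTable(
        hotspots=hotspots,
        origins={r.err_id: (r.Chromosome, int(r.origin)) for r in errs.itertuples()},
    )
    return chrom_sizes, genes, errs, truth


def _pair_hi(pair):
    return pair[0], pair[1] + 1


def make_signal_tracks(
    genes: pd.DataFrame,
    errs: pd.DataFrame,
    step: int,
    config: SimConfig,
) -> tuple["SignalTrack", "SignalTrack"]:
    """Build the EdU-HU and EU signal tracks.

    EdU-HU is triangular per ERR: maximal (1.0) at the origin, decaying
    linearly to 0 at the ERR edges — the fork-symmetric profile of
    outward replication from a single origin. EU is a constant per-gene
    level over the gene body, apportioned to windows by covered fraction
    so the track integral equals level x gene length.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    chrom_sizes = {f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)}
    edu = SignalTrack.zeros(chrom_sizes, step)
    eu = SignalTrack.zeros(chrom_sizes, step)

    for err in errs.itertuples():
        v = edu.values[err.Chromosome]
        first, last = int(err.Start) // step, (int(err.End) - 1) // step
        centers = (np.arange(first, last + 1) + 0.5) * step
        origin = float(err.origin)
        left = (centers - err.Start) / max(origin - err.Start, 1)
        right = (err.End - centers) / max(err.End - origin, 1)
        tri = np.clip(np.where(centers <= origin, left, right), 0.0, None)
        v[first : last + 1] = np.maximum(v[first : last + 1], tri)

    for g in genes.itertuples():
        v = eu.values[g.Chromosome]
        first, last = int(g.Start) // step, (int(g.End) - 1) // step
        for i in range(first, min(last, len(v) - 1) + 1):
            lo, hi = max(g.Start, i * step), min(g.End, (i + 1) * step)
            v[i] += g.eu_level * (hi - lo) / step
    return edu, eu


def _random_kmers(rng, n: int, k: int) -> np.ndarray:
    return np.array(
        ["".join(BASES[rng.integers(0, 4, k)]) for _ in range(n)], dtype=object
    )


def _substitute_one(rng, s: str) -> str:
    i = int(rng.integers(len(s)))
    alt = [b for b in "ACGT" if b != s[i]]
    return s[:i] + alt[int(rng.integers(3))] + s[i + 1 :]


def _whitelist(rng, n: int, k: int, min_dist: int = 3) -> list[str]:
    """Random barcodes with pairwise Hamming distance >= min_dist."""
    out: list[str] = []
    while len(out) < n:
        cand = "".join(BASES[rng.integers(0, 4, k)])
        if all(sum(a != b for a, b in zip(cand, w)) >= min_dist for w in out):
            out.append(cand)
    return out


def simulate_bliss_reads(
    genes: pd.DataFrame,
    errs: pd.DataFrame,
    truth: TruthTable,
    config: SimConfig,
) -> tuple[pd.DataFrame, TruthTable]:
    """Emit BLISS break reads with PCR duplicates, UMI/barcode errors.

    Unique molecules arise as Poisson(background_break_rate x length)
    uniform per chromosome, plus Poisson(rate x (multiplier - 1) x width)
    extra molecules uniform inside each planted hotspot window, so the
    total rate in a hotspot is multiplier-scaled. Each molecule carries a
    random UMI and a sample barcode; with probability
    ``pcr_duplication_rate`` the molecule is re-emitted once with
    position jitter in [-pos_jitter_max, +pos_jitter_max], at most one
    UMI substitution (probability ``umi_error_rate``) and at most one
    barcode substitution (probability ``barcode_error_rate``). MAPQ is a
    pass/fail mixture: below 30 with probability ``mapq_fail_rate``.

    Returns the read table (one row per read, duplicates flagged with
    the parent ``molecule_id``) and the truth table updated with the
    per-sample barcode whitelist.
    """
    rng = _rng(config, _STREAM_READS)
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    samples = [f"S{i + 1}" for i in range(config.n_samples)]
    whitelist = _whitelist(rng, config.n_samples, config.barcode_length)
    truth.barcode_by_sample = dict(zip(samples, whitelist))

    mol_chrom, mol_pos = [], []
    for chrom in chroms:
        n_bg = rng.poisson(config.background_break_rate * config.chrom_length)
        mol_chrom += [chrom] * int(n_bg)
        mol_pos += list(rng.integers(0, config.chrom_length, int(n_bg)))
    for h in truth.hotspots.itertuples():
        extra_rate = config.background_break_rate * (
            config.hotspot_rate_multiplier - 1.0
        )
        n_extra = rng.poisson(extra_rate * (h.End - h.Start))
        mol_chrom += [h.Chromosome] * int(n_extra)
        mol_pos += list(rng.integers(h.Start, h.End, int(n_extra)))

    n_mol = len(mol_pos)
    sample_idx = rng.integers(0, config.n_samples, n_mol)
    umis = _random_kmers(rng, n_mol, config.umi_length)
    strands = np.where(rng.random(n_mol) < 0.5, "+", "-")

    def draw_mapq(n):
        fail = rng.random(n) < config.mapq_fail_rate
        q = rng.integers(30, 61, n)
        q[fail] = rng.integers(0, 30, int(fail.sum()))
        return q

    rows = []
    for i in range(n_mol):
        sid = samples[sample_idx[i]]
        rows.append(
            (
                mol_chrom[i],
                int(mol_pos[i]),
                strands[i],
                0,
                umis[i],
                whitelist[sample_idx[i]],
                sid,
                i,
                False,
            )
        )
        if rng.random() < config.pcr_duplication_rate:
            jitter = int(
                rng.integers(-config.pos_jitter_max, config.pos_jitter_max + 1)
            )
            dpos = min(max(int(mol_pos[i]) + jitter, 0), config.chrom_length - 1)
            dumi = umis[i]
            if rng.random() < config.umi_error_rate:
                dumi = _substitute_one(rng, dumi)
            dbc = whitelist[sample_idx[i]]
            if rng.random() < config.barcode_error_rate:
                dbc = _substitute_one(rng, dbc)
            rows.append((mol_chrom[i], dpos, strands[i], 0, dumi, dbc, sid, i, True))

    reads = pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "pos",
            "strand",
            "mapq",
            "umi",
            "barcode",
            "sample_id",
            "molecule_id",
            "is_duplicate",
        ],
    )
    reads["mapq"] = draw_mapq(len(reads))
    reads["prefix"] = reads["umi"] + reads["barcode"]
    return reads, truth


def simulate_counts(
    genes: pd.DataFrame,
    true_scale_factors,
    n_spike: int,
    config: SimConfig,
    noise: str = "poisson",
) -> pd.DataFrame:
    """Count matrix over host genes plus ``n_spike`` spike-in rows.

    Spike rows have equal expected counts across samples before scaling;
    every sample's expectations are then multiplied by its true factor.
    ``true_scale_factors`` is a mapping sample -> factor or a sequence
    (samples are then named S1..Sn). ``noise`` is "poisson" or "none"
    (deterministic rounding). Spike row ids carry the ``spike_`` prefix.
    """
    if n_spike < 8:
        raise ValueError("n_spike must be >= 8 for a stable size-factor median")
    if noise not in ("poisson", "none"):
        raise ValueError(f"unknown noise model: {noise!r}")
    if isinstance(true_scale_factors, dict):
        samples = list(true_scale_factors)
        factors = np.array([true_scale_factors[s] for s in samples], dtype=float)
    else:
        factors = np.asarray(true_scale_factors, dtype=float)
        samples = [f"S{i + 1}" for i in range(len(factors))]
    if (factors <= 0).any():
        raise ValueError("scale factors must be positive")

    rng = _rng(config, _STREAM_COUNTS)
    host_ids = list(genes["gene_id"]) if len(genes) else []
    host_mu = np.round(rng.lognormal(4.0, 1.0, len(host_ids))) + 1
    spike_ids = [f"spike_{i + 1}" for i in range(n_spike)]
    spike_mu = np.round(rng.lognormal(4.0, 0.5, n_spike)) + 1

    mu = np.concatenate([host_mu, spike_mu])
    expected = mu[:, None] * factors[None, :]
    if noise == "poisson":
        counts = rng.poisson(expected)
    else:
        counts = np.rint(expected).astype(int)
    return pd.DataFrame(counts, index=host_ids + spike_ids, columns=samples)
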