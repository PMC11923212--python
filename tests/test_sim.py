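"""Synthetic-data generator: determinism, geometry and noise model."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import trcmap as t


class TestGenomeConstruction:
    def test_no_genes_still_produces_errs(self):
        cfg = t.SimConfig(seed=3, n_genes=0, n_hotspots=0)
        _, genes, errs, _ = t.make_genome_and_annotation(cfg)
        assert len(genes) == 0
        assert len(errs) == cfg.n_errs

    def test_same_seed_identical_outputs(self, sim_config, genome):
        chrom_sizes, genes, errs, truth = genome
        cs2, g2, e2, t2 = t.make_genome_and_annotation(
            dataclasses.replace(sim_config)
        )
        assert cs2 == chrom_sizes
        assert g2.to_csv() == genes.to_csv()
        assert e2.to_csv() == errs.to_csv()
        assert t2.hotspots.to_csv() == truth.hotspots.to_csv()

    def test_genes_within_bounds_and_disjoint(self, genome, sim_config):
        chrom_sizes, genes, _, _ = genome
        assert len(genes) == sim_config.n_genes
        for chrom, grp in genes.groupby("Chromosome"):
            assert (grp.Start >= 0).all()
            assert (grp.End <= chrom_sizes[chrom]).all()
            ivals = sorted(zip(grp.Start, grp.End))
            for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
                assert e1 <= s2, "genes overlap"

    def test_hotspots_lie_within_chromosomes(self, genome):
        chrom_sizes, _, _, truth = genome
        for h in truth.hotspots.itertuples():
            assert 0 <= h.Start < h.End <= chrom_sizes[h.Chromosome]

    def test_planted_trc_class_consistent_with_strand_and_fork(self, genome):
        """Head-on iff the constructed fork opposes the gene strand."""
        _, genes, _, truth = genome
        strands = dict(zip(genes.gene_id, genes.Strand))
        planted = truth.hotspots[truth.hotspots.trc_class != "none"]
        assert len(planted) > 0
        for h in planted.itertuples():
            expected = (
                "head_on"
                if (h.fork_direction == "right") == (strands[h.gene_id] == "-")
                else "co_directional"
            )
            assert h.trc_class == expected
            mid = (h.Start + h.End) // 2
            assert truth.fork_direction_at(h.err_id, mid) == h.fork_direction

    def test_unplaceable_config_rejected(self):
        cfg = t.SimConfig(seed=0, n_chroms=1, chrom_length=100_000,
                          n_genes=30, gene_length_range=(20_000, 20_000),
                          n_errs=0, n_hotspots=0)
        with pytest.raises(ValueError, match="could not place"):
            t.make_genome_and_annotation(cfg)

    @pytest.mark.parametrize("bad", [
        dict(pcr_duplication_rate=1.2),
        dict(hotspot_rate_multiplier=0.5),
        dict(chrom_length=0),
        dict(gene_length_range=(0, 10)),
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            t.SimConfig(**bad)


class TestSignalTracks:
    def test_edu_maximal_at_origin(self, genome, tracks, sim_config):
        _, _, errs, _ = genome
        edu, _ = tracks
        for err in errs.itertuples():
            at_origin = edu.value_at(err.Chromosome, err.origin)
            lo = edu.value_at(err.Chromosome, err.Start + 500)
            hi = edu.value_at(err.Chromosome, err.End - 500)
            assert at_origin >= max(lo, hi)
            assert at_origin > 0.9  # apex of the unit triangle

    def test_edu_zero_outside_errs(self, genome, tracks):
        chrom_sizes, _, errs, _ = genome
        edu, _ = tracks
        rng = np.random.default_rng(0)
        for _ in range(200):
            chrom = rng.choice(list(chrom_sizes))
            pos = int(rng.integers(chrom_sizes[chrom]))
            inside = any(
                e.Chromosome == chrom and e.Start - 1000 <= pos < e.End + 1000
                for e in errs.itertuples()
            )
            if not inside:
                assert edu.value_at(chrom, pos) == 0.0

    def test_eu_integral_matches_level_times_length(self, genome, tracks):
        """Direct summation oracle: track integral per gene."""
        _, genes, _, _ = genome
        _, eu = tracks
        step = eu.step
        for g in genes.head(10).itertuples():
            total = 0.0
            first, last = g.Start // step, (g.End - 1) // step
            for i in range(first, last + 1):
                total += eu.values[g.Chromosome][i] * step
            # neighbouring genes may share edge bins; allow one step of slack
            expected = g.eu_level * (g.End - g.Start)
            assert total == pytest.approx(expected, abs=2 * step * g.eu_level)


class TestBlissReads:
    def test_no_duplication_means_unique_reads(self, genome):
        cfg = t.SimConfig(seed=5, pcr_duplication_rate=0.0, umi_error_rate=0.0)
        cs, genes, errs, truth = t.make_genome_and_annotation(cfg)
        reads, _ = t.simulate_bliss_reads(genes, errs, truth, cfg)
        assert not reads.is_duplicate.any()
        assert reads.molecule_id.nunique() == len(reads)

    def test_duplicates_stay_close_to_parent(self, bliss_reads, sim_config):
        reads, _ = bliss_reads
        parents = reads[~reads.is_duplicate].set_index("molecule_id")
        dups = reads[reads.is_duplicate]
        assert len(dups) > 0
        for d in dups.itertuples():
            p = parents.loc[d.molecule_id]
            assert abs(int(d.pos) - int(p.pos)) <= sim_config.pos_jitter_max
            assert sum(a != b for a, b in zip(d.umi, p.umi)) <= 1
            assert sum(a != b for a, b in zip(d.barcode, p.barcode)) <= 1

    def test_molecule_conservation(self, bliss_reads):
        """Duplicates never create molecule ids absent from the originals."""
        reads, _ = bliss_reads
        parents = set(reads.loc[~reads.is_duplicate, "molecule_id"])
        assert set(reads.molecule_id) == parents

    def test_mapq_fail_fraction_near_configured(self, bliss_reads, sim_config):
        reads, _ = bliss_reads
        frac = (reads.mapq < 30).mean()
        n = len(reads)
        sigma = (sim_config.mapq_fail_rate * (1 - sim_config.mapq_fail_rate) / n) ** 0.5
        assert abs(frac - sim_config.mapq_fail_rate) < 4 * sigma

    def test_unit_multiplier_hotspots_match_background(self):
        """Rate-ratio CI over seeds contains 1 when no enrichment is planted."""
        in_hot, hot_len, n_tot, tot_len = 0, 0, 0, 0
        for seed in range(20):
            cfg = t.SimConfig(seed=seed, hotspot_rate_multiplier=1.0,
                              pcr_duplication_rate=0.0, n_genes=20, n_hotspots=10)
            cs, genes, errs, truth = t.make_genome_and_annotation(cfg)
            reads, _ = t.simulate_bliss_reads(genes, errs, truth, cfg)
            hs = truth.hotspots
            for chrom, grp in reads.groupby("chrom"):
                sub = hs[hs.Chromosome == chrom]
                pos = grp.pos.to_numpy()
                for h in sub.itertuples():
                    in_hot += int(((pos >= h.Start) & (pos < h.End)).sum())
            hot_len += int((hs.End - hs.Start).sum())
            n_tot += len(reads)
            tot_len += sum(cs.values())
        rate_hot = in_hot / hot_len
        rate_all = n_tot / tot_len
        se = np.sqrt(in_hot) / hot_len
        assert abs(rate_hot - rate_all) < 3 * se + 1e-12


class TestCounts:
    def test_equal_factors_give_equal_spike_expectations(self, genome, sim_config):
        _, genes, _, _ = genome
        counts = t.simulate_counts(genes, [1.0, 1.0], 64, sim_config, noise="none")
        spikes = counts.loc[counts.index.str.startswith("spike_")]
        assert (spikes.iloc[:, 0] == spikes.iloc[:, 1]).all()

    def test_noise_free_doubling_is_exact(self, genome, sim_config):
        _, genes, _, _ = genome
        counts = t.simulate_counts(genes, [1.0, 2.0], 64, sim_config, noise="none")
        assert (counts.iloc[:, 1] == 2 * counts.iloc[:, 0]).all()

    def test_counts_nonnegative_and_spike_rows_flagged(self, genome, sim_config):
        _, genes, _, _ = genome
        counts = t.simulate_counts(genes, {"a": 0.5, "b": 4.0}, 32, sim_config)
        assert (counts.to_numpy() >= 0).all()
        assert counts.index.str.startswith("spike_").sum() == 32

    def test_rejects_too_few_spikes(self, genome, sim_config):
        _, genes, _, _ = genome
        with pytest.raises(ValueError, match="n_spike"):
            t.simulate_counts(genes, [1.0], 4, sim_config)
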