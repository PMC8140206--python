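"""The synthetic-data generators: SFS draws, K80 triplets, toy genomes."""

import numpy as np
import pytest

from wgdreg import io as wio
from wgdreg.dfe import DFEModel, expected_sfs_selected
from wgdreg.simulate import (
    SimConfig,
    ToyGenomeConfig,
    generate_toy_genome,
    simulate_sfs,
    simulate_triplet_alignment,
    simulate_variants,
)


class TestSimulateSFS:
    def test_neutral_prf_limit(self, rng):
        # large theta, no distortion/error: mean x_i/x_1 approaches 1/i
        cfg = SimConfig(n_chromosomes=10, theta_neutral=1e6, epsilon=0.0)
        x = simulate_sfs(cfg, selected=False, rng=rng).x
        assert np.allclose(x / x[0], 1.0 / np.arange(1, 10), rtol=0.02)

    def test_full_mixing_symmetrizes_in_expectation(self):
        cfg = SimConfig(n_chromosomes=10, theta_neutral=2e4, epsilon=0.5)
        total = np.zeros(9)
        for seed in range(30):
            total += simulate_sfs(cfg, rng=np.random.default_rng(seed)).x
        mean = total / 30
        assert np.allclose(mean, mean[::-1], rtol=0.05)

    def test_selected_mean_matches_deterministic_expectation(self):
        cfg = SimConfig(
            n_chromosomes=20, theta_selected=5000.0, shape_a=0.5, scale_b=400.0
        )
        total = np.zeros(19)
        reps = 50
        for seed in range(reps):
            total += simulate_sfs(cfg, selected=True, rng=np.random.default_rng(seed)).x
        mean = total / reps
        expected = expected_sfs_selected(DFEModel(0, 5000.0, 0.5, 400.0), 20)
        se = np.sqrt(expected / reps)
        assert np.all(np.abs(mean - expected) < 4 * se)

    def test_total_scales_linearly_with_theta(self):
        totals = []
        for theta in (1e3, 2e3, 4e3):
            cfg = SimConfig(n_chromosomes=10, theta_neutral=theta)
            s = sum(
                simulate_sfs(cfg, rng=np.random.default_rng(k)).segregating_sites
                for k in range(50)
            )
            totals.append(s / 50)
        assert totals[1] / totals[0] == pytest.approx(2.0, rel=0.05)
        assert totals[2] / totals[1] == pytest.approx(2.0, rel=0.05)

    def test_deterministic_under_seed(self):
        cfg = SimConfig(n_chromosomes=12, seed=42)
        assert np.array_equal(simulate_sfs(cfg).x, simulate_sfs(cfg).x)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            simulate_sfs(SimConfig(n_chromosomes=2))
        with pytest.raises(ValueError):
            simulate_sfs(SimConfig(epsilon=0.7))
        with pytest.raises(ValueError):
            simulate_sfs(SimConfig(theta_neutral=-1.0))


class TestTriplet:
    def test_zero_branches_identical_to_ancestor(self):
        aln = simulate_triplet_alignment(500, (0.0, 0.0, 0.0), seed=3)
        assert aln.salmon == aln.trout == aln.charr == aln.ancestor

    def test_branch_divergence_near_nominal(self):
        from wgdreg.divergence import k80_distance

        aln = simulate_triplet_alignment(100_000, (0.05, 0.02, 0.0), seed=13)
        d = k80_distance(aln.salmon, aln.ancestor)
        assert d == pytest.approx(0.05, abs=3 * np.sqrt(0.05 / 100_000))

    def test_kappa_one_transition_transversion_ratio(self):
        # with kappa=1 all six substitution types are equally likely, so
        # transitions make up one third of differences (1 ts : 2 tv classes)
        aln = simulate_triplet_alignment(300_000, (0.1, 0.0, 0.0), kappa=1.0, seed=5)
        ts = tv = 0
        transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
        for x, y in zip(aln.ancestor, aln.salmon):
            if x != y:
                if (x, y) in transitions:
                    ts += 1
                else:
                    tv += 1
        assert ts / tv == pytest.approx(0.5, rel=0.05)

    def test_validation(self):
        with pytest.raises(ValueError):
            simulate_triplet_alignment(0, (0.1, 0.1, 0.1))
        with pytest.raises(ValueError):
            simulate_triplet_alignment(10, (-0.1, 0.1, 0.1))


class TestToyGenome:
    def test_gene_count_and_strand_aware_tss(self):
        g = generate_toy_genome(ToyGenomeConfig(n_genes=10, n_chromosomes=1), seed=1)
        assert len(g.genes) == 10
        for row in g.genes.itertuples(index=False):
            assert row.tss == (row.start if row.strand == "+" else row.end - 1)

    def test_cds_lengths_divisible_by_three_no_internal_stops(self, toy_genome):
        from wgdreg.annotate import classify_degeneracy

        for seq in toy_genome.cds_sequences.values():
            assert len(seq) % 3 == 0
            classify_degeneracy(seq)  # raises on internal stops

    def test_intervals_within_bounds(self, toy_genome):
        for df in (toy_genome.peaks, toy_genome.repeats):
            for row in df.itertuples(index=False):
                assert 0 <= row.start < row.end <= toy_genome.chrom_lengths[row.chrom]

    def test_homeoblock_pairs_non_overlapping(self, toy_genome):
        for row in toy_genome.homeoblocks.itertuples(index=False):
            if row.chrom1 == row.chrom2:
                assert row.end1 <= row.start2 or row.end2 <= row.start1

    def test_peaks_placed_only_in_introns_when_requested(self):
        cfg = ToyGenomeConfig(n_peaks=10, peak_length=80, peak_context="intron")
        g = generate_toy_genome(cfg, seed=2)
        for row in g.peaks.itertuples(index=False):
            assert np.all(g.category_truth[row.chrom][row.start : row.end] == 1)

    def test_infeasible_packing_reported(self):
        with pytest.raises(ValueError, match="packing"):
            generate_toy_genome(ToyGenomeConfig(chrom_length=5_000, n_genes=20), seed=0)

    def test_fixed_seed_bit_identical_files(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        p1 = generate_toy_genome(ToyGenomeConfig(), seed=9).write(str(d1))
        p2 = generate_toy_genome(ToyGenomeConfig(), seed=9).write(str(d2))
        for key in p1:
            assert open(p1[key], "rb").read() == open(p2[key], "rb").read(), key

    def test_written_files_round_trip(self, toy_genome, toy_dir):
        peaks = wio.read_bed(toy_dir["peaks_bed"])
        assert peaks[["chrom", "start", "end", "name"]].equals(
            toy_genome.peaks[["chrom", "start", "end", "name"]]
        )
        cds = wio.read_fasta(toy_dir["cds_fasta"])
        assert cds == toy_genome.cds_sequences
        blocks = wio.read_tsv(toy_dir["homeoblocks_tsv"])
        assert list(blocks.columns) == list(toy_genome.homeoblocks.columns)
        assert len(blocks) == len(toy_genome.homeoblocks)


class TestSimulateVariants:
    def test_deterministic_and_consistent(self, toy_genome):
        v1 = simulate_variants(toy_genome, SimConfig(n_chromosomes=20), seed=5)
        v2 = simulate_variants(toy_genome, SimConfig(n_chromosomes=20), seed=5)
        assert v1.variants.equals(v2.variants)
        assert np.array_equal(v1.genotypes, v2.genotypes)

    def test_derived_counts_match_genotypes(self, toy_genome):
        vs = simulate_variants(toy_genome, SimConfig(n_chromosomes=20), seed=5)
        clean = ~(
            vs.variants["planted_missing"] | vs.variants["planted_multiallelic"]
        )
        for k in np.flatnonzero(clean.to_numpy())[:200]:
            row = vs.variants.iloc[k]
            gts = vs.genotypes[k]
            alt_is_ancestral = row["alt"] == row["true_ancestral"]
            derived = int(np.sum(gts == 0)) if alt_is_ancestral else int(np.sum(gts == 1))
            assert derived == row["derived_count"]
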