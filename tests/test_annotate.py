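"""Degeneracy classification, region indexing, and the SNP post-filters."""

import numpy as np
import pytest
from Bio.Data import CodonTable

from wgdreg.annotate import (
    VariantRecord,
    annotate_sites,
    build_region_index,
    classify_degeneracy,
    count_callable,
    filter_variants,
)

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_AA = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    _AA[_stop] = "*"
_BASES = "ACGT"


def oracle_degeneracy(seq):
    """Brute force: mutate every site to every base and translate."""
    out = []
    for c in range(0, len(seq), 3):
        codon = seq[c : c + 3]
        aa = _AA[codon]
        if aa == "*":
            out.extend([-1, -1, -1])
            continue
        for off in range(3):
            syn = sum(1 for b in _BASES if _AA[codon[:off] + b + codon[off + 1 :]] == aa)
            out.append({1: 0, 2: 2, 3: 3, 4: 4}[syn])
    return np.array(out, dtype=np.int8)


class TestDegeneracy:
    @pytest.mark.parametrize(
        "codon,expected",
        [
            ("GGG", [0, 0, 4]),  # glycine: third position fully degenerate
            ("ATG", [0, 0, 0]),  # methionine: single codon
            ("CTA", [2, 0, 4]),  # leucine: 2-fold first position (TTA/CTA)
        ],
    )
    def test_known_codons(self, codon, expected):
        assert classify_degeneracy(codon).tolist() == expected

    def test_matches_exhaustive_oracle_on_random_codons(self, rng):
        sense = [
            a + b + c
            for a in _BASES
            for b in _BASES
            for c in _BASES
            if _AA[a + b + c] != "*"
        ]
        seq = "".join(rng.choice(sense, size=1000))
        assert np.array_equal(classify_degeneracy(seq), oracle_degeneracy(seq))

    def test_rejects_partial_codon_and_internal_stop(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            classify_degeneracy("ATGC")
        with pytest.raises(ValueError, match="stop"):
            classify_degeneracy("ATGTAAGGG")

    def test_terminal_stop_and_ambiguity_excluded(self):
        codes = classify_degeneracy("ATGNNNTAA")
        assert codes[:3].tolist() == [0, 0, 0]
        assert np.all(codes[3:] == -1)


class TestRegionIndex:
    def test_matches_toy_construction_truth(self, toy_genome, region_index):
        for chrom in toy_genome.chrom_lengths:
            assert np.array_equal(
                region_index.category[chrom], toy_genome.category_truth[chrom]
            )
            assert np.array_equal(
                region_index.degeneracy[chrom], toy_genome.degeneracy_truth[chrom]
            )

    def test_empty_gff_is_all_intergenic(self, tmp_path):
        gff = tmp_path / "empty.gff3"
        gff.write_text("##gff-version 3\n")
        idx = build_region_index(str(gff), chrom_lengths={"chr1": 1000})
        assert np.all(idx.category["chr1"] == 0)

    def test_overlap_precedence_cds_wins(self, tmp_path):
        # exon of gene A inside the intron span of overlapping gene B
        gff = tmp_path / "overlap.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\t.\tgene\t101\t200\t.\t+\t.\tID=geneA\n"
            "chr1\t.\tmRNA\t101\t200\t.\t+\t.\tID=geneA.t;Parent=geneA\n"
            "chr1\t.\tCDS\t141\t160\t.\t+\t.\tID=geneA.c;Parent=geneA.t\n"
            "chr1\t.\tgene\t51\t300\t.\t-\t.\tID=geneB\n"
        )
        idx = build_region_index(str(gff), chrom_lengths={"chr1": 400})
        assert idx.category_name("chr1", 150) == "cds"
        assert idx.category_name("chr1", 120) == "intron"
        assert idx.category_name("chr1", 350) == "intergenic"

    def test_callable_partition_property(self, toy_genome, region_index):
        mask = {c: np.ones(l, dtype=bool) for c, l in toy_genome.chrom_lengths.items()}
        total = sum(
            count_callable(mask, region_index, cat)
            for cat in ("intergenic", "intron", "utr", "cds")
        )
        assert total == sum(toy_genome.chrom_lengths.values())

    def test_callable_mask_excludes_repeats(self, toy_genome, region_index):
        mask = toy_genome.callable_mask()
        full = {c: np.ones(l, dtype=bool) for c, l in toy_genome.chrom_lengths.items()}
        repeat_bases = sum(int(r.sum()) for r in region_index.repeat.values())
        masked_out = sum(
            count_callable(full, region_index, "all")
            - count_callable(mask, region_index, "all")
            for _ in [0]
        )
        # repeats may overlap each other, so the difference is the union size
        union = sum(
            int((full[c] & region_index.repeat[c]).sum()) for c in full
        )
        assert masked_out == union
        assert union <= repeat_bases

    def test_empty_category_counts_zero(self, region_index):
        mask = {c: np.zeros_like(v, dtype=bool) for c, v in region_index.category.items()}
        assert count_callable(mask, region_index, "cds") == 0


def _record(chrom="chr1", pos=10_000, alts=("T",), depth=8.0, missing=False, n=20):
    gts = np.zeros(n, dtype=np.int8)
    gts[:3] = 1
    if missing:
        gts[0] = -1
    return VariantRecord(chrom, pos, "A", alts, depth, gts)


class TestFilters:
    def test_multiallelic_removed(self, region_index):
        recs = [_record(alts=("T", "G")), _record(pos=10_001)]
        assert len(filter_variants(recs, region_index)) == 1

    def test_depth_bounds_inclusive(self, region_index):
        kept = filter_variants(
            [
                _record(pos=10_000, depth=3.9),
                _record(pos=10_001, depth=4.0),
                _record(pos=10_002, depth=16.0),
                _record(pos=10_003, depth=16.1),
            ],
            region_index,
        )
        assert [r.pos for r in kept] == [10_001, 10_002]

    def test_repeat_and_missing_and_nan_depth_removed(self, toy_genome, region_index):
        rep = toy_genome.repeats.iloc[0]
        recs = [
            _record(chrom=rep.chrom, pos=int(rep.start)),  # in a repeat
            _record(pos=10_004, missing=True),
            _record(pos=10_005, depth=float("nan")),
            _record(pos=10_006),
        ]
        kept = filter_variants(recs, region_index)
        assert [r.pos for r in kept] == [10_006]

    def test_one_violation_each_keeps_total_minus_k(self, region_index):
        clean = [_record(pos=20_000 + k) for k in range(10)]
        bad = [
            _record(pos=30_000, alts=("T", "G")),
            _record(pos=30_001, depth=2.0),
            _record(pos=30_002, depth=20.0),
            _record(pos=30_003, missing=True),
        ]
        kept = filter_variants(clean + bad, region_index)
        assert len(kept) == len(clean)


class TestAnnotateSites:
    def test_annotation_matches_truth_categories(self, toy_genome, region_index):
        rng = np.random.default_rng(0)
        recs = []
        for chrom, cat in toy_genome.category_truth.items():
            pos = rng.choice(len(cat), size=200, replace=False)
            recs.extend(_record(chrom=chrom, pos=int(p)) for p in np.sort(pos))
        sites = annotate_sites(recs, region_index)
        assert len(sites) == len(recs)
        names = {0: "intergenic", 1: "intron", 2: "utr", 3: "cds"}
        for s in sites:
            assert s.category == names[int(toy_genome.category_truth[s.chrom][s.pos])]
            assert s.gene_id is not None

    def test_unknown_contig_skipped_and_empty_input(self, region_index):
        assert annotate_sites([], region_index) == []
        assert annotate_sites([_record(chrom="chrX")], region_index) == []

    def test_idempotent_and_order_independent(self, region_index):
        recs = [_record(pos=p) for p in (5_000, 15_000, 25_000)]
        a = annotate_sites(recs, region_index)
        b = annotate_sites(list(reversed(recs)), region_index)
        key = lambda s: (s.chrom, s.pos)
        assert sorted(map(key, a)) == sorted(map(key, b))
        assert annotate_sites(recs, region_index) == a
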