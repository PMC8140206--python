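import os

import numpy as np
import pytest

from wgdreg import io as wio
from wgdreg.annotate import build_region_index
from wgdreg.simulate import (
    SimConfig,
    ToyGenomeConfig,
    generate_toy_genome,
    simulate_category_alignments,
    simulate_variants,
)

TOY_SEED = 3


@pytest.fixture(scope="session")
def toy_genome():
    return generate_toy_genome(ToyGenomeConfig(), seed=TOY_SEED)


@pytest.fixture(scope="session")
def toy_dir(toy_genome, tmp_path_factory):
    """Toy genome serialized to disk, plus variants and triplet alignments."""
    d = tmp_path_factory.mktemp("toy")
    paths = toy_genome.write(str(d))
    variants = simulate_variants(toy_genome, SimConfig(n_chromosomes=20), seed=5)
    paths.update(variants.write(str(d), contigs=toy_genome.chrom_lengths))
    aln_dir = d / "alignments"
    aln_dir.mkdir()
    for cat, aln in simulate_category_alignments(
        ["4fold", "0fold", "cds", "utr", "intron", "intergenic"], seed=7
    ).items():
        wio.write_fasta(
            {"salmon": aln.salmon, "trout": aln.trout, "charr": aln.charr},
            str(aln_dir / f"{cat}.fasta"),
        )
    paths["alignments_dir"] = str(aln_dir)
    paths["variant_set"] = variants
    return paths


@pytest.fixture(scope="session")
def region_index(toy_genome, toy_dir):
    return build_region_index(
        toy_dir["gff3"],
        repeats_bed=toy_dir["repeats_bed"],
        peaks_bed=toy_dir["peaks_bed"],
        cds_fasta=toy_dir["cds_fasta"],
        chrom_lengths=toy_genome.chrom_lengths,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
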