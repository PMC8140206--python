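"""Synthetic data with the statistical structure the pipeline assumes.

Three generators cover every input the analysis consumes:

* :func:`simulate_sfs` draws unfolded spectra from the same Poisson Random
  Field model the DFE estimator fits (independent Poisson counts per
  frequency class around the model expectation, with demographic
  distortion and polarization-error mixing applied) — forward simulation
  from the estimator's own model, so parameter recovery is well-posed.
* :func:`simulate_triplet_alignment` evolves salmon / brown trout / Arctic
  charr sequences independently from a common ancestor along a three-taxon
  star topology under K80, returning the true ancestral sequence as ground
  truth for polarization and distance estimators.
* :func:`generate_toy_genome` builds an internally consistent miniature
  genome (genes with UTR/CDS/intron structure, CDS sequences free of
  internal stops, H3K27ac-style peaks, repeats, homeoblock pairs with
  reploidization ages, ohnolog pairs with expression) and serializes it to
  GFF3/BED/FASTA/TSV; :func:`simulate_variants` overlays a VCF of
  biallelic SNPs plus the outgroup-base table used for polarization.

All outputs are bit-identical under a fixed seed.
"""

from __future__ import annotations

import itertools
import os
from dataclasses import dataclass, replace
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy.linalg import expm

from . import dfe as dfe_mod
from . import io as wio
from .annotate import classify_degeneracy
from .sfs import SFS

__all__ = [
    "SimConfig",
    "simulate_sfs",
    "TripletAlignment",
    "simulate_triplet_alignment",
    "ToyGenomeConfig",
    "ToyGenome",
    "generate_toy_genome",
    "VariantSet",
    "simulate_variants",
    "simulate_category_alignments",
]

_BASES = np.array(["A", "C", "G", "T"])


# ---------------------------------------------------------------------------
# SFS simulation


@dataclass
class SimConfig:
    """Conditions for SFS simulation.

    Defaults mirror the study design this pipeline emulates: 62 sampled
    chromosomes (31 fully genotyped diploids), a reflected-gamma DFE of
    moderate shape with most mass effectively neutral at the shape/scale
    chosen, no polarization error and no demographic distortion unless
    requested.
    """

    n_chromosomes: int = 62
    theta_neutral: float = 10_000.0
    theta_selected: float = 10_000.0
    shape_a: float = 0.5
    scale_b: float = 400.0
    epsilon: float = 0.0
    r: np.ndarray | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_chromosomes < 4:
            raise ValueError("n_chromosomes must be >= 4")
        if self.theta_neutral < 0 or self.theta_selected < 0:
            raise ValueError("theta must be >= 0")
        if not (self.shape_a > 0 and self.scale_b > 0):
            raise ValueError("gamma shape and scale must be > 0")
        if not (0.0 <= self.epsilon <= 0.5):
            raise ValueError("epsilon must lie in [0, 0.5]")
        if self.r is not None:
            r = np.asarray(self.r, dtype=float)
            if r.size != self.n_chromosomes - 1:
                raise ValueError("r must have length n - 1")
            if np.any(~np.isfinite(r)) or np.any(r <= 0):
                raise ValueError("r must be finite and > 0")
            if abs(r[0] - 1.0) > 1e-12:
                raise ValueError("r[0] must equal 1")

    def model(self) -> dfe_mod.DFEModel:
        return dfe_mod.DFEModel(
            theta_n=self.theta_neutral,
            theta_s=self.theta_selected,
            shape=self.shape_a,
            scale=self.scale_b,
            eps_n=self.epsilon,
            eps_s=self.epsilon,
            r=None if self.r is None else np.asarray(self.r, dtype=float),
        )


def expected_sfs(config: SimConfig, selected: bool) -> np.ndarray:
    """Deterministic expectation the Poisson draws are centred on."""
    config.validate()
    model = config.model()
    n = config.n_chromosomes
    if selected:
        return dfe_mod.expected_sfs_selected(model, n)
    return dfe_mod.expected_sfs_neutral(model, n)


def simulate_sfs(
    config: SimConfig,
    selected: bool = False,
    rng: np.random.Generator | None = None,
    L: float | None = None,
) -> SFS:
    """Draw an unfolded SFS: independent Poisson counts per frequency class.

    ``L`` defaults to 100x the class theta, a nominal callable-site count
    (the PRF likelihood itself never uses L).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    mean = expected_sfs(config, selected)
    x = rng.poisson(mean).astype(float)
    theta = config.theta_selected if selected else config.theta_neutral
    if L is None:
        L = max(100.0 * theta, float(x.sum()))
    return SFS(
        n=config.n_chromosomes,
        x=x,
        L=L,
        category="selected" if selected else "neutral",
    )


# ---------------------------------------------------------------------------
# triplet alignment under K80


class TripletAlignment(NamedTuple):
    salmon: str
    trout: str
    charr: str
    ancestor: str


def _k80_transition_matrix(distance: float, kappa: float) -> np.ndarray:
    """K80 substitution probabilities after ``distance`` expected subs/site.

    Base order ACGT; transitions are A<->G and C<->T, with rate ratio
    kappa = alpha/beta.  The rate matrix is scaled to one expected
    substitution per site per unit distance.
    """
    if distance < 0:
        raise ValueError("branch length must be >= 0")
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    a = kappa / (kappa + 2.0)  # transition rate
    b = 1.0 / (kappa + 2.0)  # each transversion rate
    Q = np.array(
        [
            [-(a + 2 * b), b, a, b],
            [b, -(a + 2 * b), b, a],
            [a, b, -(a + 2 * b), b],
            [b, a, b, -(a + 2 * b)],
        ]
    )
    return expm(Q * distance)


def _evolve(codes: np.ndarray, distance: float, kappa: float, rng) -> np.ndarray:
    P = _k80_transition_matrix(distance, kappa)
    out = np.empty_like(codes)
    for base in range(4):
        idx = np.flatnonzero(codes == base)
        if idx.size:
            out[idx] = rng.choice(4, size=idx.size, p=P[base])
    return out


def simulate_triplet_alignment(
    length: int,
    branch_lengths: tuple[float, float, float],
    kappa: float = 2.0,
    seed: int | None = None,
) -> TripletAlignment:
    """Evolve salmon/trout/charr from a common ancestor on a star topology.

    ``branch_lengths`` are the K80 distances (expected substitutions per
    site) from the ancestor to salmon, trout, and charr respectively.  No
    among-site rate variation.  Returns the three tip sequences and the
    true ancestral sequence.
    """
    if length <= 0:
        raise ValueError("length must be > 0")
    rng = np.random.default_rng(seed)
    anc = rng.integers(0, 4, size=length)
    tips = [_evolve(anc, d, kappa, rng) for d in branch_lengths]
    to_str = lambda codes: "".join(_BASES[codes])
    return TripletAlignment(to_str(tips[0]), to_str(tips[1]), to_str(tips[2]), to_str(anc))


# ---------------------------------------------------------------------------
# toy genome


@dataclass
class ToyGenomeConfig:
    n_chromosomes: int = 2
    chrom_length: int = 300_000
    n_genes: int = 40
    n_peaks: int = 80
    peak_length: int = 600
    peak_context: str = "mixed"  # mixed | intron | intergenic | promoter
    n_repeats: int = 20
    repeat_length: int = 1_000
    n_homeoblocks: int = 6
    n_ohnologs: int = 10
    equal_ohnolog_expression: bool = False
    min_cds_codons: int = 80
    max_cds_codons: int = 220

    def validate(self) -> None:
        if min(self.n_chromosomes, self.chrom_length) <= 0:
            raise ValueError("sizes must be positive")
        for v in (self.n_genes, self.n_peaks, self.n_repeats, self.n_homeoblocks, self.n_ohnologs):
            if v < 0:
                raise ValueError("counts must be >= 0")


@dataclass
class ToyGenome:
    """In-memory fixture plus construction-time truth for bookkeeping tests."""

    chrom_lengths: dict[str, int]
    genes: pd.DataFrame  # gene_id, chrom, start, end, strand, tss
    gene_features: list[tuple]  # GFF3 feature tuples (0-based half-open)
    cds_sequences: dict[str, str]
    peaks: pd.DataFrame
    repeats: pd.DataFrame
    homeoblocks: pd.DataFrame
    ohnologs: pd.DataFrame
    category_truth: dict[str, np.ndarray]
    degeneracy_truth: dict[str, np.ndarray]

    def callable_mask(self) -> dict[str, np.ndarray]:
        """All positions outside repeats are callable."""
        mask = {c: np.ones(l, dtype=bool) for c, l in self.chrom_lengths.items()}
        for row in self.repeats.itertuples(index=False):
            mask[row.chrom][row.start : row.end] = False
        return mask

    def category_base_counts(self) -> dict[str, int]:
        """Construction-time truth: bases per primary category (plus folds)."""
        out: dict[str, int] = {}
        for name, code in (("intergenic", 0), ("intron", 1), ("utr", 2), ("cds", 3)):
            out[name] = int(sum(np.sum(a == code) for a in self.category_truth.values()))
        for name, code in (("0fold", 0), ("4fold", 4)):
            out[name] = int(
                sum(np.sum(d == code) for d in self.degeneracy_truth.values())
            )
        return out

    def write(self, outdir: str) -> dict[str, str]:
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "gff3": os.path.join(outdir, "genes.gff3"),
            "cds_fasta": os.path.join(outdir, "cds.fasta"),
            "peaks_bed": os.path.join(outdir, "peaks.bed"),
            "repeats_bed": os.path.join(outdir, "repeats.bed"),
            "callable_bed": os.path.join(outdir, "callable.bed"),
            "homeoblocks_tsv": os.path.join(outdir, "homeoblocks.tsv"),
            "ohnologs_tsv": os.path.join(outdir, "ohnologs.tsv"),
            "chrom_sizes": os.path.join(outdir, "chrom.sizes"),
        }
        wio.write_gff3(self.gene_features, paths["gff3"])
        wio.write_fasta(self.cds_sequences, paths["cds_fasta"])
        wio.write_bed(self.peaks, paths["peaks_bed"])
        wio.write_bed(self.repeats, paths["repeats_bed"])
        mask = self.callable_mask()
        rows = []
        for chrom in sorted(mask):
            m = mask[chrom]
            edges = np.diff(np.concatenate([[0], m.view(np.int8), [0]]))
            starts, ends = np.flatnonzero(edges == 1), np.flatnonzero(edges == -1)
            for s, e in zip(starts, ends):
                rows.append({"chrom": chrom, "start": int(s), "end": int(e)})
        callable_df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        wio.write_bed(callable_df, paths["callable_bed"])
        self.homeoblocks.to_csv(paths["homeoblocks_tsv"], sep="\t", index=False)
        self.ohnologs.to_csv(paths["ohnologs_tsv"], sep="\t", index=False)
        pd.DataFrame(
            {"chrom": list(self.chrom_lengths), "length": list(self.chrom_lengths.values())}
        ).to_csv(paths["chrom_sizes"], sep="\t", index=False, header=False)
        return paths


def _random_cds(n_codons: int, rng) -> str:
    """Random CDS: ATG start, no internal stops, stop codon at the end."""
    stops = {"TAA", "TAG", "TGA"}
    codons = ["ATG"]
    sense = [c for c in ("".join(t) for t in itertools.product("ACGT", repeat=3)) if c not in stops]
    idx = rng.integers(0, len(sense), size=n_codons - 2)
    codons.extend(sense[k] for k in idx)
    codons.append(["TAA", "TAG", "TGA"][rng.integers(0, 3)])
    return "".join(codons)


def _gene_segments(n_codons: int, rng) -> list[tuple[str, int]]:
    """Segment plan in transcription order: UTR5, CDS chunks/introns, UTR3."""
    utr5 = int(rng.integers(60, 200))
    utr3 = int(rng.integers(100, 300))
    n_exons = int(rng.integers(1, 4))
    cds_len = 3 * n_codons
    cuts = np.sort(rng.choice(np.arange(3, cds_len - 3, 3), size=n_exons - 1, replace=False)) if n_exons > 1 else np.array([], dtype=int)
    chunk_edges = np.concatenate([[0], cuts, [cds_len]])
    segments: list[tuple[str, int]] = [("utr5", utr5)]
    for k in range(n_exons):
        segments.append(("cds", int(chunk_edges[k + 1] - chunk_edges[k])))
        if k < n_exons - 1:
            segments.append(("intron", int(rng.integers(100, 400))))
    segments.append(("utr3", utr3))
    return segments


def generate_toy_genome(config: ToyGenomeConfig | None = None, seed: int = 0) -> ToyGenome:
    """Build the miniature genome fixture; see the module docstring."""
    config = config or ToyGenomeConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    chroms = {f"chr{k + 1}": config.chrom_length for k in range(config.n_chromosomes)}
    category = {c: np.zeros(l, dtype=np.uint8) for c, l in chroms.items()}
    degeneracy = {c: np.full(l, -1, dtype=np.int8) for c, l in chroms.items()}

    cursors = {c: int(rng.integers(500, 3000)) for c in chroms}
    gene_rows, features, cds_seqs = [], [], {}
    chrom_names = list(chroms)
    for g in range(config.n_genes):
        chrom = chrom_names[g % len(chrom_names)]
        n_codons = int(rng.integers(config.min_cds_codons, config.max_cds_codons))
        strand = "+" if rng.random() < 0.5 else "-"
        segments = _gene_segments(n_codons, rng)
        if strand == "-":
            segments = segments[::-1]
        total = sum(l for _, l in segments)
        start = cursors[chrom]
        if start + total > chroms[chrom] - 500:
            raise ValueError(
                f"infeasible packing: gene {g} does not fit on {chrom} "
                f"(need {total} bp at {start})"
            )
        gid = f"gene{g:03d}"
        pos = start
        placed = []
        for seg_type, seg_len in segments:
            placed.append((seg_type, pos, pos + seg_len))
            pos += seg_len
        end = pos
        cursors[chrom] = end + int(rng.integers(2000, 6000))
        tss = start if strand == "+" else end - 1

        # paint category truth with CDS > UTR > intron precedence
        category[chrom][start:end] = 1
        for seg_type, s, e in placed:
            if seg_type in ("utr5", "utr3"):
                category[chrom][s:e] = 2
        for seg_type, s, e in placed:
            if seg_type == "cds":
                category[chrom][s:e] = 3

        cds_seq = _random_cds(n_codons, rng)
        cds_seqs[gid] = cds_seq
        cds_parts = [(s, e) for t, s, e in placed if t == "cds"]
        genomic = np.concatenate([np.arange(s, e) for s, e in cds_parts])
        if strand == "-":
            genomic = genomic[::-1]
        degeneracy[chrom][genomic] = classify_degeneracy(cds_seq)

        features.append((chrom, "toy", "gene", start, end, strand, {"ID": gid}))
        mrna = f"{gid}.t1"
        features.append((chrom, "toy", "mRNA", start, end, strand, {"ID": mrna, "Parent": gid}))
        # exons: contiguous runs of non-intron segments
        exon_start = None
        exon_id = 0
        for k, (seg_type, s, e) in enumerate(placed + [("intron", end, end)]):
            if seg_type == "intron":
                if exon_start is not None:
                    features.append(
                        (chrom, "toy", "exon", exon_start, s_prev_end, strand,
                         {"ID": f"{mrna}.exon{exon_id}", "Parent": mrna})
                    )
                    exon_id += 1
                    exon_start = None
            else:
                if exon_start is None:
                    exon_start = s
                s_prev_end = e
        # segment labels follow transcription order, so 'utr5' is the 5' UTR
        # on either strand (it sits rightmost on the minus strand)
        utr_type = {"utr5": "five_prime_UTR", "utr3": "three_prime_UTR"}
        for seg_type, s, e in placed:
            if seg_type == "cds":
                features.append(
                    (chrom, "toy", "CDS", s, e, strand, {"ID": f"{mrna}.cds", "Parent": mrna})
                )
            elif seg_type in ("utr5", "utr3"):
                features.append(
                    (chrom, "toy", utr_type[seg_type], s, e, strand,
                     {"ID": f"{mrna}.{seg_type}", "Parent": mrna})
                )
        gene_rows.append(
            {"gene_id": gid, "chrom": chrom, "start": start, "end": end, "strand": strand, "tss": tss}
        )

    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "start", "end", "strand", "tss"])

    # repeats: anywhere, may overlap genes
    rep_rows = []
    for k in range(config.n_repeats):
        chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
        start = int(rng.integers(0, chroms[chrom] - config.repeat_length))
        rep_rows.append({"chrom": chrom, "start": start, "end": start + config.repeat_length,
                         "name": f"repeat{k:03d}"})
    repeats = pd.DataFrame(rep_rows, columns=["chrom", "start", "end", "name"])

    peaks = _place_peaks(config, chroms, category, genes, rng)
    homeoblocks = _place_homeoblocks(config, chroms, rng)
    ohnologs = _pick_ohnologs(config, genes, rng)

    return ToyGenome(
        chrom_lengths=chroms,
        genes=genes,
        gene_features=features,
        cds_sequences=cds_seqs,
        peaks=peaks,
        repeats=repeats,
        homeoblocks=homeoblocks,
        ohnologs=ohnologs,
        category_truth=category,
        degeneracy_truth=degeneracy,
    )


def _valid_starts(ok: np.ndarray, length: int) -> np.ndarray:
    """Start positions s such that ok[s:s+length] is all True."""
    c = np.concatenate([[0], np.cumsum(ok.astype(np.int64))])
    starts = np.arange(ok.size - length + 1)
    return starts[c[starts + length] - c[starts] == length]


def _place_peaks(config, chroms, category, genes, rng) -> pd.DataFrame:
    rows = []
    occupied = {c: np.zeros(l, dtype=bool) for c, l in chroms.items()}
    chrom_names = list(chroms)
    L = config.peak_length
    for k in range(config.n_peaks):
        placed = False
        for _ in range(50):
            chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
            if config.peak_context == "mixed":
                ok = ~occupied[chrom]
            elif config.peak_context in ("intron", "intergenic"):
                code = {"intergenic": 0, "intron": 1}[config.peak_context]
                ok = (category[chrom] == code) & ~occupied[chrom]
            elif config.peak_context == "promoter":
                ok = np.zeros(chroms[chrom], dtype=bool)
                for g in genes[genes["chrom"] == chrom].itertuples(index=False):
                    lo, hi = (g.tss - 1000, g.tss + 100) if g.strand == "+" else (g.tss - 100, g.tss + 1000)
                    ok[max(lo, 0) : min(hi + 1, chroms[chrom])] = True
                ok &= ~occupied[chrom]
            else:
                raise ValueError(f"unknown peak_context {config.peak_context!r}")
            starts = _valid_starts(ok, L)
            if starts.size == 0:
                continue
            s = int(starts[rng.integers(0, starts.size)])
            occupied[chrom][s : s + L] = True
            rows.append({"chrom": chrom, "start": s, "end": s + L, "name": f"peak{k:04d}"})
            placed = True
            break
        if not placed:
            raise ValueError(f"could not place peak {k} in context {config.peak_context!r}")
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def _place_homeoblocks(config, chroms, rng) -> pd.DataFrame:
    rows = []
    chrom_names = list(chroms)
    for k in range(config.n_homeoblocks):
        L1 = int(rng.integers(20_000, 60_000))
        L2 = int(L1 * rng.uniform(0.8, 1.2))
        for _ in range(100):
            c1 = chrom_names[int(rng.integers(0, len(chrom_names)))]
            c2 = chrom_names[int(rng.integers(0, len(chrom_names)))]
            s1 = int(rng.integers(0, chroms[c1] - L1))
            s2 = int(rng.integers(0, chroms[c2] - L2))
            if c1 != c2 or s1 + L1 <= s2 or s2 + L2 <= s1:
                break
        else:
            raise ValueError("could not place non-overlapping homeoblock pair")
        rows.append(
            {
                "block_id": f"block{k:02d}",
                "chrom1": c1, "start1": s1, "end1": s1 + L1,
                "chrom2": c2, "start2": s2, "end2": s2 + L2,
                "age_ma": float(np.round(rng.uniform(20.0, 90.0), 2)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["block_id", "chrom1", "start1", "end1", "chrom2", "start2", "end2", "age_ma"],
    )


def _pick_ohnologs(config, genes, rng) -> pd.DataFrame:
    n = min(config.n_ohnologs, len(genes) // 2)
    ids = rng.permutation(genes["gene_id"].to_numpy())[: 2 * n]
    rows = []
    for k in range(n):
        e1 = float(np.round(rng.lognormal(3.0, 1.0), 3))
        e2 = e1 if config.equal_ohnolog_expression else float(np.round(rng.lognormal(3.0, 1.0), 3))
        rows.append({"gene1": ids[2 * k], "gene2": ids[2 * k + 1], "expr1": e1, "expr2": e2})
    return pd.DataFrame(rows, columns=["gene1", "gene2", "expr1", "expr2"])


# ---------------------------------------------------------------------------
# variants over the toy genome


@dataclass
class VariantSet:
    variants: pd.DataFrame  # chrom, pos, ref, alt, true_ancestral, derived_count
    genotypes: np.ndarray
    depths: np.ndarray
    outgroups: pd.DataFrame  # chrom, pos, trout_base, charr_base
    sample_names: list[str]
    n_chromosomes: int

    def write(self, outdir: str, contigs: Mapping[str, int] | None = None) -> dict[str, str]:
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "vcf": os.path.join(outdir, "variants.vcf"),
            "outgroups_tsv": os.path.join(outdir, "outgroups.tsv"),
        }
        wio.write_vcf(
            self.variants[["chrom", "pos", "ref", "alt"]],
            self.genotypes,
            self.depths,
            self.sample_names,
            paths["vcf"],
            contigs=contigs,
        )
        self.outgroups.to_csv(paths["outgroups_tsv"], sep="\t", index=False)
        return paths


def simulate_variants(
    genome: ToyGenome,
    sim: SimConfig | None = None,
    theta_site_neutral: float = 0.008,
    outgroup_error: float = 0.01,
    f_bad_depth: float = 0.02,
    f_missing: float = 0.02,
    f_multiallelic: float = 0.01,
    seed: int = 0,
) -> VariantSet:
    """Place biallelic SNPs on the toy genome under the PRF model.

    0-fold CDS sites receive the selected (gamma-DFE) expected spectrum;
    all other callable sites the neutral one; per-class totals scale with
    the class's callable length via ``theta_site_neutral``.  A small
    fraction of sites deliberately violate each post-filter (depth out of
    the [4,16] band, missing genotypes, a third allele) so the filters are
    exercised end to end.  Outgroup bases equal the true ancestral allele
    except for independent errors at rate ``outgroup_error``.
    """
    sim = sim or SimConfig()
    sim.validate()
    rng = np.random.default_rng(seed)
    n = sim.n_chromosomes
    if n % 2 != 0:
        raise ValueError("n_chromosomes must be even (diploid samples)")
    n_samples = n // 2
    sample_names = [f"ind{k:02d}" for k in range(n_samples)]
    mask = genome.callable_mask()

    # positions by selection class
    sel_pos, neu_pos = [], []
    for chrom, cat in genome.category_truth.items():
        callable_here = mask[chrom]
        zerofold = (genome.degeneracy_truth[chrom] == 0) & callable_here
        other = callable_here & ~zerofold
        sel_pos.append((chrom, np.flatnonzero(zerofold)))
        neu_pos.append((chrom, np.flatnonzero(other)))

    records = []
    for positions, selected in ((neu_pos, False), (sel_pos, True)):
        total_L = sum(p.size for _, p in positions)
        if total_L == 0:
            continue
        theta_class = theta_site_neutral * total_L
        cfg = replace(
            sim,
            theta_neutral=theta_class,
            theta_selected=theta_class,
            r=None if sim.r is None else np.asarray(sim.r, dtype=float),
        )
        mean = expected_sfs(cfg, selected)
        x = rng.poisson(mean)
        n_snps = int(x.sum())
        flat = np.concatenate(
            [np.stack([np.full(p.size, ci), p], axis=1) for ci, (_, p) in enumerate(positions)]
        )
        chrom_names = [c for c, _ in positions]
        take = rng.choice(flat.shape[0], size=min(n_snps, flat.shape[0]), replace=False)
        derived_counts = np.repeat(np.arange(1, n), x)[: take.size]
        for (ci, pos), i in zip(flat[take], derived_counts):
            records.append((chrom_names[int(ci)], int(pos), int(i), selected))

    records.sort(key=lambda t: (t[0], t[1]))
    m = len(records)
    genotypes = np.zeros((m, n), dtype=np.int8)
    depths = np.clip(np.round(rng.normal(8.0, 2.0, size=(m, n_samples))), 1, 30).astype(int)
    var_rows, out_rows = [], []
    for k, (chrom, pos, i, selected) in enumerate(records):
        anc, der = rng.choice(4, size=2, replace=False)
        anc_b, der_b = _BASES[anc], _BASES[der]
        # REF is the ancestral or derived allele at random, as in real calls
        if rng.random() < 0.5:
            ref, alt = anc_b, der_b
            carriers = rng.choice(n, size=i, replace=False)
        else:
            ref, alt = der_b, anc_b
            carriers = rng.choice(n, size=n - i, replace=False)
        genotypes[k, carriers] = 1
        trout, charr = anc_b, anc_b
        if rng.random() < outgroup_error:
            trout = _BASES[(anc + 1 + rng.integers(0, 3)) % 4]
        if rng.random() < outgroup_error:
            charr = _BASES[(anc + 1 + rng.integers(0, 3)) % 4]
        var_rows.append(
            {"chrom": chrom, "pos": pos, "ref": str(ref), "alt": str(alt),
             "true_ancestral": str(anc_b), "derived_count": i, "selected": selected}
        )
        out_rows.append(
            {"chrom": chrom, "pos": pos, "trout_base": str(trout), "charr_base": str(charr)}
        )

    # planted filter violations
    bad_depth = rng.random(m) < f_bad_depth
    depths[bad_depth] = np.where(rng.random((int(bad_depth.sum()), 1)) < 0.5, 2, 20)
    missing = rng.random(m) < f_missing
    variants = pd.DataFrame(
        var_rows,
        columns=["chrom", "pos", "ref", "alt", "true_ancestral", "derived_count", "selected"],
    )
    variants["planted_bad_depth"] = bad_depth
    variants["planted_missing"] = missing
    for k in np.flatnonzero(missing):
        s = int(rng.integers(0, n_samples))
        genotypes[k, 2 * s] = -1
        genotypes[k, 2 * s + 1] = -1
    multi = rng.random(m) < f_multiallelic
    variants["planted_multiallelic"] = multi
    alt_col = variants["alt"].to_numpy(dtype=object)
    for k in np.flatnonzero(multi):
        third = next(b for b in _BASES if b not in (variants.at[k, "ref"], variants.at[k, "alt"]))
        alt_col[k] = f"{variants.at[k, 'alt']},{third}"
    variants["alt"] = alt_col

    outgroups = pd.DataFrame(out_rows, columns=["chrom", "pos", "trout_base", "charr_base"])
    return VariantSet(variants, genotypes, depths, outgroups, sample_names, n)


def simulate_category_alignments(
    categories: list[str],
    length: int = 20_000,
    salmon_branch: float = 0.05,
    outgroup_branch: tuple[float, float] = (0.05, 0.12),
    category_branch_scale: Mapping[str, float] | None = None,
    kappa: float = 2.0,
    seed: int = 0,
) -> dict[str, TripletAlignment]:
    """One concatenated triplet alignment per site category.

    Purifying selection shrinks divergence on the salmon branch by the
    per-category scale factor (default: coding classes < neutral classes).
    """
    scales = {
        "4fold": 1.0, "intergenic": 0.95, "intron": 0.95, "utr": 0.8,
        "cds": 0.5, "0fold": 0.35, "all": 0.9,
    }
    if category_branch_scale:
        scales.update(category_branch_scale)
    out = {}
    for k, cat in enumerate(categories):
        out[cat] = simulate_triplet_alignment(
            length,
            (salmon_branch * scales.get(cat, 1.0), outgroup_branch[0], outgroup_branch[1]),
            kappa=kappa,
            seed=(seed + 7919 * (k + 1)) % (2**31 - 1),
        )
    return out
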