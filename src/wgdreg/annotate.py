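"""Functional site classification and the study-style SNP post-filters.

Every genomic position receives exactly one primary category under the
precedence CDS > UTR > intron > intergenic; H3K27ac-peak and repeat overlap
are orthogonal flags.  Inside CDS, each position additionally carries a
codon degeneracy class (0/2/3/4-fold); 4-fold sites serve as the neutral
reference and 0-fold sites as the canonical selected class, with 2- and
3-fold sites labelled but excluded from both.

The index is dense (one byte-per-base array per chromosome), which is
exact, vectorizable, and comfortably sized for the assembled-chromosome
scale this pipeline targets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import gffutils
import numpy as np

from Bio.Data import CodonTable

from . import io as wio

__all__ = [
    "CAT_INTERGENIC",
    "CAT_INTRON",
    "CAT_UTR",
    "CAT_CDS",
    "RegionIndex",
    "SiteRecord",
    "VariantRecord",
    "classify_degeneracy",
    "build_region_index",
    "filter_variants",
    "annotate_sites",
    "count_callable",
]

logger = logging.getLogger(__name__)

CAT_INTERGENIC, CAT_INTRON, CAT_UTR, CAT_CDS = 0, 1, 2, 3
CATEGORY_NAMES = {
    CAT_INTERGENIC: "intergenic",
    CAT_INTRON: "intron",
    CAT_UTR: "utr",
    CAT_CDS: "cds",
}
PRIMARY_CATEGORIES = ("intergenic", "intron", "utr", "cds")

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
_BASES = ("A", "C", "G", "T")


def _codon_to_aa() -> dict[str, str]:
    table = dict(_STANDARD_TABLE.forward_table)
    for stop in _STANDARD_TABLE.stop_codons:
        table[stop] = "*"
    return table


_CODON_AA = _codon_to_aa()


def classify_degeneracy(cds_sequence: str, allow_terminal_stop: bool = True) -> np.ndarray:
    """Per-site codon degeneracy of a coding sequence.

    Returns an int8 array with values {0, 2, 3, 4}: the number of
    nucleotide states at the position that preserve the amino acid (a site
    is 4-fold iff every substitution is synonymous, 0-fold iff none is).
    Positions in codons containing ambiguous bases get -1 (excluded).

    Raises on length not divisible by 3 or on internal stop codons.
    """
    seq = cds_sequence.upper()
    if len(seq) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    codes = np.full(len(seq), -1, dtype=np.int8)
    n_codons = len(seq) // 3
    for c in range(n_codons):
        codon = seq[3 * c : 3 * c + 3]
        if any(b not in _BASES for b in codon):
            continue
        aa = _CODON_AA[codon]
        if aa == "*":
            if allow_terminal_stop and c == n_codons - 1:
                continue
            raise ValueError(f"internal stop codon at codon {c}")
        for offset in range(3):
            synonymous = sum(
                1
                for b in _BASES
                if _CODON_AA[codon[:offset] + b + codon[offset + 1 :]] == aa
            )
            # map "count of synonymous states" onto the conventional labels
            codes[3 * c + offset] = {1: 0, 2: 2, 3: 3, 4: 4}[synonymous]
    return codes


@dataclass
class VariantRecord:
    """One VCF site after parsing, before/after filtering."""

    chrom: str
    pos: int  # 0-based
    ref: str
    alts: tuple
    mean_depth: float
    genotypes: np.ndarray  # allele codes per chromosome copy, -1 = missing
    ancestral: str | None = None
    derived_count: int | None = None

    @property
    def alt(self) -> str:
        return self.alts[0]

    @property
    def ref_count(self) -> int:
        return int(np.sum(self.genotypes == 0))

    @property
    def alt_count(self) -> int:
        return int(np.sum(self.genotypes == 1))

    @property
    def has_missing(self) -> bool:
        return bool(np.any(self.genotypes < 0))


@dataclass
class SiteRecord:
    """One polarized, annotated biallelic SNP."""

    chrom: str
    pos: int
    ref: str
    alt: str
    derived_count: int | None
    category: str
    peak: bool
    degeneracy: int | None
    gene_id: str | None


class RegionIndex:
    """Dense per-chromosome category/flag/degeneracy arrays plus TSS lookup."""

    def __init__(self, chrom_lengths: Mapping[str, int]):
        self.chrom_lengths = dict(chrom_lengths)
        self.category = {c: np.zeros(l, dtype=np.uint8) for c, l in chrom_lengths.items()}
        self.peak = {c: np.zeros(l, dtype=bool) for c, l in chrom_lengths.items()}
        self.repeat = {c: np.zeros(l, dtype=bool) for c, l in chrom_lengths.items()}
        self.degeneracy = {c: np.full(l, -1, dtype=np.int8) for c, l in chrom_lengths.items()}
        self._tss_pos: dict[str, np.ndarray] = {}
        self._tss_gene: dict[str, np.ndarray] = {}

    def set_tss(self, chrom: str, positions: np.ndarray, gene_ids: list[str]) -> None:
        order = np.argsort(positions, kind="stable")
        self._tss_pos[chrom] = np.asarray(positions)[order]
        self._tss_gene[chrom] = np.asarray(gene_ids, dtype=object)[order]

    def nearest_gene(self, chrom: str, pos: int) -> str | None:
        tss = self._tss_pos.get(chrom)
        if tss is None or tss.size == 0:
            return None
        k = np.searchsorted(tss, pos)
        candidates = [j for j in (k - 1, k) if 0 <= j < tss.size]
        # nearest TSS; equidistant ties go to the lexicographically smaller id
        best = min(candidates, key=lambda j: (abs(int(tss[j]) - pos), str(self._tss_gene[chrom][j])))
        return str(self._tss_gene[chrom][best])

    def category_name(self, chrom: str, pos: int) -> str:
        return CATEGORY_NAMES[int(self.category[chrom][pos])]

    def category_mask(self, chrom: str, selector: str) -> np.ndarray:
        """Boolean mask for a category selector.

        Selectors: the four primary categories, plus the degeneracy-defined
        '0fold' / '4fold' subsets of CDS, plus 'all'.
        """
        cat = self.category[chrom]
        if selector == "all":
            return np.ones_like(cat, dtype=bool)
        if selector in ("0fold", "4fold"):
            want = 0 if selector == "0fold" else 4
            return (cat == CAT_CDS) & (self.degeneracy[chrom] == want)
        code = {v: k for k, v in CATEGORY_NAMES.items()}.get(selector)
        if code is None:
            raise ValueError(f"unknown category selector {selector!r}")
        return cat == code


def _paint(arr: np.ndarray, start: int, end: int, value) -> None:
    arr[max(start, 0) : min(end, arr.size)] = value


def build_region_index(
    gff3_path: str,
    repeats_bed: str | None = None,
    peaks_bed: str | None = None,
    cds_fasta: str | None = None,
    chrom_lengths: Mapping[str, int] | None = None,
) -> RegionIndex:
    """Build the region index from GFF3 gene models and BED flag tracks.

    Categories are painted in increasing precedence (gene span as intron,
    then UTR features, then CDS), so overlapping features resolve to
    CDS > UTR > intron > intergenic.  When ``cds_fasta`` maps gene ids to
    spliced CDS sequences, per-site degeneracy codes are scattered back to
    genomic coordinates (strand-aware).
    """
    try:
        db = gffutils.create_db(
            gff3_path, ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
    except gffutils.exceptions.EmptyInputError:
        # featureless genome: everything is intergenic
        if chrom_lengths is None:
            raise ValueError("empty GFF3 requires explicit chromosome lengths")
        db = None
    if db is None:
        index = RegionIndex(chrom_lengths)
        if repeats_bed is not None:
            for row in wio.read_bed(repeats_bed).itertuples(index=False):
                if row.chrom in index.repeat:
                    _paint(index.repeat[row.chrom], row.start, row.end, True)
        if peaks_bed is not None:
            for row in wio.read_bed(peaks_bed).itertuples(index=False):
                if row.chrom in index.peak:
                    _paint(index.peak[row.chrom], row.start, row.end, True)
        return index
    if chrom_lengths is None:
        chrom_lengths = {}
        for feat in db.all_features():
            chrom_lengths[feat.seqid] = max(chrom_lengths.get(feat.seqid, 0), feat.end)
    index = RegionIndex(chrom_lengths)

    genes = list(db.features_of_type("gene"))
    for gene in genes:
        if gene.seqid not in index.category:
            continue
        _paint(index.category[gene.seqid], gene.start - 1, gene.end, CAT_INTRON)
    for ftype in ("five_prime_UTR", "three_prime_UTR", "UTR"):
        for feat in db.features_of_type(ftype):
            if feat.seqid in index.category:
                _paint(index.category[feat.seqid], feat.start - 1, feat.end, CAT_UTR)
    for feat in db.features_of_type("CDS"):
        if feat.seqid in index.category:
            _paint(index.category[feat.seqid], feat.start - 1, feat.end, CAT_CDS)

    tss_acc: dict[str, list] = {}
    for gene in genes:
        tss = gene.start - 1 if gene.strand == "+" else gene.end - 1
        tss_acc.setdefault(gene.seqid, []).append((tss, gene.id))
    for chrom, items in tss_acc.items():
        pos = np.array([p for p, _ in items])
        ids = [g for _, g in items]
        index.set_tss(chrom, pos, ids)

    if cds_fasta is not None:
        cds_seqs = wio.read_fasta(cds_fasta)
        for gene in genes:
            seq = cds_seqs.get(gene.id)
            if seq is None:
                continue
            parts = sorted(
                db.children(gene, featuretype="CDS"), key=lambda f: f.start
            )
            if not parts:
                continue
            codes = classify_degeneracy(seq)
            genomic = np.concatenate(
                [np.arange(p.start - 1, p.end) for p in parts]
            )
            if gene.strand == "-":
                genomic = genomic[::-1]
            if genomic.size != codes.size:
                logger.warning(
                    "CDS length mismatch for %s (%d vs %d); degeneracy skipped",
                    gene.id, genomic.size, codes.size,
                )
                continue
            index.degeneracy[gene.seqid][genomic] = codes

    if repeats_bed is not None:
        for row in wio.read_bed(repeats_bed).itertuples(index=False):
            if row.chrom in index.repeat:
                _paint(index.repeat[row.chrom], row.start, row.end, True)
    if peaks_bed is not None:
        for row in wio.read_bed(peaks_bed).itertuples(index=False):
            if row.chrom in index.peak:
                _paint(index.peak[row.chrom], row.start, row.end, True)
    return index


def filter_variants(
    records: Iterable[VariantRecord],
    region_index: RegionIndex,
    depth_bounds: tuple[float, float] = (4.0, 16.0),
    require_complete: bool = True,
) -> list[VariantRecord]:
    """Apply the post-calling SNP filters.

    Removes multiallelic sites, repeat-overlapping sites, sites whose mean
    depth falls below/above the bounds (boundary values retained), and —
    when ``require_complete`` — sites with any missing genotype.  Sites
    without a depth annotation are dropped with a warning.
    """
    lo, hi = depth_bounds
    kept = []
    for rec in records:
        if len(rec.alts) != 1:
            continue
        if rec.chrom in region_index.repeat and region_index.repeat[rec.chrom][rec.pos]:
            continue
        if rec.mean_depth is None or np.isnan(rec.mean_depth):
            logger.warning("site %s:%d lacks depth annotation; dropped", rec.chrom, rec.pos + 1)
            continue
        if rec.mean_depth < lo or rec.mean_depth > hi:
            continue
        if require_complete and rec.has_missing:
            continue
        kept.append(rec)
    return kept


def annotate_sites(records: Iterable[VariantRecord], region_index: RegionIndex) -> list[SiteRecord]:
    """Attach category, peak flag, degeneracy, and nearest-gene id to sites.

    Records on contigs absent from the index are skipped (and counted in a
    log message).  Polarization fields pass through when present.
    """
    out = []
    skipped = 0
    for rec in records:
        if rec.chrom not in region_index.category:
            skipped += 1
            continue
        pos = rec.pos
        deg = int(region_index.degeneracy[rec.chrom][pos])
        out.append(
            SiteRecord(
                chrom=rec.chrom,
                pos=pos,
                ref=rec.ref,
                alt=rec.alt,
                derived_count=rec.derived_count,
                category=region_index.category_name(rec.chrom, pos),
                peak=bool(region_index.peak[rec.chrom][pos]),
                degeneracy=deg if deg >= 0 else None,
                gene_id=region_index.nearest_gene(rec.chrom, pos),
            )
        )
    if skipped:
        logger.info("skipped %d records on contigs absent from the index", skipped)
    return out


def count_callable(
    callable_mask: Mapping[str, np.ndarray],
    region_index: RegionIndex,
    category: str,
    peak: bool | None = None,
) -> int:
    """Number of callable positions in a category (optionally within/outside peaks)."""
    total = 0
    for chrom, mask in callable_mask.items():
        if chrom not in region_index.category:
            continue
        sel = mask & region_index.category_mask(chrom, category)
        if peak is True:
            sel &= region_index.peak[chrom]
        elif peak is False:
            sel &= ~region_index.peak[chrom]
        total += int(sel.sum())
    return total


def site_matches(site: SiteRecord, category: str, peak: bool | None = None) -> bool:
    """Does an annotated site belong to a category selector (as count_callable)?"""
    if peak is True and not site.peak:
        return False
    if peak is False and site.peak:
        return False
    if category == "all":
        return True
    if category == "0fold":
        return site.category == "cds" and site.degeneracy == 0
    if category == "4fold":
        return site.category == "cds" and site.degeneracy == 4
    return site.category == category
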