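"""Ancestral-allele assignment at biallelic SNPs by three-taxon parsimony.

The rule is strict: an allele is called ancestral only when the aligned
bases of both outgroups (brown trout and Arctic charr) agree with each
other AND match one of the two salmon alleles.  Anything else — outgroup
disagreement, a third state, a gap or N — leaves the site unresolved, and
unresolved sites are excluded from unfolded-SFS construction.  Residual
mis-polarization is absorbed downstream by the DFE model's epsilon
parameter rather than by a majority fallback here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

__all__ = ["OutgroupColumn", "infer_ancestral", "polarization_rate", "polarize_records"]

_BASES = {"A", "C", "G", "T"}


@dataclass(frozen=True)
class OutgroupColumn:
    """Salmon ref/alt plus the aligned outgroup bases at one SNP."""

    ref: str
    alt: str
    trout: str
    charr: str

    def __post_init__(self):
        if self.ref == self.alt or self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError("salmon alleles must be two distinct bases")


def infer_ancestral(column: OutgroupColumn) -> str | None:
    """Return the ancestral allele, or None when parsimony cannot resolve it."""
    t, c = column.trout.upper(), column.charr.upper()
    if t not in _BASES or c not in _BASES:
        return None
    if t != c:
        return None
    if t not in (column.ref, column.alt):
        return None
    return t


def polarization_rate(columns: Iterable[OutgroupColumn]) -> float:
    """Fraction of columns the parsimony rule resolves."""
    total = resolved = 0
    for col in columns:
        total += 1
        if infer_ancestral(col) is not None:
            resolved += 1
    if total == 0:
        raise ValueError("need at least one column")
    return resolved / total


def polarize_records(records: list, outgroups: pd.DataFrame) -> list:
    """Attach ancestral alleles and derived counts to variant records.

    ``outgroups`` is the per-SNP table (chrom, pos, trout_base, charr_base)
    produced by an upstream whole-genome alignment; ``records`` carry
    ref/alt and ref/alt allele counts.  Returns the resolved subset with
    ``ancestral`` and ``derived_count`` filled in; unresolved sites drop out.
    """
    table = {
        (row.chrom, int(row.pos)): (row.trout_base, row.charr_base)
        for row in outgroups.itertuples(index=False)
    }
    kept = []
    for rec in records:
        bases = table.get((rec.chrom, rec.pos))
        if bases is None:
            continue
        anc = infer_ancestral(OutgroupColumn(rec.ref, rec.alt, bases[0], bases[1]))
        if anc is None:
            continue
        rec.ancestral = anc
        rec.derived_count = rec.alt_count if anc == rec.ref else rec.ref_count
        kept.append(rec)
    return kept
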