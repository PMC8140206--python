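"""Unfolded site frequency spectra and classic diversity statistics.

The SFS container holds the derived-allele-count spectrum x_1..x_{n-1} for a
site category together with the number of callable sites L (positions that
passed the same filters as the variants), which normalizes per-site
diversity.  pi follows Nei & Li (1979) and Tajima's D follows Tajima (1989),
both computed from the spectrum; with complete genotypes these equal the
genotype-matrix definitions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

__all__ = ["SFS", "build_sfs", "nucleotide_diversity", "tajimas_d", "watterson_theta"]


@dataclass
class SFS:
    """Unfolded (or folded) derived-allele-count spectrum.

    n : sampled chromosomes (>= 4).
    x : counts at derived frequencies 1..n-1 (unfolded), or minor-allele
        frequencies 1..floor(n/2) when folded.
    L : callable sites, L >= sum(x).
    """

    n: int
    x: np.ndarray
    L: float
    category: str = ""
    folded: bool = False

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        if self.n < 4:
            raise ValueError("sample size n must be >= 4")
        expected = self.n // 2 if self.folded else self.n - 1
        if self.x.size != expected:
            raise ValueError(f"spectrum length {self.x.size} != {expected}")
        if np.any(self.x < 0):
            raise ValueError("spectrum counts must be >= 0")
        if self.L < self.segregating_sites:
            raise ValueError("callable sites L must be >= number of segregating sites")

    @property
    def segregating_sites(self) -> float:
        return float(self.x.sum())

    def fold(self) -> "SFS":
        """Collapse derived classes i and n-i onto minor-allele classes."""
        if self.folded:
            return self
        n = self.n
        y = np.array(
            [
                self.x[i - 1] if 2 * i == n else self.x[i - 1] + self.x[n - i - 1]
                for i in range(1, n // 2 + 1)
            ]
        )
        return SFS(self.n, y, self.L, self.category, folded=True)


def build_sfs(site_records: Iterable, n: int, L: float, category: str | None = None) -> SFS:
    """Count polarized sites into an unfolded SFS.

    Records must carry ``derived_count`` in [1, n-1]; records with an
    unresolved ancestral state (derived_count None) are rejected here —
    filter them out upstream.  ``category`` only labels the result; callers
    pre-select the records.
    """
    x = np.zeros(n - 1)
    for rec in site_records:
        i = rec.derived_count
        if i is None or not (1 <= i <= n - 1):
            raise ValueError(f"derived count {i!r} outside [1, {n - 1}]")
        x[i - 1] += 1
    return SFS(n=n, x=x, L=L, category=category or "")


def nucleotide_diversity(sfs: SFS) -> float:
    """Per-site pi: mean pairwise difference over callable sites.

    pi = sum_i i (n - i) x_i / (C(n, 2) L); fold-invariant because the
    weight i (n - i) is symmetric in i <-> n - i.
    """
    if sfs.L <= 0:
        raise ValueError("pi undefined for L = 0")
    n = sfs.n
    if sfs.folded:
        iarr = np.arange(1, n // 2 + 1)
    else:
        iarr = np.arange(1, n)
    num = float(np.sum(iarr * (n - iarr) * sfs.x))
    return num / (n * (n - 1) / 2.0 * sfs.L)


def _pi_total(sfs: SFS) -> float:
    """Sum of per-site heterozygosities (pi not normalized by L)."""
    n = sfs.n
    iarr = np.arange(1, n // 2 + 1) if sfs.folded else np.arange(1, n)
    return float(np.sum(iarr * (n - iarr) * sfs.x)) / (n * (n - 1) / 2.0)


def watterson_theta(sfs: SFS) -> float:
    a1 = np.sum(1.0 / np.arange(1, sfs.n))
    return sfs.segregating_sites / a1 / sfs.L


def tajimas_d(sfs: SFS) -> float:
    """Tajima's D with the standard 1989 constants; NaN when S == 0."""
    n = sfs.n
    S = sfs.segregating_sites
    if S == 0:
        return float("nan")
    a1 = np.sum(1.0 / np.arange(1, n))
    a2 = np.sum(1.0 / np.arange(1, n) ** 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return (_pi_total(sfs) - S / a1) / np.sqrt(var)
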