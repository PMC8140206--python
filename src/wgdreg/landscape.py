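"""Peak-to-gene assignment and post-WGD regulatory divergence statistics.

Peaks (H3K27ac-enriched intervals) are assigned to the gene with the
nearest TSS by peak-center distance and classified as promoter peaks when
the center falls in the strand-aware window [-1000, +100] bp around the
TSS (closed on both ends), otherwise proximal.  Downstream statistics
compare peak counts and expression between ohnolog gene pairs, and peak
densities (peaks per 100 kb) between homeoblock interval pairs, including
the contrast between blocks that reploidized before vs after a 40 Ma age
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PROMOTER_WINDOW",
    "assign_peaks",
    "peak_expression_association",
    "ohnolog_divergence",
    "homeoblock_divergence",
]

PROMOTER_WINDOW = (-1000, 100)  # strand-aware bp around the TSS, closed


def assign_peaks(
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    promoter_window: tuple[int, int] = PROMOTER_WINDOW,
) -> pd.DataFrame:
    """Assign each peak to the gene with the nearest TSS.

    peaks: chrom, start, end, name (BED convention).
    genes: gene_id, chrom, tss, strand.

    Returns one row per assignable peak: peak id, center, gene_id, signed
    strand-aware distance to the TSS (negative = upstream), and class
    ('promoter' within the window, else 'proximal').  Peaks on contigs
    without genes are dropped; their count is in the DataFrame attrs.
    """
    rows = []
    unassigned = 0
    by_chrom = {
        chrom: sub.sort_values(["tss", "gene_id"], kind="stable").reset_index(drop=True)
        for chrom, sub in genes.groupby("chrom")
    }
    lo, hi = promoter_window
    for peak in peaks.itertuples(index=False):
        sub = by_chrom.get(peak.chrom)
        if sub is None or len(sub) == 0:
            unassigned += 1
            continue
        center = (int(peak.start) + int(peak.end)) // 2
        dist = np.abs(sub["tss"].to_numpy() - center)
        best = np.flatnonzero(dist == dist.min())
        # equidistant ties: lexicographically smaller gene id
        gene = sub.iloc[min(best, key=lambda j: str(sub["gene_id"].iloc[j]))]
        signed = center - int(gene.tss) if gene.strand == "+" else int(gene.tss) - center
        rows.append(
            {
                "peak_id": getattr(peak, "name", None),
                "chrom": peak.chrom,
                "center": center,
                "gene_id": gene.gene_id,
                "distance": signed,
                "peak_class": "promoter" if lo <= signed <= hi else "proximal",
            }
        )
    out = pd.DataFrame(
        rows, columns=["peak_id", "chrom", "center", "gene_id", "distance", "peak_class"]
    )
    out.attrs["n_unassigned"] = unassigned
    return out


def _peak_counts(assignments: pd.DataFrame, gene_ids: pd.Series) -> pd.DataFrame:
    counts = (
        assignments.groupby(["gene_id", "peak_class"]).size().unstack(fill_value=0)
        if len(assignments)
        else pd.DataFrame()
    )
    out = pd.DataFrame(index=pd.Index(gene_ids, name="gene_id"))
    for cls in ("promoter", "proximal"):
        out[cls] = counts[cls].reindex(out.index).fillna(0).astype(int) if cls in counts else 0
    return out


def _association(x: np.ndarray, y: np.ndarray) -> dict:
    """Spearman rho plus least-squares slope/p; NaN when a side is constant."""
    if len(x) < 3 or np.all(x == x[0]) or np.all(y == y[0]):
        return {"rho": np.nan, "rho_p": np.nan, "slope": np.nan, "slope_p": np.nan}
    rho, rho_p = stats.spearmanr(x, y)
    lr = stats.linregress(x, y)
    return {"rho": float(rho), "rho_p": float(rho_p), "slope": float(lr.slope), "slope_p": float(lr.pvalue)}


def peak_expression_association(
    assignments: pd.DataFrame, expression: pd.DataFrame
) -> dict[str, dict]:
    """Association of per-gene peak counts with expression level.

    expression: gene_id, expr.  Genes without assigned peaks count as 0.
    Returns {'promoter': {...}, 'proximal': {...}} with Spearman rho and a
    linear-trend slope/p each.
    """
    if len(expression) < 3:
        raise ValueError("need at least 3 genes")
    counts = _peak_counts(assignments, expression["gene_id"])
    expr = expression.set_index("gene_id")["expr"].reindex(counts.index).to_numpy(float)
    return {
        cls: _association(counts[cls].to_numpy(float), expr)
        for cls in ("promoter", "proximal")
    }


def ohnolog_divergence(pairs: pd.DataFrame, assignments: pd.DataFrame) -> pd.DataFrame:
    """Per-ohnolog-pair peak-count and expression divergence, with trends.

    pairs: gene1, gene2, expr1, expr2 (normalized mean expression).
    Divergence measures: |delta peaks| per class and
    |log2(e1 + 1) - log2(e2 + 1)| for expression.  Pairs with missing
    expression are dropped (count in attrs).  Trend tests of expression
    divergence on peak-count divergence are in attrs['trend'].
    """
    pairs = pairs.copy()
    n_before = len(pairs)
    pairs = pairs.dropna(subset=["expr1", "expr2"])
    all_genes = pd.unique(pd.concat([pairs["gene1"], pairs["gene2"]]))
    counts = _peak_counts(assignments, pd.Series(all_genes))
    rows = []
    for p in pairs.itertuples(index=False):
        c1, c2 = counts.loc[p.gene1], counts.loc[p.gene2]
        rows.append(
            {
                "gene1": p.gene1,
                "gene2": p.gene2,
                "d_promoter": abs(int(c1["promoter"]) - int(c2["promoter"])),
                "d_proximal": abs(int(c1["proximal"]) - int(c2["proximal"])),
                "d_expr": abs(np.log2(p.expr1 + 1.0) - np.log2(p.expr2 + 1.0)),
            }
        )
    out = pd.DataFrame(rows, columns=["gene1", "gene2", "d_promoter", "d_proximal", "d_expr"])
    out.attrs["n_dropped"] = n_before - len(pairs)
    out.attrs["trend"] = {
        cls: _association(out[f"d_{cls}"].to_numpy(float), out["d_expr"].to_numpy(float))
        if len(out)
        else _association(np.array([]), np.array([]))
        for cls in ("promoter", "proximal")
    }
    return out


@dataclass
class HomeoblockContrast:
    divergence: pd.DataFrame  # per block pair
    young_median: float
    old_median: float
    rank_sum_p: float
    length_rho: float
    length_rho_p: float


def homeoblock_divergence(
    pairs: pd.DataFrame,
    peaks: pd.DataFrame | None = None,
    age_threshold: float = 40.0,
) -> HomeoblockContrast:
    """Peak-density divergence between duplicated genome blocks.

    pairs: block_id, chrom1, start1, end1, chrom2, start2, end2, age_ma,
    plus optional precomputed p1/p2 peak counts (otherwise counted from
    ``peaks`` by center overlap).  Densities are peaks per 100 kb of block
    length; divergence is |d1 - d2| and the 1:1-line residual
    (d1 - d2)/sqrt(2).  Blocks younger than ``age_threshold`` (still
    polyploid more recently) are contrasted against older blocks with a
    Wilcoxon rank-sum test, and divergence is correlated (Spearman) with
    min(L1, L2).
    """
    df = pairs.copy()
    if "p1" not in df.columns or "p2" not in df.columns:
        if peaks is None:
            raise ValueError("peak counts p1/p2 absent and no peaks table given")
        centers = ((peaks["start"] + peaks["end"]) // 2).to_numpy()
        chroms = peaks["chrom"].to_numpy()

        def count_in(chrom, start, end):
            return int(np.sum((chroms == chrom) & (centers >= start) & (centers < end)))

        df["p1"] = [count_in(r.chrom1, r.start1, r.end1) for r in df.itertuples(index=False)]
        df["p2"] = [count_in(r.chrom2, r.start2, r.end2) for r in df.itertuples(index=False)]

    df["L1"] = df["end1"] - df["start1"]
    df["L2"] = df["end2"] - df["start2"]
    if np.any(df["L1"] <= 0) or np.any(df["L2"] <= 0):
        raise ValueError("block lengths must be > 0")
    df["d1"] = df["p1"] / (df["L1"] / 1e5)
    df["d2"] = df["p2"] / (df["L2"] / 1e5)
    df["divergence"] = np.abs(df["d1"] - df["d2"])
    df["residual"] = (df["d1"] - df["d2"]) / np.sqrt(2.0)

    young = df.loc[df["age_ma"] < age_threshold, "divergence"]
    old = df.loc[df["age_ma"] >= age_threshold, "divergence"]
    if len(young) >= 2 and len(old) >= 2:
        p = float(stats.mannwhitneyu(young, old, alternative="two-sided").pvalue)
        ym, om = float(young.median()), float(old.median())
    else:
        p, ym, om = np.nan, np.nan, np.nan

    min_len = np.minimum(df["L1"], df["L2"]).to_numpy(float)
    div = df["divergence"].to_numpy(float)
    if len(df) >= 3 and np.ptp(min_len) > 0 and np.ptp(div) > 0:
        rho, rho_p = stats.spearmanr(min_len, div)
    else:
        rho, rho_p = np.nan, np.nan
    return HomeoblockContrast(df, ym, om, p, float(rho), float(rho_p))
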