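"""Readers and writers for the plain-text formats the pipeline exchanges.

Internal coordinates are 0-based half-open everywhere; conversion to the
1-based closed convention of GFF3/VCF happens only in this module.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BED_COLUMNS = ["chrom", "start", "end", "name"]


def read_bed(path: str) -> pd.DataFrame:
    """Read a BED3/BED4+ file into a DataFrame (0-based half-open, as BED)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    ncol = min(df.shape[1], 4)
    df = df.iloc[:, :ncol]
    df.columns = BED_COLUMNS[:ncol]
    if "name" not in df.columns:
        df["name"] = [f"feature_{k}" for k in range(len(df))]
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_bed(df: pd.DataFrame, path: str) -> None:
    cols = [c for c in BED_COLUMNS if c in df.columns]
    df.to_csv(path, sep="\t", header=False, index=False, columns=cols)


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, path, "fasta")


def write_gff3(features: Iterable[tuple], path: str) -> None:
    """Write GFF3 from tuples (chrom, source, type, start0, end0, strand, attrs).

    start0/end0 are 0-based half-open and converted to GFF3 1-based closed.
    attrs is a dict written in the given insertion order.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, source, ftype, start, end, strand, attrs in features:
            attr_s = ";".join(f"{k}={v}" for k, v in attrs.items())
            fh.write(
                f"{chrom}\t{source}\t{ftype}\t{start + 1}\t{end}\t.\t{strand}\t.\t{attr_s}\n"
            )


def write_vcf(
    variants: pd.DataFrame,
    genotypes: np.ndarray,
    depths: np.ndarray,
    sample_names: list[str],
    path: str,
    contigs: Mapping[str, int] | None = None,
) -> None:
    """Write a minimal VCF v4.2 with GT and DP per sample.

    variants: DataFrame with chrom, pos (0-based), ref, alt.
    genotypes: (n_sites, 2 * n_samples) allele codes (0 ref / 1 alt / -1 missing).
    depths: (n_sites, n_samples) integer per-sample depths.
    """
    n_samples = len(sample_names)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contigs:
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_names)
            + "\n"
        )
        for k, row in enumerate(variants.itertuples(index=False)):
            fields = [
                row.chrom,
                str(row.pos + 1),
                ".",
                row.ref,
                row.alt,
                ".",
                "PASS",
                ".",
                "GT:DP",
            ]
            for s in range(n_samples):
                a, b = genotypes[k, 2 * s], genotypes[k, 2 * s + 1]
                gt = "./." if a < 0 or b < 0 else f"{a}/{b}"
                fields.append(f"{gt}:{int(depths[k, s])}")
            fh.write("\t".join(fields) + "\n")


def write_sfs(path: str, x: np.ndarray, n: int, L: float, category: str = "") -> None:
    """Serialize an unfolded SFS as a single count line with an n/L header."""
    with open(path, "w") as fh:
        fh.write(f"#n={n}\tL={L:.6g}\tcategory={category}\n")
        fh.write("\t".join(str(int(v)) for v in x) + "\n")


def read_sfs(path: str) -> tuple[np.ndarray, int, float, str]:
    with open(path) as fh:
        header = fh.readline().lstrip("#").strip()
        counts = fh.readline().split()
    meta = dict(item.split("=", 1) for item in header.split("\t"))
    x = np.array([int(v) for v in counts])
    return x, int(meta["n"]), float(meta["L"]), meta.get("category", "")


def write_tsv(df: pd.DataFrame, path: str) -> None:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
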