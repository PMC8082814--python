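"""Plain-text readers and writers for the pipeline's interchange formats.

Everything is tab-separated text: dosage matrices, a minimal VCF with a DS
(dosage) FORMAT field, feature x sample phenotype tables, GWAS summary
statistics, LeafCutter-dialect junction counts, and BED intervals (intron
coordinates are 1-based inclusive internally and converted to 0-based
half-open on BED export).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .preprocess import Intron
from .sim import GenotypeMatrix

__all__ = [
    "write_dosage_tsv",
    "read_dosage_tsv",
    "write_vcf",
    "write_phenotypes",
    "read_phenotypes",
    "write_gwas_tsv",
    "read_gwas_tsv",
    "read_junction_counts",
    "write_junction_counts",
    "introns_to_bed",
    "read_bed",
]

GWAS_COLUMNS = ["variant_id", "chrom", "pos", "ref", "alt", "beta", "se", "p", "n"]


def write_dosage_tsv(G: GenotypeMatrix, path: str) -> None:
    df = pd.concat(
        [
            G.variants.reset_index(drop=True),
            pd.DataFrame(G.dosages.T, columns=G.samples),
        ],
        axis=1,
    )
    df.to_csv(path, sep="\t", index=False)


def read_dosage_tsv(path: str) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta_cols = ["variant_id", "chrom", "pos", "ref", "alt", "maf"]
    samples = [c for c in df.columns if c not in meta_cols]
    return GenotypeMatrix(
        dosages=df[samples].values.T,
        variants=df[meta_cols].copy(),
        samples=samples,
    )


def write_vcf(G: GenotypeMatrix, path: str) -> None:
    """Minimal VCF 4.2 with a DS FORMAT field."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alt allele dosage">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.samples)
            + "\n"
        )
        for j, row in G.variants.iterrows():
            ds = "\t".join(
                "." if np.isnan(x) else f"{x:g}" for x in G.dosages[:, j]
            )
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['variant_id']}\t"
                f"{row['ref']}\t{row['alt']}\t.\tPASS\t.\tDS\t{ds}\n"
            )


def write_phenotypes(Y: pd.DataFrame, path: str) -> None:
    Y.to_csv(path, sep="\t", index_label="feature")


def read_phenotypes(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="feature")


def write_gwas_tsv(gwas: pd.DataFrame, path: str) -> None:
    gwas[GWAS_COLUMNS].to_csv(path, sep="\t", index=False)


def read_gwas_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def read_junction_counts(path: str) -> pd.DataFrame:
    """LeafCutter-dialect table: chrom:start:end:cluster rows x samples."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_junction_counts(counts: pd.DataFrame, path: str) -> None:
    counts.to_csv(path, sep="\t", index_label="junction")


def introns_to_bed(introns: list[Intron], path: str) -> None:
    """Export introns as BED (0-based half-open) intervals."""
    with open(path, "w") as fh:
        for i in introns:
            fh.write(f"{i.chrom}\t{i.start - 1}\t{i.end}\t.\t0\t{i.strand}\n")


def read_bed(path: str) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", dtype={0: str}
    ).iloc[:, :3]
    df.columns = ["chrom", "start", "end"]
    return df
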