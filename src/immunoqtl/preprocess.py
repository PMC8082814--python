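"""Genotype QC, expression normalization, and intron-cluster harmonization.

Variant filters follow standard QTL-study practice: drop variants with
missingness above 5%, minor allele frequency below 5%, or an exact
Hardy-Weinberg test p-value below 1e-5, in that order.  Expression is
normalized per feature with a rank-based inverse-normal transform after an
optional per-sample library-size scaling.  Intron clusters quantified
separately per dataset are merged by shared splice sites (connected
components) and usage is recomputed against the merged cluster totals, so
splicing phenotypes are comparable across datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .sim import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "hwe_exact_p",
    "filter_variants",
    "impute_missing_dosages",
    "normalize_expression",
    "inverse_normal_transform",
    "Intron",
    "IntronCluster",
    "parse_junction_index",
    "clusters_from_counts",
    "merge_intron_clusters",
    "intron_usage",
]


def hwe_exact_p(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Enumerates all heterozygote counts compatible with the observed allele
    counts and sums the probabilities of configurations no more likely
    than the observed one (the standard exact HWE test).
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n == 0:
        return 1.0
    n_a = 2 * n_aa + n_ab  # copies of allele a
    rare = min(n_a, 2 * n - n_a)
    # heterozygote counts share the parity of the rare-allele count
    het_values = np.arange(rare % 2, rare + 1, 2)

    # unnormalized log-probabilities of each heterozygote count
    logp = []
    for h in het_values:
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        logp.append(
            h * np.log(2.0)
            - gammaln(h + 1)
            - gammaln(hom_r + 1)
            - gammaln(hom_c + 1)
        )
    logp = np.array(logp)
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs_het = n_ab
    obs_p = probs[het_values == obs_het]
    if len(obs_p) == 0:
        raise ValueError(
            f"heterozygote count {n_ab} incompatible with allele counts"
        )
    # tolerance guards against ties lost to floating point
    return float(min(1.0, probs[probs <= obs_p[0] * (1 + 1e-12)].sum()))


def filter_variants(
    G: GenotypeMatrix,
    maf_min: float = 0.05,
    hwe_p_min: float = 1e-5,
    miss_max: float = 0.05,
) -> GenotypeMatrix:
    """Apply missingness, MAF, and exact-HWE filters, in that order.

    HWE is evaluated on hard calls (dosages rounded to the nearest
    genotype).  An empty result is a warning, not an error.
    """
    X = G.dosages
    keep = G.missingness() <= miss_max
    keep &= G.empirical_maf() >= maf_min

    hard = np.round(X)
    for v in np.flatnonzero(keep):
        g = hard[:, v]
        g = g[~np.isnan(g)]
        n_bb = int((g == 0).sum())
        n_ab = int((g == 1).sum())
        n_aa = int((g == 2).sum())
        if hwe_exact_p(n_aa, n_ab, n_bb) < hwe_p_min:
            keep[v] = False

    if not keep.any():
        logger.warning("all %d variants removed by QC filters", G.n_variants)
    return G.subset_variants(keep)


def impute_missing_dosages(G: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing dosages with the per-variant mean (for regression)."""
    X = G.dosages.copy()
    col_mean = np.nanmean(X, axis=0)
    nan_rows, nan_cols = np.nonzero(np.isnan(X))
    X[nan_rows, nan_cols] = col_mean[nan_cols]
    return GenotypeMatrix(X, G.variants.copy(), list(G.samples))


def inverse_normal_transform(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform with offset (rank - 0.5)/n.

    Ties receive average ranks.  A constant vector maps to all zeros.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    if np.all(v == v[0]):
        return np.zeros(n)
    ranks = stats.rankdata(v, method="average")
    return stats.norm.ppf((ranks - 0.5) / n)


def normalize_expression(
    tpm: pd.DataFrame, *, library_scale: bool = True
) -> pd.DataFrame:
    """Scale samples then quantile-normalize each feature to a normal.

    ``library_scale`` rescales each sample column to a common total
    (guarding against residual depth effects after TPM); each feature row
    is then mapped through the rank-based inverse-normal transform, giving
    per-feature mean ~0 and variance ~1.  Constant features come out as
    all-zero rows with a logged warning.
    """
    if (tpm.values < 0).any():
        raise ValueError("TPM values must be non-negative")
    X = tpm.values.astype(float)
    if library_scale:
        totals = X.sum(axis=0)
        totals = np.where(totals > 0, totals, 1.0)
        X = X / totals * np.median(totals)
    out = np.empty_like(X)
    n_const = 0
    for i in range(X.shape[0]):
        if np.all(X[i] == X[i, 0]):
            out[i] = 0.0
            n_const += 1
        else:
            out[i] = inverse_normal_transform(X[i])
    if n_const:
        logger.warning("%d constant features set to all-zero rows", n_const)
    return pd.DataFrame(out, index=tpm.index, columns=tpm.columns)


# ---------------------------------------------------------------------------
# intron clusters


@dataclass(frozen=True)
class Intron:
    """One intron, 1-based inclusive coordinates."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    @property
    def donor(self) -> tuple[str, int]:
        return (self.chrom, self.start)

    @property
    def acceptor(self) -> tuple[str, int]:
        return (self.chrom, self.end)


@dataclass
class IntronCluster:
    cluster_id: str
    members: list[Intron]
    counts: pd.DataFrame  # introns (row per member, same order) x samples


def parse_junction_index(idx: str) -> tuple[Intron, str]:
    """Parse a ``chrom:start:end:cluster`` junction row label."""
    parts = idx.split(":")
    if len(parts) < 4:
        raise ValueError(f"malformed junction id {idx!r}")
    chrom, start, end = parts[0], int(parts[1]), int(parts[2])
    cluster = ":".join(parts[3:])
    strand = "+"
    if cluster.endswith(("_+", "_-")):
        strand = cluster[-1]
        cluster = cluster[:-2]
    return Intron(chrom, start, end, strand), cluster


def clusters_from_counts(counts: pd.DataFrame) -> list[IntronCluster]:
    """Group a junction-count table into per-cluster objects."""
    groups: dict[str, list[tuple[Intron, str]]] = {}
    for idx in counts.index:
        intron, cid = parse_junction_index(idx)
        groups.setdefault(cid, []).append((intron, idx))
    out = []
    for cid, pairs in groups.items():
        members = [p[0] for p in pairs]
        rows = [p[1] for p in pairs]
        out.append(IntronCluster(cid, members, counts.loc[rows]))
    return out


class _UnionFind:
    def __init__(self):
        self.parent: dict = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def merge_intron_clusters(
    cluster_sets: list[list[IntronCluster]],
) -> tuple[list[IntronCluster], pd.DataFrame]:
    """Union clusters across datasets by shared splice sites; recompute usage.

    Clusters whose introns share a donor or acceptor coordinate are merged
    into one (connected components over splice-site keys).  Junction
    counts are outer-joined over samples (absent = 0 reads), summed for
    introns observed in several datasets, and usage is recomputed as
    intron count divided by the merged-cluster total per sample.

    An intron whose strand conflicts with an already-recorded strand at a
    shared splice site is rejected and logged.

    Returns (merged clusters, usage DataFrame indexed like the counts).
    """
    uf = _UnionFind()
    site_strand: dict[tuple[str, int], str] = {}
    intron_counts: dict[Intron, pd.Series] = {}
    rejected = 0

    for dataset in cluster_sets:
        for cl in dataset:
            for intron, (_, row) in zip(cl.members, cl.counts.iterrows()):
                conflict = False
                for site in (intron.donor, intron.acceptor):
                    if site in site_strand and site_strand[site] != intron.strand:
                        conflict = True
                if conflict:
                    rejected += 1
                    logger.warning(
                        "rejected intron %s:%d-%d(%s): strand conflict at a "
                        "shared splice site",
                        intron.chrom, intron.start, intron.end, intron.strand,
                    )
                    continue
                for site in (intron.donor, intron.acceptor):
                    site_strand.setdefault(site, intron.strand)
                uf.union(("site", *intron.donor), ("site", *intron.acceptor))
                if intron in intron_counts:
                    intron_counts[intron] = intron_counts[intron].add(
                        row, fill_value=0
                    )
                else:
                    intron_counts[intron] = row.astype(float)

    groups: dict = {}
    for intron in intron_counts:
        groups.setdefault(uf.find(("site", *intron.donor)), []).append(intron)

    all_samples = sorted(
        {s for series in intron_counts.values() for s in series.index}
    )
    merged: list[IntronCluster] = []
    usage_rows, usage_index = [], []
    for k, (_, members) in enumerate(
        sorted(groups.items(), key=lambda kv: (kv[1][0].chrom, kv[1][0].start))
    ):
        members = sorted(members, key=lambda i: (i.chrom, i.start, i.end))
        cid = f"merged_{k}"
        mat = pd.DataFrame(
            [intron_counts[i].reindex(all_samples).fillna(0.0) for i in members],
            index=[f"{i.chrom}:{i.start}:{i.end}:{cid}" for i in members],
        )
        totals = mat.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            usage = mat.div(totals.where(totals > 0), axis=1)
        merged.append(IntronCluster(cid, members, mat))
        usage_rows.append(usage)
        usage_index.extend(mat.index)

    usage_df = (
        pd.concat(usage_rows) if usage_rows else pd.DataFrame(columns=all_samples)
    )
    return merged, usage_df


def intron_usage(counts: pd.DataFrame) -> pd.DataFrame:
    """Within-cluster usage fractions for a junction-count table."""
    cluster_ids = [parse_junction_index(i)[1] for i in counts.index]
    totals = counts.groupby(cluster_ids).transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        return counts / totals.where(totals > 0)
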