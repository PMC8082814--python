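"""GWAS locus definition and Bayesian colocalization with regulatory QTLs.

Loci are defined by greedy clumping of GWAS summary statistics: repeatedly
take the remaining variant with the smallest p-value as a lead, remove all
variants within 500 kb on either side (a 1 Mb locus), and stop when no
variant below the significance threshold (default 1e-7) remains.  Leads
falling in configured exclusion regions (default the HLA band,
chr6:25-35 Mb) are dropped with a recorded reason.

Colocalization follows the standard single-causal-variant framework: each
variant's association in each trait is summarized by a Wakefield
approximate Bayes factor (ABF)

    log ABF = 0.5 log(se^2 / (se^2 + W^2)) + 0.5 z^2 W^2 / (se^2 + W^2),

and the five hypotheses (no association; GWAS only; QTL only; two distinct
causal variants; one shared causal variant) are scored by summing ABFs
over causal configurations with per-variant priors p1, p2, p12.  All sums
use log-sum-exp.  A locus is called colocalized when any tested feature
reaches PP4 above the threshold (default 0.75).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

__all__ = [
    "Locus",
    "ColocPriors",
    "ColocResult",
    "define_loci",
    "ascertain_features",
    "wakefield_log_abf",
    "coloc_posteriors",
    "harmonize_stats",
    "colocalization_rate",
]

HLA_REGION = ("6", 25_000_000, 35_000_000)


@dataclass
class Locus:
    trait: str
    lead_variant: str
    chrom: str
    pos: int
    p: float
    window: tuple[int, int]
    member_variants: list[str] = field(default_factory=list)
    excluded: bool = False
    reason: str = ""

    @property
    def locus_id(self) -> str:
        return f"{self.trait}:{self.lead_variant}"


@dataclass
class ColocPriors:
    """Per-variant causal priors and ABF prior effect scales."""

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    W_gwas: float = 0.15
    W_qtl: float = 0.15

    def __post_init__(self):
        if min(self.p1, self.p2) <= 0 or self.p12 < 0:
            raise ValueError("p1 and p2 must be positive, p12 non-negative")
        if self.p1 + self.p2 + self.p12 > 0.1:
            raise ValueError("priors imply implausibly dense causal variants")


@dataclass
class ColocResult:
    locus_id: str
    feature: str
    modality: str  # "expression" or "splicing"
    pp: np.ndarray  # PP0..PP4
    top_variant: str
    n_variants: int

    @property
    def pp4(self) -> float:
        return float(self.pp[4])


def _normalize_chrom(c: str) -> str:
    return str(c).removeprefix("chr")


def define_loci(
    gwas: pd.DataFrame,
    trait: str = "trait",
    p_threshold: float = 1e-7,
    half_window_bp: int = 500_000,
    exclusions: list[tuple[str, int, int]] = (HLA_REGION,),
) -> list[Locus]:
    """Greedy clumping of GWAS summary statistics into 1 Mb loci.

    Deterministic and independent of input row order: p-value ties break
    toward the smaller genomic coordinate.
    """
    df = gwas[["variant_id", "chrom", "pos", "p"]].copy()
    df["chrom"] = df["chrom"].map(_normalize_chrom)
    df = df.sort_values(["p", "chrom", "pos"], kind="stable").reset_index(drop=True)
    alive = np.ones(len(df), dtype=bool)
    chroms = df["chrom"].values
    pos = df["pos"].values
    pvals = df["p"].values
    loci: list[Locus] = []

    for i in range(len(df)):
        if not alive[i] or pvals[i] >= p_threshold:
            continue
        lead_chrom, lead_pos = chroms[i], int(pos[i])
        in_window = alive & (chroms == lead_chrom) & (
            np.abs(pos - lead_pos) <= half_window_bp
        )
        members = df.loc[in_window, "variant_id"].tolist()
        alive[in_window] = False
        excluded, reason = False, ""
        for exc_chrom, exc_lo, exc_hi in exclusions:
            if lead_chrom == _normalize_chrom(exc_chrom) and exc_lo <= lead_pos <= exc_hi:
                excluded = True
                reason = f"lead in excluded region {exc_chrom}:{exc_lo}-{exc_hi}"
        loci.append(
            Locus(
                trait=trait,
                lead_variant=df["variant_id"].iloc[i],
                chrom=lead_chrom,
                pos=lead_pos,
                p=float(pvals[i]),
                window=(lead_pos - half_window_bp, lead_pos + half_window_bp),
                member_variants=members,
                excluded=excluded,
                reason=reason,
            )
        )
    return loci


def ascertain_features(
    locus: Locus,
    qtl_results: pd.DataFrame,
    bpval_max: float = 0.01,
    window_bp: int = 1_000_000,
) -> list[str]:
    """Features eligible for colocalization at a locus.

    A feature qualifies when its permutation p-value is below ``bpval_max``
    and its anchor lies within ``window_bp`` of the lead variant.
    ``qtl_results`` needs columns feature, chrom, anchor_pos, bpval.
    """
    t = qtl_results
    mask = (
        (t["bpval"] < bpval_max)
        & (t["chrom"].map(_normalize_chrom) == locus.chrom)
        & (np.abs(t["anchor_pos"] - locus.pos) <= window_bp)
    )
    return t.loc[mask, "feature"].tolist()


def wakefield_log_abf(beta, se, W: float):
    """Log approximate Bayes factor for a single-variant association."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    if W < 0:
        raise ValueError("prior scale W must be non-negative")
    z = beta / se
    r = W**2 / (se**2 + W**2)
    return 0.5 * np.log1p(-r) + 0.5 * z**2 * r


def harmonize_stats(
    a: pd.DataFrame, b: pd.DataFrame, drop_ambiguous: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align two summary-stat tables on (chrom, pos, allele pair).

    Effect signs in ``b`` are flipped where its ref/alt assignment is
    swapped relative to ``a``.  Strand-ambiguous variants (A/T, C/G) are
    dropped by default since their orientation cannot be resolved from
    summary data alone.
    """
    def _key(df):
        return [
            (_normalize_chrom(c), p, tuple(sorted((r.upper(), t.upper()))))
            for c, p, r, t in zip(df["chrom"], df["pos"], df["ref"], df["alt"])
        ]

    AMBIG = {("A", "T"), ("C", "G")}
    a = a.copy()
    b = b.copy()
    a["_key"] = _key(a)
    b["_key"] = _key(b)
    if drop_ambiguous:
        a = a[[k[2] not in AMBIG for k in a["_key"]]]
        b = b[[k[2] not in AMBIG for k in b["_key"]]]
    common = set(a["_key"]) & set(b["_key"])
    a = a[a["_key"].isin(common)].sort_values("_key").reset_index(drop=True)
    b = b[b["_key"].isin(common)].sort_values("_key").reset_index(drop=True)
    flip = (a["ref"].str.upper().values != b["ref"].str.upper().values)
    b.loc[flip, "beta"] = -b.loc[flip, "beta"]
    b.loc[flip, ["ref", "alt"]] = b.loc[flip, ["alt", "ref"]].values
    return a.drop(columns="_key"), b.drop(columns="_key")


def coloc_posteriors(
    gwas_stats: pd.DataFrame,
    qtl_stats: pd.DataFrame,
    priors: ColocPriors | None = None,
    locus_id: str = "locus",
    feature: str = "feature",
    modality: str = "expression",
) -> ColocResult:
    """Posterior probabilities of the five colocalization hypotheses.

    Both tables need columns variant_id, beta, se; the computation is
    restricted to their variant intersection.  Hypothesis likelihoods are
    accumulated with log-sum-exp over per-variant ABFs; the reported top
    variant maximizes the per-variant shared-causal term.
    """
    priors = priors or ColocPriors()
    merged = gwas_stats[["variant_id", "beta", "se"]].merge(
        qtl_stats[["variant_id", "beta", "se"]],
        on="variant_id",
        suffixes=("_gwas", "_qtl"),
    )
    if len(merged) == 0:
        raise ValueError(
            f"no common variants between GWAS and QTL stats at {locus_id}/{feature}"
        )
    l1 = wakefield_log_abf(merged["beta_gwas"], merged["se_gwas"], priors.W_gwas)
    l2 = wakefield_log_abf(merged["beta_qtl"], merged["se_qtl"], priors.W_qtl)

    lse1 = logsumexp(l1)
    lse2 = logsumexp(l2)
    lse12 = logsumexp(l1 + l2)

    lH0 = 0.0
    lH1 = np.log(priors.p1) + lse1
    lH2 = np.log(priors.p2) + lse2
    with np.errstate(divide="ignore"):
        lH4 = np.log(priors.p12) + lse12
    # sum over distinct pairs = (sum_i)(sum_j) - sum_{i==j}, done in log space
    pair_total = lse1 + lse2
    if len(merged) == 1 or pair_total - lse12 < 1e-14:
        lH3 = -np.inf
    else:
        lH3 = (
            np.log(priors.p1)
            + np.log(priors.p2)
            + pair_total
            + np.log1p(-np.exp(lse12 - pair_total))
        )
    lh = np.array([lH0, lH1, lH2, lH3, lH4])
    pp = np.exp(lh - logsumexp(lh))
    top = merged["variant_id"].iloc[int(np.argmax(l1 + l2))]
    return ColocResult(
        locus_id=locus_id,
        feature=feature,
        modality=modality,
        pp=pp,
        top_variant=top,
        n_variants=len(merged),
    )


def colocalization_rate(
    loci: list[Locus],
    results: list[ColocResult],
    pp4_min: float = 0.75,
    min_loci: int = 10,
) -> pd.DataFrame:
    """Per-trait colocalization summary.

    A locus is colocalized when any tested feature exceeds the PP4
    threshold; loci are classified eQTL-only, sQTL-only or both by the
    modalities reaching it.  Excluded loci do not count; traits with at
    most ``min_loci`` loci are flagged as underpowered.  Duplicate result
    rows are ignored.
    """
    seen = set()
    by_locus: dict[str, set[str]] = {}
    for r in results:
        key = (r.locus_id, r.feature, r.modality)
        if key in seen:
            continue
        seen.add(key)
        if r.pp4 > pp4_min:
            by_locus.setdefault(r.locus_id, set()).add(r.modality)

    rows = []
    for trait in sorted({l.trait for l in loci}):
        usable = [l for l in loci if l.trait == trait and not l.excluded]
        n = len(usable)
        e_only = s_only = both = 0
        for l in usable:
            mods = by_locus.get(l.locus_id, set())
            if "expression" in mods and "splicing" in mods:
                both += 1
            elif "expression" in mods:
                e_only += 1
            elif "splicing" in mods:
                s_only += 1
        n_coloc = e_only + s_only + both
        rows.append(
            {
                "trait": trait,
                "n_loci": n,
                "n_coloc": n_coloc,
                "rate": n_coloc / n if n else np.nan,
                "eqtl_only": e_only,
                "sqtl_only": s_only,
                "both": both,
                "underpowered": n <= min_loci,
            }
        )
    return pd.DataFrame(rows)
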