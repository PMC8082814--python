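"""End-to-end synthetic studies exercising the pipeline with known truth.

Each routine wires the generators to one analysis stage and reports the
recovery or calibration quantities of interest: colocalization
discrimination between shared and distinct causal variants, permutation
calibration on all-null features, shrinkage recovery across conditions,
the LD-bin specificity pattern, and pi1 replication on known mixtures.
These are the package's own benchmark experiments; the test suite asserts
on their outputs and the acceptance script reports them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .coloc import ColocPriors, coloc_posteriors
from .diagnostics import ld_bin_profile, pi1_replication
from .mash import EffectPanel, Mash
from .qtl import CisQTL
from .sim import (
    GenotypeMatrix,
    _marginal_stats,
    _redraw_cohort,
    simulate_effect_panel,
    simulate_genotypes,
)

__all__ = [
    "simulate_locus_pair",
    "coloc_discrimination_study",
    "permutation_calibration_study",
    "mash_recovery_study",
    "ld_bin_pattern_study",
    "pi1_recovery_study",
]


def simulate_locus_pair(
    coloc_status: str,
    seed: int,
    n_variants: int = 100,
    ld_rho: float = 0.9,
    n_gwas: int = 10_000,
    h2_snp: float = 0.004,
    n_qtl: int = 300,
    qtl_h2: float = 0.1,
    distinct_r2_max: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame, GenotypeMatrix]:
    """Simulate GWAS and QTL summary statistics for one locus.

    ``coloc_status`` selects whether the GWAS causal variant coincides with
    the QTL causal variant ("shared_causal"), is a variant in low LD with
    it ("distinct_causal", r-squared below ``distinct_r2_max`` in the
    reference panel), or is absent ("no_gwas").  Both cohorts are fresh
    draws from the same LD structure; statistics are per-variant OLS.
    """
    rng = np.random.default_rng(seed)
    ref = simulate_genotypes(
        2_000, n_variants, ld_rho=ld_rho, maf_range=(0.1, 0.5),
        seed=int(rng.integers(2**31)),
    )
    qtl_causal_idx = n_variants // 2
    qtl_causal = ref.variants["variant_id"].iloc[qtl_causal_idx]

    if coloc_status == "shared_causal":
        gwas_causal_idx = qtl_causal_idx
    elif coloc_status == "distinct_causal":
        r2 = ref.ld_r2_with(qtl_causal)
        candidates = np.flatnonzero(r2 < distinct_r2_max)
        if len(candidates) == 0:
            raise RuntimeError("no low-LD variant available for a distinct causal")
        gwas_causal_idx = int(candidates[rng.integers(len(candidates))])
    elif coloc_status == "no_gwas":
        gwas_causal_idx = None
    else:
        raise ValueError(f"unknown coloc_status {coloc_status!r}")

    def _cohort_stats(n, h2, causal_idx, cohort_seed):
        crng = np.random.default_rng(cohort_seed)
        X = _redraw_cohort(ref, n, ld_rho, crng)
        y = crng.standard_normal(n)
        if causal_idx is not None and h2 > 0:
            g = X[:, causal_idx]
            beta_c = np.sqrt(h2 / (1 - h2)) / g.std() if g.std() > 0 else 0.0
            y = beta_c * g + y
        out = ref.variants[["variant_id", "chrom", "pos", "ref", "alt"]].copy()
        return pd.concat(
            [out.reset_index(drop=True), _marginal_stats(X, y)], axis=1
        )

    gwas = _cohort_stats(n_gwas, h2_snp, gwas_causal_idx, int(rng.integers(2**31)))
    qtl = _cohort_stats(n_qtl, qtl_h2, qtl_causal_idx, int(rng.integers(2**31)))
    return gwas, qtl, ref


def coloc_discrimination_study(
    n_replicates: int = 200,
    seed: int = 0,
    pp4_min: float = 0.75,
    **locus_kwargs,
) -> dict[str, float]:
    """Fraction of loci reaching PP4 under shared vs distinct causals."""
    rng = np.random.default_rng(seed)
    priors = ColocPriors()
    out = {}
    for status in ("shared_causal", "distinct_causal"):
        hits = 0
        for _ in range(n_replicates):
            gwas, qtl, _ = simulate_locus_pair(
                status, seed=int(rng.integers(2**31)), **locus_kwargs
            )
            res = coloc_posteriors(gwas, qtl, priors)
            hits += res.pp4 > pp4_min
        out[status] = hits / n_replicates
    return out


def permutation_calibration_study(
    n_features: int = 500,
    n_samples: int = 150,
    n_variants: int = 30,
    n_perm: int = 1000,
    n_perm_oracle: int = 0,
    seed: int = 0,
) -> dict:
    """Beta-approximated permutation p-values on all-null features.

    Phenotypes are pure noise, so feature-level p-values should be uniform
    and the q < 0.05 call rate should stay at the nominal level.  With
    ``n_perm_oracle`` > 0, an empirical permutation p-value at that depth
    is also computed per feature for cross-checking the Beta smoothing.
    """
    rng = np.random.default_rng(seed)
    G = simulate_genotypes(
        n_samples, n_variants, ld_rho=0.5, maf_range=(0.1, 0.5),
        seed=int(rng.integers(2**31)),
    )
    Y = pd.DataFrame(
        rng.standard_normal((n_features, n_samples)),
        index=[f"feat{f:04d}" for f in range(n_features)],
        columns=G.samples,
    )
    meta = pd.DataFrame(
        {
            "feature": Y.index,
            "chrom": "1",
            "anchor_pos": int(G.variants["pos"].median()),
        }
    )
    model = CisQTL(G, Y, meta)
    res = model.fit(n_perm=n_perm, seed=int(rng.integers(2**31)))
    out = {
        "bpvals": res.table["bpval"].values,
        "qvalues": res.table["qvalue"].values,
        "fpr_q05": float(res.table["significant"].mean()),
        "ks_uniform": float(stats.kstest(res.table["bpval"].values, "uniform")[0]),
    }
    if n_perm_oracle:
        orng = np.random.default_rng(seed + 1)
        emp = []
        for f_i in range(n_features):
            cis = model._cis_index(Y.index[f_i])
            y = model._Yr[f_i]
            X = model._Xr[:, cis]
            _, _, _, p = model._scan_one(y, X)
            minima = model._min_p_permutations(y, X, n_perm_oracle, orng)
            emp.append((1 + np.sum(minima <= p.min())) / (n_perm_oracle + 1))
        out["empirical_pvals"] = np.array(emp)
    return out


def mash_recovery_study(
    n_features: int = 1000,
    n_conditions: int = 6,
    se_scale: float = 0.1,
    seed: int = 0,
) -> dict:
    """Shrinkage recovery on a simulated multi-condition effect panel.

    The strong set mixes fully shared, group-shared, condition-specific
    and null features; the random set is predominantly null, as in real
    QTL scans.  Reports the posterior/raw RMSE ratio against the truth,
    the share-by-magnitude rate among truly shared features, the LFSR
    false-call rate on null slots, and the EM log-likelihood trace.
    """
    rng = np.random.default_rng(seed)
    strong_b, strong_s, truth = simulate_effect_panel(
        n_features,
        n_conditions,
        {"shared": 0.4, "group": 0.2, "specific": 0.2, "null": 0.2},
        beta_scale=0.5,
        se_scale=se_scale,
        seed=int(rng.integers(2**31)),
    )
    rand_b, rand_s, _ = simulate_effect_panel(
        2 * n_features,
        n_conditions,
        {"shared": 0.02, "group": 0.02, "specific": 0.02, "null": 0.94},
        beta_scale=0.5,
        se_scale=se_scale,
        seed=int(rng.integers(2**31)),
    )
    model = Mash(
        EffectPanel(rand_b, rand_s, "random"),
        EffectPanel(strong_b, strong_s, "strong"),
    )
    fit = model.fit()

    true = truth.betas.values
    rmse_post = float(np.sqrt(np.mean((fit.post_mean.values - true) ** 2)))
    rmse_raw = float(np.sqrt(np.mean((strong_b.values - true) ** 2)))

    shared_mask = (truth.table["pattern"] == "shared").values
    null_mask = (truth.table["pattern"] == "null").values
    lfsr = fit.lfsr.values
    pm = fit.post_mean.values

    # pairwise two-fold rule among truly shared features
    shared_ok = []
    for f in np.flatnonzero(shared_mask):
        for i in range(n_conditions):
            for j in range(i + 1, n_conditions):
                if lfsr[f, i] < 0.05 or lfsr[f, j] < 0.05:
                    a, b = pm[f, i], pm[f, j]
                    if min(abs(a), abs(b)) > 0:
                        ratio = max(abs(a), abs(b)) / min(abs(a), abs(b))
                        shared_ok.append(
                            (np.sign(a) == np.sign(b)) and ratio <= 2.0
                        )
                    else:
                        shared_ok.append(False)
    return {
        "rmse_posterior": rmse_post,
        "rmse_raw": rmse_raw,
        "rmse_ratio": rmse_post / rmse_raw,
        "shared_by_magnitude_rate": float(np.mean(shared_ok)),
        "null_lfsr_rate": float((lfsr[null_mask] < 0.05).mean()),
        "loglik_trace": fit.loglik_trace,
        "fit": fit,
        "truth": truth,
    }


def ld_bin_pattern_study(
    n_replicates: int = 100,
    pattern: str = "shared",
    n_groups: int = 6,
    n_samples: int = 300,
    n_variants: int = 200,
    qtl_h2: float = 0.5,
    ld_rho: float = 0.99,
    maf_range: tuple[float, float] = (0.4, 0.5),
    seed: int = 0,
) -> dict:
    """Monotone LD-bin pattern recovery for shared vs group-specific QTLs.

    For each replicate, one causal variant drives the phenotype in every
    group (``pattern='shared'``) or in group 0 only (``pattern='specific'``);
    per-group association stats at the locus are binned by LD with the
    causal (lead) variant.  Profiles whose best QTL variant (smallest p
    across groups) is not in close LD with the lead (r-squared <= 0.8) are
    dropped, mirroring the display-retention rule of the diagnostic.
    Reports the fraction of retained replicates with a monotone
    min -log10 p profile per group.
    """
    from .coloc import Locus

    rng = np.random.default_rng(seed)
    monotone = []
    n_dropped = 0
    for rep in range(n_replicates):
        G = simulate_genotypes(
            n_samples, n_variants, ld_rho=ld_rho, maf_range=maf_range,
            spacing_bp=5_000, seed=int(rng.integers(2**31)),
        )
        causal_idx = n_variants // 2
        g = G.dosages[:, causal_idx]
        beta = np.sqrt(qtl_h2 / (1 - qtl_h2)) / g.std()
        stats_per_group = {}
        for grp in range(n_groups):
            active = pattern == "shared" or grp == 0
            y = (beta * g if active else 0.0) + rng.standard_normal(n_samples)
            tbl = _marginal_stats(G.dosages, y)
            tbl["variant_id"] = G.variants["variant_id"].values
            stats_per_group[f"group{grp}"] = tbl
        lead = G.variants["variant_id"].iloc[causal_idx]
        locus = Locus(
            trait="sim",
            lead_variant=lead,
            chrom="1",
            pos=int(G.variants["pos"].iloc[causal_idx]),
            p=1e-9,
            window=(0, 10**9),
        )
        prof = ld_bin_profile(locus, "gene", G, stats_per_group)
        if not (prof.lead_to_strong_r2 > 0.8):
            n_dropped += 1
            continue
        mono = prof.monotone_groups()
        monotone.append([bool(mono[f"group{g_}"]) for g_ in range(n_groups)])
    monotone = np.array(monotone, dtype=float)
    return {
        "monotone_fraction_per_group": monotone.mean(axis=0),
        "all_groups_monotone_fraction": float(monotone.all(axis=1).mean()),
        "n_retained": len(monotone),
        "n_dropped": n_dropped,
        "pattern": pattern,
    }


def pi1_recovery_study(m: int = 2000, seed: int = 0) -> dict:
    """pi1 on a uniform null and on a 50/50 null/alternative mixture."""
    rng = np.random.default_rng(seed)
    p_null = rng.uniform(size=m)
    est_null = pi1_replication(p_null, n_bootstrap=200, seed=int(rng.integers(2**31)))
    p_mix = np.concatenate(
        [rng.uniform(size=m // 2), rng.beta(0.1, 1.0, size=m // 2)]
    )
    est_mix = pi1_replication(p_mix, n_bootstrap=200, seed=int(rng.integers(2**31)))
    return {"pi1_null": est_null.pi1, "pi1_mixture": est_mix.pi1,
            "est_null": est_null, "est_mix": est_mix}
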