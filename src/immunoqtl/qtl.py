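"""Cis-QTL mapping with a permutation pass and beta-approximated p-values.

The model mirrors the standard cis-scan design: for each molecular feature
(gene expression or intron usage), every variant within a 1 Mb window of
the feature anchor (TSS for genes, cluster midpoint for introns) is tested
with ordinary least squares after projecting the covariates out of both
the phenotype and the genotypes.  A permutation pass permutes the
residualized phenotype (keeping LD intact), records the minimal nominal p
per permutation, and fits a Beta distribution to the minima by maximum
likelihood; the feature-level p-value ("bpval") is the fitted Beta CDF at
the observed minimum.  Multiplicity across features is handled with
Storey q-values; features with q < 0.05 are called significant.

Usage::

    model = CisQTL(G, Y, feature_meta, covariates=C)
    res = model.fit(n_perm=1000, seed=1)
    res.table            # per-feature lead variant, bpval, q-value
    res.summary()
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sim import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = ["CisQTL", "CisQTLResults", "storey_pi0", "storey_qvalues", "select_covariates"]


def _residualize(M: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Project the column space of C out of each column of M (samples x p)."""
    Q, _ = np.linalg.qr(C)
    return M - Q @ (Q.T @ M)


def _check_covariates(C: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(C)
    if rank < C.shape[1]:
        # flag the columns whose removal restores full rank
        bad = []
        for j in range(C.shape[1]):
            others = np.delete(C, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                bad.append(names[j])
        raise ValueError(f"rank-deficient covariates; collinear columns: {bad}")


class CisQTL:
    """Cis-window association model for a panel of molecular features.

    Parameters
    ----------
    genotypes : GenotypeMatrix
    phenotypes : DataFrame, features x samples (normalized scores)
    feature_meta : DataFrame with columns feature, chrom, anchor_pos
    covariates : optional DataFrame, samples x k (an intercept is always
        included implicitly and must not be supplied)
    cis_window_bp : half-width of the cis window around the anchor
    """

    def __init__(
        self,
        genotypes: GenotypeMatrix,
        phenotypes: pd.DataFrame,
        feature_meta: pd.DataFrame,
        covariates: pd.DataFrame | None = None,
        cis_window_bp: int = 1_000_000,
    ):
        if list(phenotypes.columns) != list(genotypes.samples):
            phenotypes = phenotypes.loc[:, list(genotypes.samples)]
        self.G = genotypes
        self.Y = phenotypes
        self.meta = feature_meta.set_index("feature")
        self.cis_window_bp = cis_window_bp

        n = genotypes.n_samples
        if covariates is None:
            C = np.ones((n, 1))
            self._k_cov = 0
        else:
            covariates = covariates.loc[list(genotypes.samples)]
            C = np.column_stack([np.ones(n), covariates.values])
            _check_covariates(C, ["intercept", *map(str, covariates.columns)])
            self._k_cov = covariates.shape[1]
        self._C = C
        # residualize once; degrees of freedom account for projected columns
        self._df = n - self._k_cov - 2
        if self._df < 1:
            raise ValueError("not enough samples for the covariate count")
        self._Xr = _residualize(np.nan_to_num(genotypes.dosages), C)
        self._Yr = _residualize(phenotypes.values.T, C).T  # features x samples

    def _cis_index(self, feature: str) -> np.ndarray:
        row = self.meta.loc[feature]
        v = self.G.variants
        mask = (v["chrom"].values == row["chrom"]) & (
            np.abs(v["pos"].values - row["anchor_pos"]) <= self.cis_window_bp
        )
        return np.flatnonzero(mask)

    def _scan_one(self, y: np.ndarray, X: np.ndarray):
        """OLS of residualized y on each residualized variant column."""
        sxx = (X**2).sum(axis=0)
        sxy = X.T @ y
        syy = (y**2).sum()
        with np.errstate(invalid="ignore", divide="ignore"):
            beta = np.where(sxx > 0, sxy / sxx, 0.0)
        rss = np.maximum(syy - beta * sxy, 0.0)
        sigma2 = rss / self._df
        with np.errstate(invalid="ignore", divide="ignore"):
            se = np.sqrt(np.where(sxx > 0, sigma2 / sxx, np.inf))
        t = np.where(np.isfinite(se) & (se > 0), beta / se, 0.0)
        p = np.clip(2 * stats.t.sf(np.abs(t), self._df), np.finfo(float).tiny, 1.0)
        return beta, se, t, p

    def nominal_scan(self) -> pd.DataFrame:
        """Per feature x cis-variant association statistics."""
        rows = []
        v = self.G.variants
        for f_i, feature in enumerate(self.Y.index):
            cis = self._cis_index(feature)
            if len(cis) == 0:
                continue
            beta, se, t, p = self._scan_one(self._Yr[f_i], self._Xr[:, cis])
            anchor = self.meta.loc[feature, "anchor_pos"]
            rows.append(
                pd.DataFrame(
                    {
                        "feature": feature,
                        "variant_id": v["variant_id"].values[cis],
                        "distance": v["pos"].values[cis] - anchor,
                        "beta": beta,
                        "se": se,
                        "z": t,
                        "p": p,
                        "n": self.G.n_samples,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
            columns=["feature", "variant_id", "distance", "beta", "se", "z", "p", "n"]
        )

    # -- permutation pass ---------------------------------------------------

    def _min_p_permutations(
        self, y: np.ndarray, X: np.ndarray, n_perm: int, rng: np.random.Generator
    ) -> np.ndarray:
        """Minimal nominal p over cis variants for each phenotype permutation.

        Works on correlations: for fixed df the minimal p corresponds to the
        maximal |r|, and correlations of all permutations against all
        variants reduce to one matrix product.
        """
        n = len(y)
        Xs = X - X.mean(axis=0)
        norms = np.sqrt((Xs**2).sum(axis=0))
        ok = norms > 0
        Xs = Xs[:, ok] / norms[ok]
        ys = y - y.mean()
        ynorm = np.sqrt((ys**2).sum())
        if ynorm == 0 or not ok.any():
            return np.ones(n_perm)
        ys = ys / ynorm
        perms = np.array([rng.permutation(n) for _ in range(n_perm)])
        R = ys[perms] @ Xs  # n_perm x variants
        rmax = np.abs(R).max(axis=1)
        rmax = np.clip(rmax, 0, 1 - 1e-12)
        tstat = rmax * np.sqrt(self._df / (1 - rmax**2))
        return np.clip(2 * stats.t.sf(tstat, self._df), np.finfo(float).tiny, 1.0)

    @staticmethod
    def _fit_beta(minima: np.ndarray) -> tuple[float, float] | None:
        """MLE Beta(a, b) fit to permutation minima, moment-matched start."""
        x = np.clip(minima, 1e-300, 1 - 1e-12)
        m, v = x.mean(), x.var()
        if v <= 0:
            return None
        c = m * (1 - m) / v - 1
        a0, b0 = max(m * c, 1e-3), max((1 - m) * c, 1e-3)
        try:
            a, b, _, _ = stats.beta.fit(x, a0, b0, floc=0, fscale=1)
        except Exception:  # noqa: BLE001 - any fit failure falls back
            return None
        if not (np.isfinite(a) and np.isfinite(b) and a > 0 and b > 0):
            return None
        return float(a), float(b)

    def fit(self, n_perm: int = 1000, seed: int = 0) -> "CisQTLResults":
        """Permutation pass over all features plus Storey q-values."""
        if n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        rng = np.random.default_rng(seed)
        v = self.G.variants
        rows = []
        for f_i, feature in enumerate(self.Y.index):
            cis = self._cis_index(feature)
            if len(cis) == 0:
                continue
            y = self._Yr[f_i]
            X = self._Xr[:, cis]
            beta, se, t, p = self._scan_one(y, X)
            lead = int(np.argmin(p))
            p_obs = p[lead]
            minima = self._min_p_permutations(y, X, n_perm, rng)
            ab = self._fit_beta(minima)
            if ab is None:
                logger.warning(
                    "Beta fit failed for %s; using empirical permutation p", feature
                )
                bpval = (1 + np.sum(minima <= p_obs)) / (n_perm + 1)
            else:
                bpval = float(stats.beta.cdf(p_obs, *ab))
            rows.append(
                {
                    "feature": feature,
                    "lead_variant": v["variant_id"].values[cis[lead]],
                    "beta": beta[lead],
                    "se": se[lead],
                    "nominal_p": p_obs,
                    "bpval": max(bpval, np.finfo(float).tiny),
                }
            )
        table = pd.DataFrame(rows)
        if len(table):
            q, pi0 = storey_qvalues(table["bpval"].values)
            table["qvalue"] = q
            table["significant"] = table["qvalue"] < 0.05
        else:
            pi0 = 1.0
        return CisQTLResults(model=self, table=table, pi0=pi0, n_perm=n_perm)


@dataclass
class CisQTLResults:
    """Per-feature results of the permutation pass."""

    model: CisQTL
    table: pd.DataFrame
    pi0: float
    n_perm: int

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum()) if len(self.table) else 0

    def summary(self) -> str:
        t = self.table
        lines = [
            "Cis-QTL permutation pass",
            f"  features tested      : {len(t)}",
            f"  samples              : {self.model.G.n_samples}",
            f"  covariates           : {self.model._k_cov}",
            f"  permutations         : {self.n_perm}",
            f"  estimated pi0        : {self.pi0:.3f}",
            f"  significant (q<0.05) : {self.n_significant}",
        ]
        return "\n".join(lines)


def storey_pi0(pvals: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Estimate the null proportion pi0 on a lambda grid with smoothing.

    The grid estimates pi0(l) = #{p > l} / (m (1 - l)) are extrapolated to
    l = 1 with a weighted linear fit; weights are proportional to 1 - l,
    the inverse variance of each grid point, which keeps the noisy
    rightmost points from dominating the extrapolation.  For fewer than
    100 p-values the single-point estimate at lambda = 0.5 is used.
    """
    p = np.asarray(pvals, dtype=float)
    if len(p) == 0:
        raise ValueError("empty p-value vector")
    m = len(p)
    if m < 100:
        return float(np.clip(np.mean(p > 0.5) / 0.5, 1.0 / m, 1.0))
    if lambdas is None:
        lambdas = np.arange(0.20, 0.96, 0.05)
    pi0_l = np.array([np.mean(p > l) / (1 - l) for l in lambdas])
    coef = np.polyfit(lambdas, pi0_l, 1, w=1.0 - lambdas)
    pi0 = np.polyval(coef, 1.0)
    return float(np.clip(pi0, 1.0 / m, 1.0))


def storey_qvalues(
    pvals: np.ndarray, pi0: float | None = None
) -> tuple[np.ndarray, float]:
    """Storey q-values: step-up pi0 * m * p / rank with monotone enforcement."""
    p = np.asarray(pvals, dtype=float)
    if len(p) == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if pi0 is None:
        pi0 = storey_pi0(p)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * pi0 * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q, float(pi0)


def select_covariates(
    G: GenotypeMatrix,
    Y: pd.DataFrame,
    feature_meta: pd.DataFrame,
    pc_grid: list[int],
    *,
    n_genotype_pcs: int = 3,
    n_perm: int = 200,
    seed: int = 0,
) -> int:
    """Choose the phenotype-PC count that maximizes significant features.

    Three genotype PCs are always included.  For each candidate count the
    permutation pass is run and features with q < 0.05 counted; ties break
    toward fewer PCs.
    """
    if not pc_grid:
        raise ValueError("pc_grid must be non-empty")

    def _pcs(M: np.ndarray, k: int) -> np.ndarray:
        Mc = M - M.mean(axis=0)
        U, s, _ = np.linalg.svd(Mc, full_matrices=False)
        return U[:, :k] * s[:k]

    geno_pcs = _pcs(np.nan_to_num(G.dosages), n_genotype_pcs)
    pheno_pcs_full = _pcs(Y.values.T, max(pc_grid)) if max(pc_grid) > 0 else None

    best_count, best_hits = None, -1
    for k in sorted(pc_grid):
        cols = {f"geno_pc{i}": geno_pcs[:, i] for i in range(geno_pcs.shape[1])}
        for i in range(k):
            cols[f"pheno_pc{i}"] = pheno_pcs_full[:, i]
        C = pd.DataFrame(cols, index=list(G.samples))
        res = CisQTL(G, Y, feature_meta, covariates=C).fit(n_perm=n_perm, seed=seed)
        hits = res.n_significant
        logger.info("pc_grid=%d -> %d significant features", k, hits)
        if hits > best_hits:
            best_count, best_hits = k, hits
    return int(best_count)
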