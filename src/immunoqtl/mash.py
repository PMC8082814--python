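"""Multivariate empirical-Bayes shrinkage of QTL effects across cell types.

Implements the mash model in its exchangeable-effects (EE) parameterization:
observed effects ``bhat_j ~ N(b_j, S_j)`` with ``S_j = D_j R D_j`` built from
the declared standard errors and an estimated null correlation ``R``, and
true effects drawn from a mixture of zero-mean multivariate normals

    b_j ~ pi_0 delta_0 + sum_{k,l} pi_{kl} N(0, w_l U_k),

where the ``U_k`` combine canonical covariance patterns (identity,
per-condition singletons, equal effects in all conditions) with data-driven
patterns learned from the strongest signals, and ``w_l`` is a geometric
scale grid.  Only the mixture weights are estimated, by EM on a "random"
set of tests; posteriors are then computed on a "strong" set (the best
variant per feature across all conditions).  Significance of a shrunken
effect is measured by the local false sign rate (LFSR): the posterior
probability that the reported sign is wrong, with the point mass at zero
counted against both signs.

Sharing between conditions is summarized as the fraction of significant
effects with the same sign (share-by-sign) and additionally within a fold
factor in magnitude (share-by-magnitude, default twofold); conditions are
grouped by hierarchical clustering of the share-by-magnitude matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.linalg import solve_triangular
from scipy.spatial.distance import squareform
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

__all__ = [
    "EffectPanel",
    "build_strong_random_sets",
    "Mash",
    "MashResults",
    "SharingSummary",
    "sharing_stats",
    "group_cell_types",
]


@dataclass
class EffectPanel:
    """Feature x condition effect estimates with their standard errors."""

    betas: pd.DataFrame
    ses: pd.DataFrame
    label: str = ""

    def __post_init__(self):
        if self.betas.shape != self.ses.shape:
            raise ValueError("betas and ses must have identical shape")
        if self.betas.isna().any().any() or self.ses.isna().any().any():
            raise ValueError("panel must have no missing values")
        if (self.ses.values <= 0).any():
            raise ValueError("standard errors must be positive")

    @property
    def conditions(self) -> list[str]:
        return list(self.betas.columns)

    def zscores(self) -> pd.DataFrame:
        return self.betas / self.ses


def build_strong_random_sets(
    stats_per_condition: dict[str, pd.DataFrame],
    random_fraction: float = 0.30,
    seed: int = 0,
) -> tuple[EffectPanel, EffectPanel]:
    """Extract the strong and random test sets from per-condition scans.

    ``stats_per_condition`` maps condition name -> association table with
    columns (feature, variant_id, beta, se, p).  All conditions must cover
    a common feature x variant universe.  The random set is a uniform
    sample of tests (fraction ``random_fraction``); the strong set takes,
    per feature, the variant with the smallest p-value across all variants
    and all conditions.  Features missing a beta/se in any condition are
    excluded from the strong set and logged.
    """
    conds = list(stats_per_condition)
    indexed = {
        c: df.set_index(["feature", "variant_id"]) for c, df in stats_per_condition.items()
    }
    common = indexed[conds[0]].index
    for c in conds[1:]:
        common = common.intersection(indexed[c].index)
    if len(common) == 0:
        raise ValueError("no common feature x variant tests across conditions")

    rng = np.random.default_rng(seed)
    n_random = max(1, int(round(random_fraction * len(common))))
    take = rng.choice(len(common), size=min(n_random, len(common)), replace=False)
    random_idx = common[np.sort(take)]

    # strong: per feature, argmin p over (variant, condition)
    pmat = pd.DataFrame(
        {c: indexed[c].loc[common, "p"].values for c in conds},
        index=common,
    )
    min_p = pmat.min(axis=1)
    strong_pairs = (
        min_p.groupby(level="feature").idxmin().dropna()
    )  # feature -> (feature, variant)

    def _panel(idx, label):
        betas = pd.DataFrame(
            {c: indexed[c].loc[idx, "beta"].values for c in conds},
            index=[f"{f}|{v}" for f, v in idx],
        )
        ses = pd.DataFrame(
            {c: indexed[c].loc[idx, "se"].values for c in conds},
            index=betas.index,
        )
        keep = ~(betas.isna().any(axis=1) | ses.isna().any(axis=1))
        if (~keep).any():
            logger.warning("%d tests dropped for missing values", int((~keep).sum()))
        return EffectPanel(betas[keep], ses[keep], label)

    strong_idx = pd.MultiIndex.from_tuples(strong_pairs.values)
    return _panel(strong_idx, "strong"), _panel(random_idx, "random")


# ---------------------------------------------------------------------------


def _canonical_components(n: int) -> dict[str, np.ndarray]:
    comps = {"identity": np.eye(n)}
    for c in range(n):
        U = np.zeros((n, n))
        U[c, c] = 1.0
        comps[f"singleton_{c}"] = U
    comps["equal_effects"] = np.ones((n, n))
    return comps


def _data_driven_components(
    z_strong: np.ndarray, n_components: int
) -> dict[str, np.ndarray]:
    """Top eigenvector rank-1 patterns plus the full empirical covariance."""
    cov = np.cov(z_strong, rowvar=False)
    cov = np.atleast_2d(cov)
    w, V = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    comps = {}
    for r, i in enumerate(order[:n_components]):
        if w[i] <= 0:
            continue
        comps[f"dd_eig_{r}"] = w[i] * np.outer(V[:, i], V[:, i])
    # clip negative eigenvalues so the empirical covariance is PSD
    w_clip = np.clip(w, 0, None)
    if (w != w_clip).any():
        logger.warning("clipped negative eigenvalues in data-driven covariance")
    comps["dd_cov"] = (V * w_clip) @ V.T
    return comps


def _normalize_component(U: np.ndarray) -> np.ndarray:
    m = np.max(np.diag(U))
    return U / m if m > 0 else U


class Mash:
    """Empirical-Bayes mixture model over multi-condition effects (EE mode).

    Parameters
    ----------
    random : EffectPanel used to fit mixture weights (and null correlation).
    strong : EffectPanel used to learn data-driven covariances and on which
        posteriors are computed.
    n_dd_components : number of rank-1 eigenpatterns learned from the
        strong set (the full empirical covariance is always added).
    scale_grid : prior effect standard deviations; default is a 10-point
        geometric sequence spanning [0.05, 2] times the largest
        noise-adjusted effect magnitude in the strong set.
    null_z_max : |z| cutoff defining near-null random tests for the null
        correlation estimate.
    """

    def __init__(
        self,
        random: EffectPanel,
        strong: EffectPanel,
        n_dd_components: int = 5,
        scale_grid: np.ndarray | None = None,
        tol: float = 1e-6,
        max_iter: int = 1000,
        null_z_max: float = 2.0,
    ):
        if random.conditions != strong.conditions:
            raise ValueError("random and strong panels must share conditions")
        if len(random.conditions) < 2:
            raise ValueError("need at least 2 conditions")
        self.random = random
        self.strong = strong
        self.n_dd_components = n_dd_components
        self.tol = tol
        self.max_iter = max_iter
        self.null_z_max = null_z_max
        self.conditions = random.conditions

        if scale_grid is None:
            z_imp = np.sqrt(
                np.maximum(strong.betas.values**2 - strong.ses.values**2, 0)
            )
            top = max(z_imp.max(), 1e-3)
            scale_grid = np.geomspace(0.05 * top, 2.0 * top, 10)
        self.scale_grid = np.asarray(scale_grid, dtype=float)

    # -- model pieces -------------------------------------------------------

    def _null_correlation(self) -> np.ndarray:
        z = self.random.zscores().values
        near_null = (np.abs(z) < self.null_z_max).all(axis=1)
        if near_null.sum() < 10:
            logger.warning("too few near-null tests; using identity correlation")
            return np.eye(len(self.conditions))
        R = np.corrcoef(z[near_null], rowvar=False)
        R = np.nan_to_num(R, nan=0.0)
        np.fill_diagonal(R, 1.0)
        return R

    def _components(self) -> dict[str, np.ndarray]:
        comps = _canonical_components(len(self.conditions))
        comps.update(
            _data_driven_components(
                self.strong.zscores().values, self.n_dd_components
            )
        )
        return {name: _normalize_component(U) for name, U in comps.items()}

    def _mixture_covs(self, comps) -> tuple[list[str], list[np.ndarray]]:
        names, covs = ["null"], [np.zeros((len(self.conditions),) * 2)]
        for cname, U in comps.items():
            for w in self.scale_grid:
                names.append(f"{cname}@{w:.4g}")
                covs.append(w**2 * U)
        return names, covs

    def _loglik_matrix(
        self, panel: EffectPanel, covs: list[np.ndarray], R: np.ndarray
    ) -> np.ndarray:
        """log N(bhat_j; 0, S_j + V_m) for every test j and component m."""
        B = panel.betas.values
        SE = panel.ses.values
        n, p = B.shape
        out = np.empty((n, len(covs)))
        # tests sharing a standard-error row share S; factor once per group
        uniq, inverse = np.unique(SE, axis=0, return_inverse=True)
        for u in range(len(uniq)):
            rows = np.flatnonzero(inverse == u)
            S = np.outer(uniq[u], uniq[u]) * R
            Bg = B[rows]
            for m, V in enumerate(covs):
                C = S + V
                try:
                    L = np.linalg.cholesky(C)
                except np.linalg.LinAlgError:
                    L = np.linalg.cholesky(C + 1e-10 * np.eye(p))
                sol = solve_triangular(L, Bg.T, lower=True)
                out[rows, m] = (
                    -0.5 * p * np.log(2 * np.pi)
                    - np.log(np.diag(L)).sum()
                    - 0.5 * (sol**2).sum(axis=0)
                )
        return out

    # -- fitting ------------------------------------------------------------

    def fit(self) -> "MashResults":
        R = self._null_correlation()
        comps = self._components()
        names, covs = self._mixture_covs(comps)
        L = self._loglik_matrix(self.random, covs, R)

        M = len(names)
        pi = np.full(M, 1.0 / M)
        trace = []
        for it in range(self.max_iter):
            logw = np.log(pi + 1e-300) + L
            ll_j = logsumexp(logw, axis=1)
            ll = ll_j.sum()
            trace.append(ll)
            resp = np.exp(logw - ll_j[:, None])
            pi_new = resp.mean(axis=0)
            if it > 0 and abs(trace[-1] - trace[-2]) < self.tol * abs(trace[-2]):
                pi = pi_new
                break
            pi = pi_new
        else:
            logger.warning("EM reached max_iter=%d without converging", self.max_iter)

        post = self._posterior(self.strong, names, covs, pi, R)
        return MashResults(
            conditions=self.conditions,
            component_names=names,
            component_covs=covs,
            mixture_weights=pd.Series(pi, index=names),
            null_correlation=pd.DataFrame(
                R, index=self.conditions, columns=self.conditions
            ),
            loglik_trace=np.array(trace),
            strong=self.strong,
            **post,
        )

    def _posterior(self, panel, names, covs, pi, R) -> dict:
        B = panel.betas.values
        SE = panel.ses.values
        n, p = B.shape
        post_mean = np.zeros((n, p))
        post_m2 = np.zeros((n, p))
        p_neg = np.zeros((n, p))
        p_pos = np.zeros((n, p))

        L = self._loglik_matrix(panel, covs, R)
        logw = np.log(pi + 1e-300) + L
        resp = np.exp(logw - logsumexp(logw, axis=1)[:, None])

        uniq, inverse = np.unique(SE, axis=0, return_inverse=True)
        for u in range(len(uniq)):
            rows = np.flatnonzero(inverse == u)
            S = np.outer(uniq[u], uniq[u]) * R
            Bg = B[rows]
            for m, V in enumerate(covs):
                r = resp[rows, m][:, None]
                if not V.any():  # null: point mass at zero
                    p_neg[rows] += r
                    p_pos[rows] += r
                    continue
                A = np.linalg.solve(V + S, V)  # (V+S)^-1 V
                mu = Bg @ A  # rows of posterior means, mu_j = A.T b_j
                Sigma = V - V @ A
                var = np.clip(np.diag(Sigma), 0, None)
                sd = np.sqrt(var)
                post_mean[rows] += r * mu
                post_m2[rows] += r * (var + mu**2)
                with np.errstate(divide="ignore", invalid="ignore"):
                    zneg = np.where(sd > 0, -mu / sd, np.where(mu > 0, -np.inf, np.inf))
                cdf_neg = stats.norm.cdf(zneg)
                point = sd == 0
                # degenerate directions carry their mass as a point mass
                p_neg[rows] += r * np.where(
                    point & (mu == 0), 1.0, np.where(point, mu < 0, cdf_neg)
                )
                p_pos[rows] += r * np.where(
                    point & (mu == 0), 1.0, np.where(point, mu > 0, 1 - cdf_neg)
                )

        post_var = np.clip(post_m2 - post_mean**2, 0, None)
        lfsr = np.minimum(p_neg, p_pos)
        idx, cols = panel.betas.index, panel.betas.columns
        return {
            "post_mean": pd.DataFrame(post_mean, index=idx, columns=cols),
            "post_sd": pd.DataFrame(np.sqrt(post_var), index=idx, columns=cols),
            "lfsr": pd.DataFrame(np.clip(lfsr, 0, 1), index=idx, columns=cols),
        }


@dataclass
class MashResults:
    """Posterior effects, LFSR, and the fitted mixture."""

    conditions: list[str]
    component_names: list[str]
    component_covs: list[np.ndarray]
    mixture_weights: pd.Series
    null_correlation: pd.DataFrame
    loglik_trace: np.ndarray
    strong: EffectPanel
    post_mean: pd.DataFrame
    post_sd: pd.DataFrame
    lfsr: pd.DataFrame

    def n_active(self, lfsr_cut: float = 0.05) -> pd.Series:
        """Number of conditions with LFSR below the cutoff, per feature."""
        return (self.lfsr < lfsr_cut).sum(axis=1)

    def sharing(
        self,
        fold: float = 2.0,
        lfsr_cut: float = 0.05,
        exclude_features: pd.Index | None = None,
    ) -> "SharingSummary":
        return sharing_stats(
            self, fold=fold, lfsr_cut=lfsr_cut, exclude_features=exclude_features
        )

    def summary(self) -> str:
        w = self.mixture_weights
        top = w.sort_values(ascending=False).head(5)
        act = self.n_active()
        lines = [
            "Multivariate shrinkage (EE mode)",
            f"  conditions              : {len(self.conditions)}",
            f"  strong-set tests        : {len(self.post_mean)}",
            f"  EM iterations           : {len(self.loglik_trace)}",
            f"  final log-likelihood    : {self.loglik_trace[-1]:.2f}",
            f"  null weight             : {w['null']:.3f}",
            "  top mixture components  : "
            + ", ".join(f"{k}={v:.3f}" for k, v in top.items()),
            f"  active in all conditions: {(act == len(self.conditions)).mean():.1%}",
        ]
        return "\n".join(lines)


@dataclass
class SharingSummary:
    """Pairwise sharing fractions and the per-feature activity counts."""

    pairwise_sign: pd.DataFrame
    pairwise_magnitude: pd.DataFrame
    n_active: pd.Series
    fold: float
    lfsr_cut: float


def sharing_stats(
    post: MashResults,
    fold: float = 2.0,
    lfsr_cut: float = 0.05,
    exclude_features: pd.Index | None = None,
) -> SharingSummary:
    """Pairwise share-by-sign and share-by-magnitude between conditions.

    For a condition pair (a, b), the denominator is the set of features
    significant (LFSR < cut) in a or b; share-by-sign is the fraction with
    equal posterior-mean signs, share-by-magnitude additionally requires
    the magnitude ratio within [1/fold, fold].  ``exclude_features`` drops
    rows (e.g. an HLA band) before computing, so robustness to region
    exclusion is directly reportable.
    """
    pm = post.post_mean
    lf = post.lfsr
    if exclude_features is not None:
        keep = ~pm.index.isin(exclude_features)
        pm, lf = pm[keep], lf[keep]
    conds = list(pm.columns)
    k = len(conds)
    sign = np.full((k, k), np.nan)
    mag = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(k):
            if i == j:
                sign[i, j] = mag[i, j] = 1.0
                continue
            sig = (lf.iloc[:, i] < lfsr_cut) | (lf.iloc[:, j] < lfsr_cut)
            if sig.sum() == 0:
                continue
            a = pm.iloc[:, i][sig].values
            b = pm.iloc[:, j][sig].values
            same_sign = np.sign(a) == np.sign(b)
            sign[i, j] = same_sign.mean()
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(
                    np.minimum(np.abs(a), np.abs(b)) > 0,
                    np.maximum(np.abs(a), np.abs(b))
                    / np.minimum(np.abs(a), np.abs(b)),
                    np.inf,
                )
            mag[i, j] = (same_sign & (ratio <= fold)).mean()
    return SharingSummary(
        pairwise_sign=pd.DataFrame(sign, index=conds, columns=conds),
        pairwise_magnitude=pd.DataFrame(mag, index=conds, columns=conds),
        n_active=post.n_active(lfsr_cut) if exclude_features is None
        else (lf < lfsr_cut).sum(axis=1),
        fold=fold,
        lfsr_cut=lfsr_cut,
    )


def group_cell_types(pairwise_magnitude: pd.DataFrame, k: int = 6) -> pd.Series:
    """Group conditions by hierarchical clustering of sharing.

    Average-linkage clustering on distance 1 - sharing, cut into k groups.
    """
    n = len(pairwise_magnitude)
    if k > n:
        raise ValueError(f"k={k} exceeds the number of conditions ({n})")
    S = pairwise_magnitude.values.astype(float)
    S = (S + S.T) / 2  # enforce symmetry against estimation asymmetries
    D = np.clip(1.0 - S, 0, None)
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=pairwise_magnitude.index, name="group")
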