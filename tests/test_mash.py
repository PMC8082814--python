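"""Multivariate shrinkage: panels, EM fit, posteriors, sharing, grouping."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from immunoqtl import (
    EffectPanel,
    Mash,
    MashResults,
    build_strong_random_sets,
    group_cell_types,
    sharing_stats,
    simulate_effect_panel,
)


def _stats_tables(p_tensor, betas=None):
    """Build per-condition association tables from a feature x snp x cond
    p-value tensor."""
    n_feat, n_snp, n_cond = p_tensor.shape
    out = {}
    for c in range(n_cond):
        rows = []
        for f in range(n_feat):
            for s in range(n_snp):
                rows.append(
                    {
                        "feature": f"f{f}",
                        "variant_id": f"s{s}",
                        "beta": betas[f, s, c] if betas is not None else 0.1,
                        "se": 0.05,
                        "p": p_tensor[f, s, c],
                    }
                )
        out[f"c{c}"] = pd.DataFrame(rows)
    return out


class TestStrongRandomSets:
    def test_strong_set_matches_bruteforce_argmin(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=(2, 3, 2))
        tables = _stats_tables(p)
        strong, _ = build_strong_random_sets(tables, random_fraction=0.5, seed=1)
        for f in range(2):
            # oracle: exhaustive argmin over the p tensor for this feature
            s_best = np.unravel_index(np.argmin(p[f]), p[f].shape)[0]
            assert f"f{f}|s{s_best}" in strong.betas.index
        assert not strong.betas.isna().any().any()

    def test_random_fraction_one_is_full_universe(self):
        rng = np.random.default_rng(2)
        tables = _stats_tables(rng.uniform(size=(3, 4, 2)))
        _, random = build_strong_random_sets(tables, random_fraction=1.0, seed=3)
        assert len(random.betas) == 12


def _fit_small_panels(seed=4, n=200):
    strong_b, strong_s, _ = simulate_effect_panel(
        n, 3, {"shared": 0.4, "specific": 0.3, "null": 0.3}, seed=seed
    )
    rand_b, rand_s, _ = simulate_effect_panel(
        2 * n, 3, {"shared": 0.03, "specific": 0.03, "null": 0.94}, seed=seed + 1
    )
    return (
        EffectPanel(rand_b, rand_s, "random"),
        EffectPanel(strong_b, strong_s, "strong"),
    )


class TestMashFit:
    def test_em_loglik_nondecreasing(self):
        random, strong = _fit_small_panels()
        fit = Mash(random, strong).fit()
        assert np.all(np.diff(fit.loglik_trace) >= -1e-6 * np.abs(fit.loglik_trace[:-1]))

    def test_pure_null_random_set_concentrates_on_null(self):
        rng = np.random.default_rng(5)
        ses = pd.DataFrame(np.full((400, 3), 0.1), columns=list("abc"))
        betas = pd.DataFrame(
            0.1 * rng.standard_normal((400, 3)), columns=list("abc")
        )
        strong_b, strong_s, _ = simulate_effect_panel(
            100, 3, {"shared": 0.5, "null": 0.5}, seed=6
        )
        strong_b.columns = strong_s.columns = list("abc")
        fit = Mash(
            EffectPanel(betas, ses, "random"),
            EffectPanel(strong_b, strong_s, "strong"),
        ).fit()
        w = fit.mixture_weights
        smallest = min(
            float(name.split("@")[1]) for name in w.index if "@" in name
        )
        near_null = w["null"] + sum(
            v for name, v in w.items()
            if "@" in name and float(name.split("@")[1]) == smallest
        )
        assert near_null >= 0.9

    def test_posterior_matches_conjugate_closed_form(self):
        # single scaled-identity component, weights fixed: conditions
        # decouple, so posterior mean = bhat * W / (W + se^2) per condition
        random, strong = _fit_small_panels(seed=7)
        model = Mash(random, strong)
        W = 0.3**2
        bhat = strong.betas.values
        se2 = strong.ses.values**2
        covs = [np.zeros((3, 3)), W * np.eye(3)]
        post = model._posterior(
            strong, ["null", "comp"], covs, np.array([0.0, 1.0]), np.eye(3)
        )
        want = bhat * W / (W + se2)
        np.testing.assert_allclose(post["post_mean"].values, want, atol=1e-10)

    def test_posterior_matches_numerical_integration(self):
        # 2 conditions, 2 non-null components with hand-set weights
        conds = ["x", "y"]
        bhat = pd.DataFrame([[0.4, -0.1]], columns=conds)
        ses = pd.DataFrame([[0.15, 0.2]], columns=conds)
        random = EffectPanel(bhat, ses, "random")  # unused by _posterior
        strong = EffectPanel(bhat, ses, "strong")
        model = Mash(random, strong)
        U1 = 0.09 * np.eye(2)
        U2 = 0.16 * np.ones((2, 2)) + 0.04 * np.eye(2)
        pi = np.array([0.0, 0.3, 0.7])
        post = model._posterior(
            strong, ["null", "u1", "u2"], [np.zeros((2, 2)), U1, U2], pi, np.eye(2)
        )
        # oracle: fine-grid integration of the mixture posterior
        grid = np.linspace(-2, 2, 601)
        gx, gy = np.meshgrid(grid, grid, indexing="ij")
        pts = np.stack([gx.ravel(), gy.ravel()], axis=1)
        S = np.diag(ses.values[0] ** 2)
        dens = np.zeros(len(pts))
        for w, U in zip(pi[1:], [U1, U2]):
            prior = stats.multivariate_normal(np.zeros(2), U, allow_singular=True)
            lik = stats.multivariate_normal(bhat.values[0], S)
            dens += w * prior.pdf(pts) * lik.pdf(pts)
        dens /= dens.sum()
        want = (pts * dens[:, None]).sum(axis=0)
        np.testing.assert_allclose(post["post_mean"].values[0], want, atol=5e-3)

    def test_huge_standard_errors_shrink_to_zero(self):
        random, strong = _fit_small_panels(seed=8)
        noisy = EffectPanel(
            strong.betas.copy(), strong.ses * 0 + 50.0, "strong"
        )
        fit = Mash(random, noisy).fit()
        assert np.abs(fit.post_mean.values).max() < 1e-2

    def test_symmetric_posterior_gives_lfsr_half(self):
        conds = ["x", "y"]
        bhat = pd.DataFrame([[0.0, 0.0]], columns=conds)
        ses = pd.DataFrame([[0.1, 0.1]], columns=conds)
        strong = EffectPanel(bhat, ses, "strong")
        model = Mash(strong, strong)
        post = model._posterior(
            strong, ["null", "u"], [np.zeros((2, 2)), 0.04 * np.eye(2)],
            np.array([0.0, 1.0]), np.eye(2),
        )
        np.testing.assert_allclose(post["lfsr"].values, 0.5, atol=1e-12)

    def test_posterior_mean_bounded_by_observed_range(self):
        random, strong = _fit_small_panels(seed=9)
        fit = Mash(random, strong).fit()
        assert np.abs(fit.post_mean.values).max() <= np.abs(strong.betas.values).max()


class TestSharing:
    def _results(self, post_mean, lfsr):
        conds = list(post_mean.columns)
        return MashResults(
            conditions=conds,
            component_names=["null"],
            component_covs=[np.zeros((len(conds),) * 2)],
            mixture_weights=pd.Series([1.0], index=["null"]),
            null_correlation=pd.DataFrame(
                np.eye(len(conds)), index=conds, columns=conds
            ),
            loglik_trace=np.array([0.0]),
            strong=EffectPanel(post_mean, post_mean * 0 + 0.1, "strong"),
            post_mean=post_mean,
            post_sd=post_mean * 0 + 0.1,
            lfsr=lfsr,
        )

    def test_identical_significant_columns_fully_shared(self):
        pm = pd.DataFrame({"a": [0.5, -0.8], "b": [0.5, -0.8]})
        lf = pd.DataFrame({"a": [0.01, 0.01], "b": [0.01, 0.01]})
        sh = sharing_stats(self._results(pm, lf))
        assert sh.pairwise_magnitude.values.min() == 1.0
        assert sh.pairwise_sign.values.min() == 1.0

    def test_twofold_threshold_arithmetic(self):
        pm = pd.DataFrame({"a": [0.5, 0.5, 0.3], "b": [1.1, 0.9, -0.3]})
        lf = pd.DataFrame(np.full((3, 2), 0.01), columns=["a", "b"])
        sh = sharing_stats(self._results(pm, lf))
        # 0.5 vs 1.1 -> ratio 2.2, not shared; 0.5 vs 0.9 -> shared;
        # +0.3 vs -0.3 -> sign flip, shared by neither measure
        assert sh.pairwise_magnitude.loc["a", "b"] == pytest.approx(1 / 3)
        assert sh.pairwise_sign.loc["a", "b"] == pytest.approx(2 / 3)

    def test_region_exclusion_is_reportable(self):
        rng = np.random.default_rng(10)
        pm = pd.DataFrame(rng.normal(0.5, 0.1, size=(50, 2)), columns=["a", "b"])
        pm.iloc[:10, 1] = -pm.iloc[:10, 1]  # discordant block (an "HLA band")
        lf = pd.DataFrame(np.full((50, 2), 0.01), columns=["a", "b"])
        res = self._results(pm, lf)
        full = sharing_stats(res).pairwise_sign.loc["a", "b"]
        excl = sharing_stats(
            res, exclude_features=pm.index[:10]
        ).pairwise_sign.loc["a", "b"]
        assert excl == pytest.approx(1.0)
        assert full == pytest.approx(0.8)

    def test_n_active_counts_lfsr_below_cut(self):
        pm = pd.DataFrame({"a": [0.5], "b": [0.5], "c": [0.0]})
        lf = pd.DataFrame({"a": [0.01], "b": [0.2], "c": [0.5]})
        sh = sharing_stats(self._results(pm, lf))
        assert sh.n_active.iloc[0] == 1


class TestGrouping:
    def test_perfect_blocks_recovered(self):
        conds = list("abcdef")
        S = np.eye(6)
        for block in ([0, 1], [2, 3], [4, 5]):
            for i in block:
                for j in block:
                    S[i, j] = 1.0
        groups = group_cell_types(pd.DataFrame(S, index=conds, columns=conds), k=3)
        assert groups["a"] == groups["b"]
        assert groups["c"] == groups["d"]
        assert groups["e"] == groups["f"]
        assert len(set(groups)) == 3

    def test_duplicate_conditions_share_group(self):
        S = pd.DataFrame([[1.0, 1.0], [1.0, 1.0]], index=["a", "b"], columns=["a", "b"])
        g = group_cell_types(S, k=1)
        assert g["a"] == g["b"]

    def test_k_equals_n_gives_singletons(self):
        S = pd.DataFrame(np.eye(4) * 0.5 + 0.5 * np.eye(4), index=list("abcd"),
                         columns=list("abcd"))
        g = group_cell_types(S, k=4)
        assert len(set(g)) == 4

    def test_k_too_large_raises(self):
        S = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
        with pytest.raises(ValueError):
            group_cell_types(S, k=5)
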