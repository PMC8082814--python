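"""Locus clumping, Wakefield ABFs, colocalization posteriors, rates."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logsumexp

from immunoqtl import (
    ColocPriors,
    ColocResult,
    Locus,
    ascertain_features,
    coloc_posteriors,
    colocalization_rate,
    define_loci,
    harmonize_stats,
    wakefield_log_abf,
)


def enumeration_pp(l1, l2, p1, p2, p12):
    """Oracle: explicit sum over all causal-configuration pairs.

    Works with raw exponentials, which is safe for the small toy inputs it
    is used on; independent of the log-sum-exp implementation.
    """
    abf1 = np.exp(np.asarray(l1))
    abf2 = np.exp(np.asarray(l2))
    h0 = 1.0
    h1 = p1 * abf1.sum()
    h2 = p2 * abf2.sum()
    h3 = p1 * p2 * sum(
        abf1[i] * abf2[j]
        for i in range(len(abf1))
        for j in range(len(abf2))
        if i != j
    )
    h4 = p12 * (abf1 * abf2).sum()
    hs = np.array([h0, h1, h2, h3, h4])
    return hs / hs.sum()


def _stats(betas, ses, ids=None):
    ids = ids or [f"v{i}" for i in range(len(betas))]
    return pd.DataFrame({"variant_id": ids, "beta": betas, "se": ses})


class TestWakefieldABF:
    def test_hand_computed_value(self):
        # 0.5*ln(0.01/0.0325) + 0.5*9*0.0225/0.0325 computed by hand
        got = wakefield_log_abf(0.3, 0.1, 0.15)
        assert got == pytest.approx(-0.5893268 + 3.1153846, abs=1e-6)

    def test_null_z_gives_negative_evidence(self):
        assert wakefield_log_abf(0.0, 0.1, 0.15) < 0

    def test_vanishing_prior_scale_gives_zero(self):
        assert wakefield_log_abf(0.3, 0.1, 1e-9) == pytest.approx(0.0, abs=1e-6)

    def test_invalid_se_rejected(self):
        with pytest.raises(ValueError):
            wakefield_log_abf(0.1, 0.0, 0.15)


class TestColocPosteriors:
    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        priors = ColocPriors()
        for trial in range(30):
            n = int(rng.integers(1, 7))
            gwas = _stats(rng.normal(0, 0.2, n), rng.uniform(0.03, 0.2, n))
            qtl = _stats(rng.normal(0, 0.3, n), rng.uniform(0.05, 0.3, n))
            res = coloc_posteriors(gwas, qtl, priors)
            l1 = wakefield_log_abf(gwas["beta"], gwas["se"], priors.W_gwas)
            l2 = wakefield_log_abf(qtl["beta"], qtl["se"], priors.W_qtl)
            want = enumeration_pp(l1, l2, priors.p1, priors.p2, priors.p12)
            np.testing.assert_allclose(res.pp, want, atol=1e-10)

    def test_pp_sums_to_one(self):
        rng = np.random.default_rng(1)
        gwas = _stats(rng.normal(0, 1, 5), rng.uniform(0.05, 0.2, 5))
        qtl = _stats(rng.normal(0, 1, 5), rng.uniform(0.05, 0.2, 5))
        res = coloc_posteriors(gwas, qtl)
        assert res.pp.sum() == pytest.approx(1.0, abs=1e-12)

    def test_zero_shared_prior_kills_pp4(self):
        gwas = _stats([0.5, 0.0], [0.05, 0.05])
        qtl = _stats([0.5, 0.0], [0.05, 0.05])
        res = coloc_posteriors(gwas, qtl, ColocPriors(p12=0.0))
        assert res.pp[4] == 0.0

    def test_empty_intersection_raises(self):
        gwas = _stats([0.5], [0.05], ids=["a"])
        qtl = _stats([0.5], [0.05], ids=["b"])
        with pytest.raises(ValueError, match="no common variants"):
            coloc_posteriors(gwas, qtl)

    def test_top_variant_maximizes_joint_evidence(self):
        gwas = _stats([0.02, 0.6, 0.01], [0.05, 0.05, 0.05])
        qtl = _stats([0.01, 0.7, 0.02], [0.06, 0.06, 0.06])
        res = coloc_posteriors(gwas, qtl)
        assert res.top_variant == "v1"


def clump_oracle(df, p_threshold, half_window):
    """Independent greedy clumping by literal sorting and masking."""
    work = df.sort_values(["p", "chrom", "pos"], kind="stable").copy()
    leads = []
    while len(work) and work["p"].iloc[0] < p_threshold:
        lead = work.iloc[0]
        leads.append(lead["variant_id"])
        keep = ~(
            (work["chrom"] == lead["chrom"])
            & (np.abs(work["pos"] - lead["pos"]) <= half_window)
        )
        work = work[keep]
    return leads


class TestDefineLoci:
    def _gwas(self, rng, n=50):
        return pd.DataFrame(
            {
                "variant_id": [f"v{i}" for i in range(n)],
                "chrom": rng.choice(["1", "2"], size=n),
                "pos": rng.integers(1, 5_000_000, size=n),
                "p": 10.0 ** rng.uniform(-12, 0, size=n),
            }
        )

    def test_matches_bruteforce_oracle_on_random_instances(self):
        rng = np.random.default_rng(2)
        for trial in range(25):
            gwas = self._gwas(rng)
            loci = define_loci(gwas, exclusions=[])
            got = [l.lead_variant for l in loci]
            assert got == clump_oracle(gwas, 1e-7, 500_000)

    def test_single_significant_variant(self):
        gwas = pd.DataFrame(
            {"variant_id": ["x"], "chrom": ["3"], "pos": [100], "p": [1e-8]}
        )
        loci = define_loci(gwas)
        assert len(loci) == 1 and loci[0].lead_variant == "x"

    def test_no_significant_variants_gives_empty(self):
        gwas = pd.DataFrame(
            {"variant_id": ["x"], "chrom": ["3"], "pos": [100], "p": [1e-3]}
        )
        assert define_loci(gwas) == []

    def test_row_order_invariance(self):
        rng = np.random.default_rng(3)
        gwas = self._gwas(rng)
        a = [l.lead_variant for l in define_loci(gwas)]
        b = [l.lead_variant for l in define_loci(gwas.sample(frac=1, random_state=1))]
        assert a == b

    def test_hla_lead_excluded_with_reason(self):
        gwas = pd.DataFrame(
            {
                "variant_id": ["hla", "ok"],
                "chrom": ["6", "1"],
                "pos": [30_000_000, 1_000_000],
                "p": [1e-9, 1e-8],
            }
        )
        loci = define_loci(gwas)
        by_id = {l.lead_variant: l for l in loci}
        assert by_id["hla"].excluded and "excluded region" in by_id["hla"].reason
        assert not by_id["ok"].excluded


class TestAscertainFeatures:
    def _locus(self):
        return Locus("t", "lead", "1", 2_000_000, 1e-9,
                     (1_500_000, 2_500_000))

    def _qtl_results(self):
        return pd.DataFrame(
            {
                "feature": ["near_sig", "near_weak", "far_sig"],
                "chrom": ["1", "1", "1"],
                "anchor_pos": [2_100_000, 2_200_000, 9_000_000],
                "bpval": [0.001, 0.5, 0.001],
            }
        )

    def test_manual_filter(self):
        got = ascertain_features(self._locus(), self._qtl_results())
        assert got == ["near_sig"]

    def test_bpval_boundary_selects_all_in_window(self):
        got = ascertain_features(self._locus(), self._qtl_results(), bpval_max=1.01)
        assert got == ["near_sig", "near_weak"]

    def test_no_feature_passes(self):
        qtl = self._qtl_results()
        qtl["bpval"] = 0.9
        assert ascertain_features(self._locus(), qtl) == []


class TestColocalizationRate:
    def _loci(self, n, trait="t"):
        return [
            Locus(trait, f"L{i}", "1", i * 3_000_000 + 1_000_000, 1e-9,
                  (0, 1))
            for i in range(n)
        ]

    def _result(self, locus, feature, modality, pp4):
        pp = np.array([0, 0, 0, 1 - pp4, pp4], dtype=float)
        return ColocResult(locus.locus_id, feature, modality, pp, "v", 1)

    def test_manual_tally_with_modalities(self):
        loci = self._loci(12)
        results = []
        for l in loci[:3]:  # eQTL-only
            results.append(self._result(l, "g", "expression", 0.9))
        for l in loci[3:5]:  # sQTL-only
            results.append(self._result(l, "i", "splicing", 0.8))
        for l in loci[5:6]:  # both
            results.append(self._result(l, "g", "expression", 0.9))
            results.append(self._result(l, "i", "splicing", 0.85))
        for l in loci[6:]:  # below threshold
            results.append(self._result(l, "g", "expression", 0.3))
        summary = colocalization_rate(loci, results).iloc[0]
        assert summary["n_loci"] == 12
        assert summary["eqtl_only"] == 3
        assert summary["sqtl_only"] == 2
        assert summary["both"] == 1
        assert summary["rate"] == pytest.approx(6 / 12)
        assert not summary["underpowered"]

    def test_duplicated_results_do_not_inflate(self):
        loci = self._loci(4)
        res = [self._result(loci[0], "g", "expression", 0.9)]
        once = colocalization_rate(loci, res).iloc[0]
        twice = colocalization_rate(loci, res + res).iloc[0]
        assert once["n_coloc"] == twice["n_coloc"] == 1

    def test_no_hits_gives_zero_rate_and_small_traits_flagged(self):
        loci = self._loci(5)
        summary = colocalization_rate(loci, []).iloc[0]
        assert summary["rate"] == 0.0
        assert summary["underpowered"]


class TestHarmonize:
    def test_allele_swap_flips_beta(self):
        a = pd.DataFrame(
            {"variant_id": ["v"], "chrom": ["1"], "pos": [100], "ref": ["A"],
             "alt": ["G"], "beta": [0.5], "se": [0.1]}
        )
        b = a.copy()
        b["ref"], b["alt"] = "G", "A"
        b["beta"] = 0.5
        ha, hb = harmonize_stats(a, b)
        assert hb["beta"].iloc[0] == pytest.approx(-0.5)

    def test_strand_ambiguous_dropped(self):
        a = pd.DataFrame(
            {"variant_id": ["v1", "v2"], "chrom": ["1", "1"], "pos": [100, 200],
             "ref": ["A", "C"], "alt": ["T", "T"], "beta": [0.5, 0.2],
             "se": [0.1, 0.1]}
        )
        ha, hb = harmonize_stats(a, a.copy())
        assert list(ha["variant_id"]) == ["v2"]
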