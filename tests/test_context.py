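"""Differentiation metric, decile/context enrichment, promoter correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methtrio.context import (
    decile_enrichment,
    differentiation_cv,
    eqtm_sign_context,
    matched_null_enrichment,
    promoter_methylation_vs_expression,
    sample_matched_null,
)
from methtrio.datamodel import GenomicInterval


def _beta_from_medians(medians, n_ind=5):
    """Cell-type beta frames whose per-site medians equal ``medians`` rows."""
    out = {}
    for ct_i in range(len(medians[0])):
        vals = np.array([[m[ct_i]] * n_ind for m in medians], dtype=float)
        out[f"ct{ct_i}"] = pd.DataFrame(
            vals, index=[f"cg{i}" for i in range(len(medians))]
        )
    return out


class TestDifferentiationCV:
    def test_equal_medians_zero_cv(self):
        scores = differentiation_cv(_beta_from_medians([(0.5, 0.5, 0.5)]))
        assert scores["cv"].iloc[0] == 0.0

    def test_closed_form(self):
        # medians (0.2, 0.4, 0.6): sample sd 0.2, mean 0.4 -> cv 0.5
        scores = differentiation_cv(_beta_from_medians([(0.2, 0.4, 0.6)]))
        assert scores["cv"].iloc[0] == pytest.approx(0.5)

    def test_cell_type_order_invariance(self, rng):
        b = {f"ct{i}": pd.DataFrame(rng.random((20, 4))) for i in range(3)}
        a = differentiation_cv(b)["cv"]
        c = differentiation_cv({k: b[k] for k in reversed(list(b))})["cv"]
        np.testing.assert_allclose(a, c)

    def test_median_padding_invariance(self):
        base = _beta_from_medians([(0.2, 0.4, 0.6)], n_ind=5)
        padded = {
            ct: pd.concat([df, df.median(axis=1).rename(99)], axis=1)
            for ct, df in base.items()
        }
        assert differentiation_cv(base)["cv"].iloc[0] == pytest.approx(
            differentiation_cv(padded)["cv"].iloc[0]
        )

    def test_zero_mean_undefined(self):
        scores = differentiation_cv(_beta_from_medians([(0.0, 0.0, 0.0)]))
        assert np.isnan(scores["cv"].iloc[0])

    def test_shifted_sites_score_higher(self, small_cohort):
        beta = {ct: m.beta for ct, m in small_cohort.methylation.items()}
        scores = differentiation_cv(beta)
        shifted = small_cohort.truth.loc[
            small_cohort.truth["type"] == "differentiated", "feature_id"
        ]
        flag = scores.index.isin(shifted)
        p = stats.mannwhitneyu(
            scores["cv"][flag], scores["cv"][~flag], alternative="greater"
        ).pvalue
        assert p < 0.01


class TestDecileEnrichment:
    def test_top_decile_indicator(self, rng):
        scores = pd.Series(np.arange(100, dtype=float))
        flags = pd.Series(scores >= 90)
        table, p = decile_enrichment(scores, flags)
        assert table.loc[table["bin"] == 10, "proportion"].iloc[0] == 1.0
        assert (table.loc[table["bin"] < 10, "proportion"] == 0).all()

    def test_independent_flags_flat_profile(self, rng):
        scores = pd.Series(rng.random(2000))
        flags = pd.Series(rng.random(2000) < 0.3)
        table, p = decile_enrichment(scores, flags)
        # binomial 99% CI around the overall rate
        rate = flags.mean()
        half = 2.58 * np.sqrt(rate * (1 - rate) / 200)
        assert ((table["proportion"] - rate).abs() < half).mean() >= 0.8
        assert p > 0.01

    def test_wilcoxon_matches_oracle(self, rng):
        scores = pd.Series(rng.normal(size=40))
        flags = pd.Series(rng.random(40) < 0.5)
        _, p = decile_enrichment(scores, flags)
        ref = stats.mannwhitneyu(
            scores[flags], scores[~flags], alternative="two-sided"
        ).pvalue
        assert p == pytest.approx(ref)

    def test_too_few_sites_rejected(self):
        with pytest.raises(ValueError):
            decile_enrichment(pd.Series([1.0, 2.0]), pd.Series([True, False]))


def _pairs(rng, n, inside_rate, feature):
    """Pair table with anchors placed inside the feature at ``inside_rate``."""
    inside = rng.random(n) < inside_rate
    pos = np.where(
        inside,
        rng.integers(feature.start, feature.end, n),
        rng.integers(feature.end + 1000, feature.end + 50_000, n),
    )
    return pd.DataFrame(
        {
            "chrom": feature.chrom,
            "pos": pos,
            "maf": rng.uniform(0.05, 0.5, n),
            "distance": rng.integers(-50_000, 50_000, n),
            "level": rng.random(n),
        },
        index=[f"p{i}" for i in range(n)],
    )


class TestMatchedNullEnrichment:
    def test_saturating_feature_no_enrichment(self, rng):
        feature = GenomicInterval("chr1", 0, 10_000_000)
        sig = _pairs(rng, 100, 1.0, GenomicInterval("chr1", 0, 1000))
        null = _pairs(rng, 500, 1.0, GenomicInterval("chr1", 0, 1000))
        out = matched_null_enrichment(sig, null, {"all": [feature]}, seed=0)
        assert out["odds_ratio"].iloc[0] == pytest.approx(1.0, abs=1e-9) or np.isnan(
            out["odds_ratio"].iloc[0]
        )
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_planted_enrichment_detected(self):
        rng = np.random.default_rng(2)
        feature = GenomicInterval("chr1", 0, 10_000)
        sig = _pairs(rng, 500, 0.6, feature)
        null = _pairs(rng, 2000, 0.3, feature)
        out = matched_null_enrichment(sig, null, {"f": [feature]}, seed=0)
        assert out["odds_ratio"].iloc[0] > 1
        assert out["p"].iloc[0] < 0.05

    def test_no_matching_equals_random_sampling(self, rng):
        null = _pairs(rng, 300, 0.5, GenomicInterval("chr1", 0, 10_000))
        sig = _pairs(rng, 50, 0.5, GenomicInterval("chr1", 0, 10_000))
        a = sample_matched_null(sig, null, match_on=(), seed=3)
        b = null.loc[np.random.default_rng(3).choice(null.index, size=50, replace=True)]
        pd.testing.assert_frame_equal(a, b)

    def test_matching_recovers_confounded_or(self):
        # null pool biased toward high-MAF pairs that sit outside the feature;
        # matching on MAF removes the confounding
        rng = np.random.default_rng(5)
        feature = GenomicInterval("chr1", 0, 10_000)
        sig = _pairs(rng, 400, 0.5, feature)
        sig["maf"] = rng.uniform(0.05, 0.25, 400)
        low = _pairs(rng, 1000, 0.5, feature)
        low["maf"] = rng.uniform(0.05, 0.25, 1000)
        high = _pairs(rng, 1000, 0.05, feature)
        high["maf"] = rng.uniform(0.25, 0.5, 1000)
        null = pd.concat([low, high], ignore_index=True)
        matched = matched_null_enrichment(
            sig, null, {"f": [feature]}, match_on=("maf",), seed=1
        )
        unmatched = matched_null_enrichment(
            sig, null, {"f": [feature]}, match_on=(), seed=1
        )
        # unmatched null under-represents in-feature pairs -> inflated OR
        assert unmatched["odds_ratio"].iloc[0] > matched["odds_ratio"].iloc[0]
        assert matched["odds_ratio"].iloc[0] == pytest.approx(1.0, abs=0.35)


class TestEqtmSignContext:
    def _sites(self, positions):
        return pd.DataFrame(
            {"chrom": "chr1", "pos": positions},
            index=[f"s{i}" for i in range(len(positions))],
        )

    def test_identical_lists_identical_proportions(self):
        sites = self._sites([5, 50, 500])
        feats = {"f": [GenomicInterval("chr1", 0, 100)]}
        out = eqtm_sign_context(sites, sites, self._sites([5, 5000]), feats)
        assert out["prop_pos"].iloc[0] == out["prop_neg"].iloc[0]

    def test_proportions_match_brute_force(self, rng):
        feats = {"f": [GenomicInterval("chr1", 100, 300)]}
        pos = self._sites(rng.integers(0, 500, 40))
        neg = self._sites(rng.integers(0, 500, 30))
        non = self._sites(rng.integers(0, 500, 100))
        out = eqtm_sign_context(pos, neg, non, feats)
        for name, df in (("prop_pos", pos), ("prop_neg", neg), ("prop_expected", non)):
            expect = ((df["pos"] >= 100) & (df["pos"] < 300)).mean()
            assert out[name].iloc[0] == pytest.approx(expect)

    def test_planted_negative_excess(self, rng):
        feats = {"f": [GenomicInterval("chr1", 0, 1000)]}
        pos = self._sites(rng.integers(2000, 10_000, 100))
        neg = self._sites(
            np.concatenate([rng.integers(0, 1000, 60), rng.integers(2000, 10_000, 40)])
        )
        non = self._sites(
            np.concatenate([rng.integers(0, 1000, 30), rng.integers(2000, 10_000, 170)])
        )
        out = eqtm_sign_context(pos, neg, non, feats)
        assert out["or_neg"].iloc[0] > out["or_pos"].iloc[0]


class TestPromoterMethylationExpression:
    def test_null_rho_near_zero(self, rng):
        beta = pd.DataFrame(
            rng.random((60, 20)), index=[f"cg{i}" for i in range(60)]
        )
        rpkm = pd.DataFrame(
            rng.lognormal(1, 1, (30, 20)), index=[f"g{i}" for i in range(30)]
        )
        site_gene = pd.Series(
            [f"g{i % 30}" for i in range(60)], index=beta.index
        )
        out = promoter_methylation_vs_expression(beta, rpkm, site_gene)
        rhos = out["per_individual"]["rho"]
        assert abs(rhos.mean()) < 3 / np.sqrt(30 * 20)

    def test_global_repression_negative_everywhere(self, rng):
        n_genes, n_ind = 40, 15
        meth = rng.random(n_genes)
        expr = np.exp(-3 * meth)[:, None] * rng.lognormal(0, 0.1, (n_genes, n_ind))
        beta = pd.DataFrame(
            np.repeat(meth[:, None], n_ind, axis=1) + rng.normal(0, 0.01, (n_genes, n_ind)),
            index=[f"cg{i}" for i in range(n_genes)],
        ).clip(0, 1)
        rpkm = pd.DataFrame(expr, index=[f"g{i}" for i in range(n_genes)])
        site_gene = pd.Series([f"g{i}" for i in range(n_genes)], index=beta.index)
        out = promoter_methylation_vs_expression(beta, rpkm, site_gene)
        assert (out["per_individual"]["rho"] < 0).all()

    def test_single_gene_no_test_marker(self, rng):
        beta = pd.DataFrame(rng.random((2, 10)), index=["cg0", "cg1"])
        rpkm = pd.DataFrame(rng.random((1, 10)), index=["g0"])
        site_gene = pd.Series(["g0", "g0"], index=beta.index)
        out = promoter_methylation_vs_expression(beta, rpkm, site_gene)
        assert out["per_individual"]["rho"].isna().all()
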