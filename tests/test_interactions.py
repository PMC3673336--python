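"""Interaction model, permutation pi1 envelope, TF-methylation analyses."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methtrio.interactions import (
    InteractionBatch,
    _batch_product_p,
    build_interaction_batch,
    interaction_test,
    minor_hom_count,
    permutation_pi1_envelope,
    select_interaction_triplets,
    snp_tf_interaction,
    tf_meth_correlation,
)
from methtrio.datamodel import GenomicInterval


class TestInteractionTest:
    def test_perfect_interaction(self, rng):
        s = rng.binomial(2, 0.4, 50).astype(float)
        m = rng.normal(size=50)
        y = (s - s.mean()) * (m - m.mean())
        beta, t, p = interaction_test(y, s, m)
        assert p < 1e-10

    def test_coefficients_match_normal_equations_oracle(self, rng):
        s = rng.binomial(2, 0.4, 60).astype(float)
        m = rng.normal(size=60)
        y = 0.5 * s + 0.2 * m + 0.7 * s * m + rng.normal(size=60)
        beta, t, p = interaction_test(y, s, m, center=False)
        x = np.column_stack([np.ones(60), s, m, s * m])
        oracle = np.linalg.solve(x.T @ x, x.T @ y)
        assert beta == pytest.approx(oracle[3], abs=1e-10)

    def test_centering_leaves_product_inference_unchanged(self, rng):
        s = rng.binomial(2, 0.4, 80).astype(float)
        m = rng.normal(2.0, 1.0, 80)
        y = rng.normal(size=80) + 0.4 * s * m
        _, t_c, p_c = interaction_test(y, s, m, center=True)
        _, t_u, p_u = interaction_test(y, s, m, center=False)
        assert t_c == pytest.approx(t_u, rel=1e-9)
        # and affine rescaling of the inputs leaves the centered t unchanged
        _, t_r, _ = interaction_test(y, 3 * s + 1, 0.5 * m - 2, center=True)
        assert t_r == pytest.approx(t_c, rel=1e-9)

    def test_collinear_design_no_test(self, rng):
        s = rng.binomial(2, 0.4, 30).astype(float)
        beta, t, p = interaction_test(rng.normal(size=30), s, s)
        assert np.isnan(p)

    def test_type_i_error_calibrated(self):
        rng = np.random.default_rng(0)
        batch = InteractionBatch(
            rng.normal(size=(1000, 40)),
            rng.binomial(2, 0.3, (1000, 40)).astype(float),
            rng.normal(size=(1000, 40)),
        )
        p = _batch_product_p(batch, batch.expr)
        assert np.nanmean(p < 0.05) == pytest.approx(0.05, abs=0.02)


class TestPi1Envelope:
    def test_fixed_seed_identical_bands(self, rng):
        batch = InteractionBatch(
            rng.normal(size=(120, 40)),
            rng.binomial(2, 0.3, (120, 40)).astype(float),
            rng.normal(size=(120, 40)),
        )
        a = permutation_pi1_envelope(batch, n_perm=100, seed=3)
        b = permutation_pi1_envelope(batch, n_perm=100, seed=3)
        pd.testing.assert_frame_equal(a.qq_bands, b.qq_bands)
        assert a.empirical_p == b.empirical_p

    def test_null_empirical_p_uniform(self):
        ps = []
        for seed in range(60):
            rng = np.random.default_rng(seed)
            batch = InteractionBatch(
                rng.normal(size=(100, 50)),
                rng.binomial(2, 0.3, (100, 50)).astype(float),
                rng.normal(size=(100, 50)),
            )
            ps.append(permutation_pi1_envelope(batch, n_perm=100, seed=seed).empirical_p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_planted_interactions_detected(self):
        rng = np.random.default_rng(1)
        t_n, n = 3000, 60
        s = rng.binomial(2, 0.3, (t_n, n)).astype(float)
        m = rng.normal(size=(t_n, n))
        e = rng.normal(size=(t_n, n)) * 0.5
        k = t_n // 10
        e[:k] += 1.0 * (s[:k] - s[:k].mean(1, keepdims=True)) * m[:k]
        env = permutation_pi1_envelope(InteractionBatch(e, s, m), n_perm=200, seed=2)
        assert env.empirical_p < 0.01
        # the reported smoother value is noisy at this test count; sanity band
        assert 0.0 < env.observed_pi1 <= 0.25

    def test_too_few_triplets_rejected(self, rng):
        batch = InteractionBatch(*(rng.normal(size=(10, 30)),) * 3)
        with pytest.raises(ValueError):
            permutation_pi1_envelope(batch, n_perm=100)


class TestMinorHomCount:
    def test_counts_minor_allele_side(self):
        d = np.array([0.0] * 50 + [1.0] * 30 + [2.0] * 3)
        assert minor_hom_count(d) == 3
        d = np.array([0.0] * 3 + [1.0] * 30 + [2.0] * 50)
        assert minor_hom_count(d) == 3


class TestSelectInteractionTriplets:
    def test_filters_match_conjunction_oracle(self, small_cohort):
        cohort = small_cohort
        g = cohort.genotypes
        beta = cohort.methylation["fibroblast"].beta
        rng = np.random.default_rng(4)
        snps = list(g.snp_ids[:20])
        cpgs = list(beta.index[:10])
        exons = [f"x{i}" for i in range(8)]
        eqtl = pd.DataFrame(
            {
                "feature_id": rng.choice(snps, 40),
                "target_id": rng.choice(exons, 40),
                "p": rng.random(40) * 2e-4,
            }
        )
        eqtm = pd.DataFrame(
            {
                "feature_id": rng.choice(cpgs, 30),
                "target_id": rng.choice(exons, 30),
                "p": rng.random(30) * 2e-3,
            }
        )
        out = select_interaction_triplets(
            eqtl, eqtm, g, beta, recomb_intervals=cohort.features["recombination"]
        )
        from methtrio.association import spearman_test

        for _, row in out.iterrows():
            assert row["eqtl_p"] < 1e-4 and row["eqtm_p"] < 1e-3
            assert row["n_minor_hom"] >= 4
            dos = g.dosage[row["snp_id"]]
            _, p_sm = spearman_test(dos, beta.loc[row["cpg_id"], dos.index])
            assert np.isnan(p_sm) or p_sm >= 0.05

    def test_best_snp_per_recomb_interval(self, small_cohort):
        g = small_cohort.genotypes
        beta = small_cohort.methylation["fibroblast"].beta
        # two SNPs in the same interval -> only the better p is kept
        snp_pos = g.snps[["chrom", "pos"]]
        s1, s2 = g.snp_ids[0], None
        for cand in g.snp_ids[1:]:
            same = (
                snp_pos.loc[cand, "chrom"] == snp_pos.loc[s1, "chrom"]
                and abs(snp_pos.loc[cand, "pos"] - snp_pos.loc[s1, "pos"]) < 10_000
            )
            if same:
                s2 = cand
                break
        if s2 is None:
            pytest.skip("no co-located SNP pair in fixture")
        eqtl = pd.DataFrame(
            {"feature_id": [s1, s2], "target_id": ["x0", "x0"], "p": [1e-6, 1e-5]}
        )
        eqtm = pd.DataFrame(
            {"feature_id": [beta.index[0]], "target_id": ["x0"], "p": [1e-5]}
        )
        out = select_interaction_triplets(
            eqtl, eqtm, g, beta, recomb_intervals=small_cohort.features["recombination"],
            min_minor_homs=0, snp_meth_p_min=0.0,
        )
        assert set(out["snp_id"]) <= {s1}


def _tf_setup(rng, n_ind=60, n_cpg=30, effect=0.0, frac_affected=0.0):
    individuals = [f"i{k}" for k in range(n_ind)]
    # two exons of the same TF gene share the gene's expression signal
    gene_level = rng.normal(size=n_ind)
    tf_expr = pd.DataFrame(
        gene_level + rng.normal(0, 0.1, size=(2, n_ind)),
        index=pd.Index(["tfx_e0", "tfx_e1"], name="exon_id"),
        columns=individuals,
    )
    tf_info = pd.DataFrame(
        {"tf": "TFX", "chrom": "chr9", "tss": 1000},
        index=tf_expr.index,
    )
    cpg_meta = pd.DataFrame(
        {"chrom": "chr1", "pos": np.arange(n_cpg) * 1000 + 500},
        index=pd.Index([f"cg{i}" for i in range(n_cpg)], name="cpg_id"),
    )
    n_hit = int(frac_affected * n_cpg)
    base = rng.normal(size=(n_cpg, n_ind))
    base[:n_hit] += effect * gene_level
    beta = pd.DataFrame(
        1 / (1 + np.exp(-base)), index=cpg_meta.index, columns=individuals
    )
    peaks = {"TFX": [GenomicInterval("chr1", 0, n_cpg * 1000)]}
    return tf_expr, tf_info, beta, cpg_meta, peaks


class TestTfMethCorrelation:
    def test_tss_proximal_sites_excluded(self, rng):
        tf_expr, tf_info, beta, cpg_meta, peaks = _tf_setup(rng)
        cpg_meta = cpg_meta.copy()
        cpg_meta["chrom"] = "chr9"
        cpg_meta["pos"] = 500_000  # 0.5 Mb from the TF TSS -> excluded
        out = tf_meth_correlation(tf_expr, tf_info, beta, cpg_meta, peaks)
        assert len(out["records"]) == 0

    def test_planted_effect_pi1_recovered(self):
        # the smoother is noisy at a few thousand tests, so the recovery is
        # measured as the mean over replicate simulations
        vals = []
        for seed in range(3, 8):
            rng = np.random.default_rng(seed)
            tf_expr, tf_info, beta, cpg_meta, peaks = _tf_setup(
                rng, n_ind=100, n_cpg=1000, effect=1.0, frac_affected=0.2
            )
            out = tf_meth_correlation(tf_expr, tf_info, beta, cpg_meta, peaks)
            assert out["per_tf"].set_index("tf").loc["TFX", "pi1"] == out["pi1"]
            vals.append(out["pi1"])
        assert np.mean(vals) == pytest.approx(0.2, abs=0.07)

    def test_permuted_control_near_null(self):
        rng = np.random.default_rng(4)
        tf_expr, tf_info, beta, cpg_meta, peaks = _tf_setup(
            rng, n_ind=100, n_cpg=250, effect=1.0, frac_affected=0.2
        )
        out = tf_meth_correlation(tf_expr, tf_info, beta, cpg_meta, peaks, seed=0)
        from methtrio.association import storey_pi1

        assert storey_pi1(out["perm_p"])[1] <= 0.05


class TestSnpTfInteraction:
    def test_selection_and_planted_interaction(self):
        rng = np.random.default_rng(5)
        n_ind = 80
        individuals = pd.Index([f"ind{i:03d}" for i in range(n_ind)], name="individual")
        dosage = rng.binomial(2, 0.4, (n_ind, 3)).astype(float)
        snps = pd.DataFrame(
            {"chrom": "chr1", "pos": [100, 5000, 9000], "ref": "A", "alt": "G"},
            index=pd.Index(["s0", "s1", "s2"], name="snp_id"),
        )
        from methtrio.datamodel import GenotypeMatrix

        g = GenotypeMatrix(
            pd.DataFrame(dosage, index=individuals, columns=snps.index), snps
        )
        tf_expr = pd.DataFrame(
            rng.normal(size=(1, n_ind)), index=pd.Index(["tf_e0"], name="exon_id"),
            columns=individuals,
        )
        tf_info = pd.DataFrame({"tf": "TFX", "chrom": "chr9", "tss": 10}, index=tf_expr.index)
        s = dosage[:, 0]
        tfx = tf_expr.iloc[0].to_numpy()
        y = 0.2 * s + 0.2 * tfx + 1.0 * (s - s.mean()) * tfx + rng.normal(0, 0.5, n_ind)
        beta = pd.DataFrame(
            {ind: [v] for ind, v in zip(individuals, 1 / (1 + np.exp(-y)))},
            index=pd.Index(["cg0"], name="cpg_id"),
        )
        mqtl = pd.DataFrame(
            {"feature_id": ["s0"], "target_id": ["cg0"], "p": [1e-8], "significant": [True]}
        )
        tf_meth = {
            "records": pd.DataFrame(
                {"tf": ["TFX"], "exon_id": ["tf_e0"], "cpg_id": ["cg0"],
                 "rho": [0.5], "p": [1e-6]}
            )
        }
        peaks = {"TFX": [GenomicInterval("chr1", 0, 200)]}
        out = snp_tf_interaction(mqtl, tf_meth, g, tf_expr, tf_info, beta, peaks)
        assert len(out["triplets"]) == 1
        assert out["triplets"]["p"].iloc[0] < 1e-4
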