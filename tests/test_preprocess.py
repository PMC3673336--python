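"""Genotype QC, methylation normalization and expression processing."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methtrio.datamodel import GenotypeMatrix, ExpressionData, MethylationData
from methtrio.preprocess import (
    expressed_genes,
    filter_probes,
    hwe_chisq_p,
    normalize_methylation_450k,
    process_expression,
    qc_genotypes,
    quantile_normalize_columns,
    rpkm,
)
from methtrio.simulate import SimConfig, simulate_cohort


def _genotypes(dosage: np.ndarray) -> GenotypeMatrix:
    n_ind, n_snp = dosage.shape
    snps = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": np.arange(n_snp) * 100,
            "ref": "A",
            "alt": "G",
        },
        index=pd.Index([f"s{j}" for j in range(n_snp)], name="snp_id"),
    )
    return GenotypeMatrix(
        pd.DataFrame(dosage, index=[f"i{k}" for k in range(n_ind)], columns=snps.index),
        snps,
    )


class TestGenotypeQC:
    def test_missingness_filter(self):
        good = np.repeat([0.0, 1.0, 2.0], [25, 50, 25])
        bad = good.copy()
        bad[:6] = np.nan  # 6% missing > 5%
        g, report = qc_genotypes(
            _genotypes(np.column_stack([bad, good])), apply_assoc_maf=False
        )
        assert report.removed_missingness == 1
        assert list(g.snp_ids) == ["s1"]

    def test_exact_hwe_proportions_retained(self):
        d = np.repeat([0.0, 1.0, 2.0], [25, 50, 25])[:, None]
        assert hwe_chisq_p(25, 50, 25) > 0.99
        g, report = qc_genotypes(_genotypes(np.column_stack([d, d])), apply_assoc_maf=False)
        assert report.removed_hwe == 0

    def test_no_heterozygotes_removed_by_hwe(self):
        # (50, 0, 50): chi-square statistic equals n -> p far below 1e-6
        assert hwe_chisq_p(50, 0, 50) < 1e-6
        d = np.repeat([0.0, 2.0], [50, 50])[:, None]
        ok = np.tile(np.repeat([0.0, 1.0, 2.0], [25, 50, 25])[:, None], (1, 1))
        g, report = qc_genotypes(_genotypes(np.column_stack([d, ok])), apply_assoc_maf=False)
        assert report.removed_hwe == 1
        assert list(g.snp_ids) == ["s1"]

    def test_removal_counts_sum_to_difference(self, small_cohort):
        g, report = qc_genotypes(small_cohort.genotypes)
        removed = (
            report.removed_missingness
            + report.removed_maf
            + report.removed_hwe
            + report.removed_assoc_maf
        )
        assert report.n_input - report.n_output == removed
        assert report.n_output == len(g.snp_ids)

    def test_all_removed_raises_with_breakdown(self):
        d = np.zeros((50, 3))  # constant: MAF 0 everywhere
        with pytest.raises(ValueError, match="maf"):
            qc_genotypes(_genotypes(d))


class TestQuantileNormalization:
    def test_identical_columns_unchanged_up_to_target(self, rng):
        v = rng.random(50)
        df = pd.DataFrame({"a": v, "b": v})
        out = quantile_normalize_columns(df)
        np.testing.assert_allclose(out["a"], out["b"])
        np.testing.assert_allclose(np.sort(out["a"]), np.sort(v))

    def test_rank_order_preserved(self, rng):
        df = pd.DataFrame(rng.normal(size=(100, 5)))
        out = quantile_normalize_columns(df)
        for c in df:
            assert (
                np.argsort(out[c].to_numpy(), kind="stable")
                == np.argsort(df[c].to_numpy(), kind="stable")
            ).all()


@pytest.fixture(scope="module")
def intensity_cohort():
    cfg = SimConfig(
        n_individuals=15,
        n_genes=20,
        n_snps=60,
        n_cpgs=2000,
        fraction_null=1.0,
        simulate_intensities=True,
        seed=9,
    )
    return simulate_cohort(cfg)


class TestNormalizeMethylation:
    def test_identical_individuals_identical_output(self, rng):
        n = 200
        sites = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": np.arange(n),
                "probe_type": np.where(np.arange(n) < 80, 1, 2),
                "channel": np.where(np.arange(n) % 2 == 0, "green", "red"),
            },
            index=pd.Index([f"cg{i}" for i in range(n)], name="cpg_id"),
        )
        sites.loc[sites["probe_type"] == 2, "channel"] = ""
        m = rng.random((n, 2)) * 1000
        u = rng.random((n, 2)) * 1000
        m[:, 1] = m[:, 0]
        u[:, 1] = u[:, 0]
        md = MethylationData(
            sites,
            meth=pd.DataFrame(m, index=sites.index, columns=["a", "b"]),
            unmeth=pd.DataFrame(u, index=sites.index, columns=["a", "b"]),
        )
        out = normalize_methylation_450k(md)
        np.testing.assert_allclose(out.beta["a"], out.beta["b"], atol=1e-12)

    def test_probe_types_match_at_quantiles(self, intensity_cohort):
        out = normalize_methylation_450k(intensity_cohort.methylation["fibroblast"])
        t1 = out.sites.index[out.sites["probe_type"] == 1]
        t2 = out.sites.index[out.sites["probe_type"] == 2]
        grid = np.linspace(0.05, 0.95, 19)
        for ind in out.beta.columns[:5]:
            q1 = np.quantile(out.beta.loc[t1, ind], grid)
            q2 = np.quantile(out.beta.loc[t2, ind], grid)
            assert np.abs(q1 - q2).max() < 0.02

    def test_channel_bias_removed(self, intensity_cohort):
        # simulated red-channel gain 1.3: after normalization the type-1
        # channel medians agree to < 1%
        out = normalize_methylation_450k(intensity_cohort.methylation["fibroblast"])
        s = out.sites
        t1g = s.index[(s["probe_type"] == 1) & (s["channel"] == "green")]
        t1r = s.index[(s["probe_type"] == 1) & (s["channel"] == "red")]
        mg = out.meth.loc[t1g].median(axis=0)
        mr = out.meth.loc[t1r].median(axis=0)
        assert ((mg - mr).abs() / mg).max() < 0.01

    def test_missing_probe_type_rejected(self, rng):
        sites = pd.DataFrame(
            {"chrom": "chr1", "pos": [1, 2]},
            index=pd.Index(["cg0", "cg1"], name="cpg_id"),
        )
        md = MethylationData(
            sites,
            meth=pd.DataFrame(rng.random((2, 2)), index=sites.index, columns=["a", "b"]),
            unmeth=pd.DataFrame(rng.random((2, 2)), index=sites.index, columns=["a", "b"]),
        )
        with pytest.raises(ValueError, match="probe_type"):
            normalize_methylation_450k(md)


class TestFilterProbes:
    def _meth(self, positions):
        sites = pd.DataFrame(
            {"chrom": "chr1", "pos": positions, "probe_type": 2, "channel": ""},
            index=pd.Index([f"cg{i}" for i in range(len(positions))], name="cpg_id"),
        )
        beta = pd.DataFrame(
            np.full((len(positions), 3), 0.5), index=sites.index, columns=list("abc")
        )
        return MethylationData(sites, beta=beta)

    def test_overlapping_probe_removed(self):
        m = self._meth([100, 300])
        snps = pd.DataFrame({"chrom": ["chr1"], "pos": [101]})
        out, n = filter_probes(m, snps)
        assert n == 1 and list(out.cpg_ids) == ["cg1"]

    def test_no_snp_list_is_identity(self):
        m = self._meth([100, 300])
        out, n = filter_probes(m, None)
        assert n == 0 and len(out.cpg_ids) == 2

    def test_matches_brute_force_overlap(self, rng):
        pos = rng.integers(0, 5000, 200)
        m = self._meth(pos)
        snps = pd.DataFrame({"chrom": "chr1", "pos": rng.integers(0, 5000, 100)})
        out, n = filter_probes(m, snps, probe_span_bp=2)
        expect = {
            f"cg{i}"
            for i, p in enumerate(pos)
            if not ((snps["pos"] >= p) & (snps["pos"] < p + 2)).any()
        }
        assert set(out.cpg_ids) == expect


class TestProcessExpression:
    def _cov(self, individuals, rng):
        return pd.DataFrame(
            {
                "mean_gc": rng.normal(0.45, 0.02, len(individuals)),
                "run_date": rng.choice(["d1", "d2"], len(individuals)),
                "primer_index": rng.choice(["p1", "p2", "p3"], len(individuals)),
                "insert_size_mode": rng.integers(180, 220, len(individuals)),
            },
            index=individuals,
        )

    def test_library_scaling(self, rng):
        counts = pd.DataFrame(
            {"a": [40.0, 2e7 - 40], "b": [10.0, 1e7 - 10]},
            index=pd.Index(["e1", "e2"], name="exon_id"),
        )
        exons = pd.DataFrame(
            {"gene_id": "g1", "chrom": "chr1", "start": [0, 100], "end": [50, 200],
             "length": [50, 100]},
            index=counts.index,
        )
        e = ExpressionData(counts, exons)
        out, dropped = process_expression(
            e, self._cov(counts.columns, rng), min_exonic_reads=0
        )
        # library 'a' totals 2e7 -> scale factor 0.5
        assert out.normalized is not None
        scaled_e1_a = counts.loc["e1", "a"] * (1e7 / 2e7)
        assert scaled_e1_a == 20.0

    def test_exon_zero_fraction_filter_and_sample_floor(self, rng):
        n = 100
        counts = pd.DataFrame(
            rng.poisson(20, (3, n)).astype(float),
            index=pd.Index(["e1", "e2", "e3"], name="exon_id"),
            columns=[f"i{k}" for k in range(n)],
        )
        counts.iloc[1, :11] = 0  # zeros in 11% of samples -> removed
        counts.iloc[:, 0] = 0  # sample with zero reads -> dropped by floor
        exons = pd.DataFrame(
            {"gene_id": "g1", "chrom": "chr1", "start": 0, "end": 10, "length": 10},
            index=counts.index,
        )
        out, dropped = process_expression(
            ExpressionData(counts, exons), self._cov(counts.columns, rng),
            min_exonic_reads=1,
        )
        assert dropped == ["i0"]
        assert "e2" not in out.normalized.index

    def test_planted_gc_effect_removed(self):
        cfg = SimConfig(
            n_individuals=120, n_genes=40, n_snps=100, n_cpgs=20,
            fraction_null=1.0, gc_slope=2.0, seed=4,
        )
        cohort = simulate_cohort(cfg)
        ct = "fibroblast"
        out, _ = process_expression(
            cohort.expression[ct], cohort.covariates[ct], min_exonic_reads=0
        )
        gc = cohort.covariates[ct]["mean_gc"].to_numpy()
        slopes = []
        for i in range(out.normalized.shape[0]):
            y = np.log1p(out.normalized.iloc[i].to_numpy().clip(min=0))
            slopes.append(np.polyfit(gc, y, 1)[0])
        slopes = np.array(slopes)
        se = slopes.std(ddof=1) / np.sqrt(len(slopes))
        assert abs(slopes.mean()) < 3 * max(se, 0.05)

    def test_row_means_preserved(self, small_cohort):
        ct = "LCL"
        e = small_cohort.expression[ct]
        out, _ = process_expression(e, small_cohort.covariates[ct], min_exonic_reads=0)
        totals = e.counts.sum(axis=0)
        scaled = (e.counts * (1e7 / totals)).loc[out.normalized.index]
        np.testing.assert_allclose(
            out.normalized.mean(axis=1), scaled.mean(axis=1), atol=1e-8
        )

    def test_missing_covariates_rejected(self, small_cohort):
        ct = "tcell"
        cov = small_cohort.covariates[ct].iloc[:-3]
        with pytest.raises(ValueError, match="missing"):
            process_expression(small_cohort.expression[ct], cov, min_exonic_reads=0)


class TestRpkm:
    def test_closed_form(self):
        counts = pd.DataFrame(
            {"a": [1000.0, 1e7 - 1000]},
            index=pd.Index(["e1", "e2"], name="exon_id"),
        )
        exons = pd.DataFrame(
            {"gene_id": ["g1", "g2"], "chrom": "chr1", "start": [0, 0],
             "end": [2000, 10], "length": [2000, 10_000_000]},
            index=counts.index,
        )
        out = rpkm(ExpressionData(counts, exons))
        # 1000 reads / (2 kb * 10 M reads) = 50
        assert out.loc["g1", "a"] == pytest.approx(50.0)

    def test_zero_counts_zero_rpkm_and_matches_oracle(self, rng):
        counts = pd.DataFrame(
            rng.poisson(30, (4, 3)).astype(float),
            index=pd.Index([f"e{i}" for i in range(4)], name="exon_id"),
            columns=list("abc"),
        )
        counts.iloc[0] = 0
        exons = pd.DataFrame(
            {"gene_id": ["g1", "g1", "g2", "g3"], "chrom": "chr1",
             "start": 0, "end": 10, "length": [100, 200, 50, 400]},
            index=counts.index,
        )
        out = rpkm(ExpressionData(counts, exons))
        lib = counts.sum(axis=0) / 1e6
        for gene, idx in (("g1", ["e0", "e1"]), ("g2", ["e2"]), ("g3", ["e3"])):
            kb = exons.loc[idx, "length"].sum() / 1e3
            np.testing.assert_allclose(
                out.loc[gene], counts.loc[idx].sum(axis=0) / kb / lib
            )

    def test_expressed_genes_rule(self, rng):
        n = 100
        counts = pd.DataFrame(
            rng.poisson(5, (2, n)).astype(float) + 1,
            index=pd.Index(["e1", "e2"], name="exon_id"),
            columns=[f"i{k}" for k in range(n)],
        )
        counts.iloc[1, :15] = 0  # zero in 15% of samples -> gene not expressed
        exons = pd.DataFrame(
            {"gene_id": ["g1", "g2"], "chrom": "chr1", "start": 0, "end": 10, "length": 10},
            index=counts.index,
        )
        assert list(expressed_genes(ExpressionData(counts, exons))) == ["g1"]
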