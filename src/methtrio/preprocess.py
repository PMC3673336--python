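"""Genotype QC, 450k-style methylation normalization, expression processing.

The methylation normalization reproduces the staged scheme used for two-probe
bead arrays: type-1 probes read both signals in one colour channel and type-2
probes read methylated in green / unmethylated in red, so the two designs (and
the two channels) are equalized in stages before beta-values are formed and
jointly normalized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import GenotypeMatrix, ExpressionData, MethylationData

log = logging.getLogger(__name__)

COVARIATE_COLUMNS = ["mean_gc", "run_date", "primer_index", "insert_size_mode"]


def validate_covariates(cov: pd.DataFrame) -> pd.DataFrame:
    missing = set(COVARIATE_COLUMNS) - set(cov.columns)
    if missing:
        raise ValueError(f"covariate table missing columns {sorted(missing)}")
    if cov[COVARIATE_COLUMNS].isna().any().any():
        raise ValueError("covariate table contains missing values")
    return cov


# ---------------------------------------------------------------------------
# Genotype QC
# ---------------------------------------------------------------------------


@dataclass
class GenotypeQCReport:
    n_input: int
    removed_missingness: int
    removed_maf: int
    removed_hwe: int
    removed_assoc_maf: int
    n_output: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "filter": [
                    "input",
                    "missingness",
                    "maf_prefilter",
                    "hwe",
                    "assoc_maf",
                    "output",
                ],
                "count": [
                    self.n_input,
                    self.removed_missingness,
                    self.removed_maf,
                    self.removed_hwe,
                    self.removed_assoc_maf,
                    self.n_output,
                ],
            }
        )


def hwe_chisq_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """1-df chi-square goodness-of-fit p-value for Hardy-Weinberg proportions."""
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    p_alt = (2 * n_hom_alt + n_het) / (2 * n)
    exp = np.array(
        [n * (1 - p_alt) ** 2, 2 * n * p_alt * (1 - p_alt), n * p_alt**2]
    )
    obs = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
    mask = exp > 0
    stat = float(((obs[mask] - exp[mask]) ** 2 / exp[mask]).sum())
    return float(stats.chi2.sf(stat, df=1))


def qc_genotypes(
    g: GenotypeMatrix,
    miss_max: float = 0.05,
    maf_min_prefilter: float = 0.01,
    hwe_p_min: float = 1e-6,
    maf_min_assoc: float = 0.05,
    apply_assoc_maf: bool = True,
) -> tuple[GenotypeMatrix, GenotypeQCReport]:
    """Remove SNPs failing missingness, MAF and HWE filters.

    Each removed SNP is attributed to the first failing filter in the order
    missingness > MAF prefilter > HWE; the association-stage MAF >= 5% filter
    is applied as a second, separately counted pass.
    """
    d = g.dosage.to_numpy(dtype=float)
    n_ind, n_snp = d.shape
    miss_frac = np.isnan(d).mean(axis=0)
    with np.errstate(invalid="ignore"):
        p_alt = np.nanmean(d, axis=0) / 2.0
    maf = np.minimum(p_alt, 1 - p_alt)
    hwe_p = np.array(
        [
            hwe_chisq_p(
                int(np.nansum(d[:, j] == 0)),
                int(np.nansum(d[:, j] == 1)),
                int(np.nansum(d[:, j] == 2)),
            )
            for j in range(n_snp)
        ]
    )
    fail_miss = miss_frac > miss_max
    fail_maf = ~fail_miss & (maf < maf_min_prefilter)
    fail_hwe = ~fail_miss & ~fail_maf & (hwe_p < hwe_p_min)
    keep = ~(fail_miss | fail_maf | fail_hwe)
    fail_assoc = np.zeros(n_snp, dtype=bool)
    if apply_assoc_maf:
        fail_assoc = keep & (maf < maf_min_assoc)
        keep = keep & ~fail_assoc
    report = GenotypeQCReport(
        n_input=n_snp,
        removed_missingness=int(fail_miss.sum()),
        removed_maf=int(fail_maf.sum()),
        removed_hwe=int(fail_hwe.sum()),
        removed_assoc_maf=int(fail_assoc.sum()),
        n_output=int(keep.sum()),
    )
    if report.n_output == 0:
        raise ValueError(f"all SNPs removed by QC: {report.to_frame().to_dict('records')}")
    kept_ids = g.snp_ids[keep]
    return g.subset_snps(kept_ids), report


# ---------------------------------------------------------------------------
# Quantile normalization primitives
# ---------------------------------------------------------------------------


def quantile_normalize_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Classic quantile normalization of columns to the mean sorted vector."""
    x = df.to_numpy(dtype=float)
    n = x.shape[0]
    if n == 0:
        return df.copy()
    target = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    grid = np.arange(n, dtype=float)
    for j in range(x.shape[1]):
        ranks = stats.rankdata(x[:, j], method="average") - 1.0
        out[:, j] = np.interp(ranks, grid, target)
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def quantile_map(values: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Map ``values`` onto the empirical distribution of ``reference``."""
    values = np.asarray(values, dtype=float)
    n = values.size
    if n == 0:
        return values
    ranks = stats.rankdata(values, method="average")
    p = (ranks - 0.5) / n
    return np.quantile(np.asarray(reference, dtype=float), p)


def quantile_normalize_together(vectors: list[np.ndarray]) -> list[np.ndarray]:
    """Normalize possibly different-length vectors to their mean quantile function."""
    vectors = [np.asarray(v, dtype=float) for v in vectors]
    grid = np.linspace(0, 1, 2001)
    qfs = [np.quantile(v, grid) for v in vectors if v.size]
    target = np.mean(qfs, axis=0)
    out = []
    for v in vectors:
        if v.size == 0:
            out.append(v.copy())
            continue
        ranks = stats.rankdata(v, method="average")
        p = (ranks - 0.5) / v.size
        out.append(np.interp(p, grid, target))
    return out


# ---------------------------------------------------------------------------
# 450k methylation normalization
# ---------------------------------------------------------------------------


def normalize_methylation_450k(m: MethylationData, eps: float = 0.0) -> MethylationData:
    """Staged two-probe-type quantile normalization of raw intensities.

    1. Type-1 probes: methylated (M) and unmethylated (U) intensities are
       quantile normalized across individuals per colour channel, then the two
       channels are quantile normalized within each individual (for M and U
       separately) to remove the colour bias.
    2. Type-2 probes: M and U are quantile normalized across individuals, then
       mapped per individual onto the corresponding normalized type-1
       reference distribution (M on M, U on U).
    3. beta = M / (M + U + eps).
    4. The type-1 and type-2 beta-values are quantile normalized together
       within each individual, yielding the final beta in [0, 1].
    """
    if m.meth is None or m.unmeth is None:
        raise ValueError("raw intensities required for normalization")
    if "probe_type" not in m.sites.columns or m.sites["probe_type"].isna().any():
        raise ValueError("every site must be annotated with probe_type")
    if (m.meth.to_numpy() < 0).any() or (m.unmeth.to_numpy() < 0).any():
        raise ValueError("negative intensity")

    sites = m.sites
    t1 = sites.index[sites["probe_type"] == 1]
    t2 = sites.index[sites["probe_type"] == 2]
    t1g = sites.index[(sites["probe_type"] == 1) & (sites["channel"] == "green")]
    t1r = sites.index[(sites["probe_type"] == 1) & (sites["channel"] == "red")]
    if len(t1) and (len(t1g) + len(t1r) != len(t1)):
        raise ValueError("type-1 sites must be annotated with a colour channel")

    meth = m.meth.copy().astype(float)
    unmeth = m.unmeth.copy().astype(float)
    individuals = meth.columns

    # (1a) type 1: across individuals per channel
    for idx in (t1g, t1r):
        if len(idx):
            meth.loc[idx] = quantile_normalize_columns(meth.loc[idx])
            unmeth.loc[idx] = quantile_normalize_columns(unmeth.loc[idx])
    # (1b) between channels within individuals
    if len(t1g) and len(t1r):
        for ind in individuals:
            for mat in (meth, unmeth):
                vg, vr = quantile_normalize_together(
                    [mat.loc[t1g, ind].to_numpy(), mat.loc[t1r, ind].to_numpy()]
                )
                mat.loc[t1g, ind] = vg
                mat.loc[t1r, ind] = vr
    # (2a) type 2: across individuals
    if len(t2):
        meth.loc[t2] = quantile_normalize_columns(meth.loc[t2])
        unmeth.loc[t2] = quantile_normalize_columns(unmeth.loc[t2])
    # (2b) type 2 mapped onto the normalized type-1 reference
    if len(t2) and len(t1):
        for ind in individuals:
            meth.loc[t2, ind] = quantile_map(
                meth.loc[t2, ind].to_numpy(), meth.loc[t1, ind].to_numpy()
            )
            unmeth.loc[t2, ind] = quantile_map(
                unmeth.loc[t2, ind].to_numpy(), unmeth.loc[t1, ind].to_numpy()
            )
    # (3) beta-values
    beta = meth / (meth + unmeth + eps)
    # (4) joint QN of the two probe types per individual
    if len(t1) and len(t2):
        for ind in individuals:
            b1, b2 = quantile_normalize_together(
                [beta.loc[t1, ind].to_numpy(), beta.loc[t2, ind].to_numpy()]
            )
            beta.loc[t1, ind] = b1
            beta.loc[t2, ind] = b2
    beta = beta.clip(0.0, 1.0)
    return MethylationData(sites.copy(), beta=beta, meth=meth, unmeth=unmeth)


def filter_probes(
    m: MethylationData,
    snp_sites: pd.DataFrame | None,
    probe_span_bp: int = 2,
) -> tuple[MethylationData, int]:
    """Drop probes whose assayed interval overlaps any supplied SNP position.

    ``snp_sites`` has columns chrom, pos (the MAF threshold is applied by the
    caller).  The assayed interval defaults to the CpG dinucleotide
    [pos, pos + probe_span_bp).  Returns the filtered data and removal count.
    """
    if snp_sites is None or len(snp_sites) == 0:
        return m, 0
    by_chrom = {
        c: np.sort(sub["pos"].to_numpy()) for c, sub in snp_sites.groupby("chrom")
    }
    drop = []
    for cpg, row in m.sites.iterrows():
        pos_arr = by_chrom.get(row["chrom"])
        if pos_arr is None:
            continue
        lo = np.searchsorted(pos_arr, row["pos"], side="left")
        if lo < pos_arr.size and pos_arr[lo] < row["pos"] + probe_span_bp:
            drop.append(cpg)
    keep = m.sites.index.difference(drop, sort=False)
    filtered = MethylationData(
        m.sites.loc[keep],
        beta=None if m.beta is None else m.beta.loc[keep],
        meth=None if m.meth is None else m.meth.loc[keep],
        unmeth=None if m.unmeth is None else m.unmeth.loc[keep],
    )
    log.info("filter_probes: removed %d probes overlapping SNPs", len(drop))
    return filtered, len(drop)


# ---------------------------------------------------------------------------
# Expression processing
# ---------------------------------------------------------------------------


def _covariate_design(cov: pd.DataFrame) -> np.ndarray:
    """Intercept + continuous covariates + dummy-coded categorical factors."""
    parts = [np.ones((len(cov), 1))]
    parts.append(cov[["mean_gc", "insert_size_mode"]].to_numpy(dtype=float))
    for col in ("run_date", "primer_index"):
        dummies = pd.get_dummies(cov[col], drop_first=True)
        if dummies.shape[1]:
            parts.append(dummies.to_numpy(dtype=float))
    return np.hstack(parts)


def process_expression(
    e: ExpressionData,
    cov: pd.DataFrame,
    min_exonic_reads: float = 5e6,
    zero_fraction_max: float = 0.10,
    scale_to: float = 1e7,
    method: str = "fixed",
) -> tuple[ExpressionData, list[str]]:
    """Sample floor, library scaling, expressed-exon filter, covariate correction.

    Samples with fewer exonic reads than ``min_exonic_reads`` are dropped;
    remaining libraries are scaled to ``scale_to`` total reads (totals taken
    before exon filtering); exons with zero counts in >= ``zero_fraction_max``
    of samples are removed; each exon is then regressed on mean GC content and
    insert-size mode (continuous) with grouped intercepts for run date and
    primer index, and the output is the residual plus the exon's grand mean.

    ``method="mixed"`` fits the categorical factors as random intercepts
    (statsmodels MixedLM variance components) instead of fixed dummies.
    """
    totals = e.counts.sum(axis=0)
    dropped = [s for s in e.counts.columns if totals[s] < min_exonic_reads]
    kept = [s for s in e.counts.columns if s not in set(dropped)]
    if not kept:
        raise ValueError("all samples below the exonic-read floor")
    missing_cov = [s for s in kept if s not in cov.index]
    if missing_cov:
        raise ValueError(f"covariates missing for samples {missing_cov}")
    cov = validate_covariates(cov.loc[kept])
    counts = e.counts[kept]
    scaled = counts * (scale_to / totals[kept])

    zero_frac = (counts == 0).mean(axis=1)
    keep_exons = zero_frac < zero_fraction_max
    scaled = scaled.loc[keep_exons]

    y = scaled.to_numpy(dtype=float)  # exons x samples
    if method == "fixed":
        x = _covariate_design(cov)
        beta, *_ = np.linalg.lstsq(x, y.T, rcond=None)
        resid = y.T - x @ beta
        normalized = resid.T + y.mean(axis=1, keepdims=True)
    elif method == "mixed":
        import statsmodels.formula.api as smf

        normalized = np.empty_like(y)
        data = cov.copy()
        data["one_group"] = 1
        for i in range(y.shape[0]):
            data["y"] = y[i]
            md = smf.mixedlm(
                "y ~ mean_gc + insert_size_mode",
                data,
                groups="one_group",
                vc_formula={"run_date": "0 + C(run_date)", "primer": "0 + C(primer_index)"},
            )
            fit = md.fit(reml=True, method="lbfgs")
            resid = data["y"].to_numpy() - fit.fittedvalues.to_numpy()
            normalized[i] = resid + y[i].mean()
    else:
        raise ValueError("method must be 'fixed' or 'mixed'")

    out = ExpressionData(
        counts=counts.loc[keep_exons],
        exons=e.exons.loc[keep_exons],
        genes=e.genes,
        normalized=pd.DataFrame(
            normalized, index=scaled.index, columns=scaled.columns
        ),
    )
    return out, dropped


def expressed_genes(e: ExpressionData, min_fraction: float = 0.9) -> pd.Index:
    """Genes with at least one exonic read in more than ``min_fraction`` of samples."""
    gene_counts = e.counts.groupby(e.exons["gene_id"]).sum()
    frac = (gene_counts >= 1).mean(axis=1)
    return gene_counts.index[frac > min_fraction]


def rpkm(e: ExpressionData) -> pd.DataFrame:
    """Gene x individual reads per kilobase of merged exon per million exonic reads."""
    lib_millions = e.counts.sum(axis=0) / 1e6
    gene_counts = e.counts.groupby(e.exons["gene_id"]).sum()
    gene_kb = e.exons.groupby("gene_id")["length"].sum() / 1e3
    if (gene_kb <= 0).any():
        raise ValueError("zero-length gene model")
    gene_kb = gene_kb.loc[gene_counts.index]
    return gene_counts.div(gene_kb, axis=0).div(lib_millions, axis=1)
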