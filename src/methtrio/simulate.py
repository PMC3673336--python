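"""Synthetic cohort generator with planted, recorded ground truth.

Emulates a multi-cell-type newborn cohort assayed for genotypes (HWE SNPs),
CpG methylation (logit-normal beta-values with per-cell-type shifts and
planted methylation QTLs), and exon-level RNA-seq counts (negative binomial
with library-size and GC covariates and planted expression QTLs), together
with genomic features (promoters, CpG islands, TF peaks, recombination
intervals) and binomial allelic read counts.  Every planted effect is written
to a truth table so downstream estimators can be scored against it.

All generators are pure functions of (config, seed); each stage derives its
own RNG stream from the global seed plus the stage name, so adding one
generator never perturbs another's draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .datamodel import (
    GenomicInterval,
    GenotypeMatrix,
    ExpressionData,
    GeneModel,
    MethylationData,
)

CELL_TYPES = ("fibroblast", "LCL", "tcell")


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent RNG stream for one generator stage."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(stage.encode())])
    )


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Effect sizes are on the scale of the model that consumes them: mQTL and
    eQTM effects act on the logit of the beta-value, eQTL effects multiply the
    negative-binomial gene mean by exp(beta * dosage).
    """

    n_individuals: int = 100
    n_cell_types: int = 3
    n_genes: int = 100
    exons_per_gene: int = 2
    n_snps: int = 400
    maf_range: tuple[float, float] = (0.1, 0.5)
    n_cpgs: int = 300
    eqtl_beta: float = 1.0
    mqtl_beta: float = 1.0
    eqtm_beta: float = 0.5
    meth_noise_sd: float = 0.5
    nb_dispersion: float = 0.1
    gc_slope: float = 2.0
    fraction_null: float = 0.7
    differentiated_fraction: float = 0.2
    shift_sd: float = 1.0
    triplet_counts: dict = field(
        default_factory=lambda: {"INDEP": 0, "SME": 0, "SEM": 0}
    )
    n_tfs: int = 5
    simulate_intensities: bool = False
    gene_spacing_bp: int = 100_000
    genes_per_chrom: int = 50
    recomb_interval_bp: int = 50_000
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        for name in ("n_individuals", "n_genes", "n_snps", "n_cpgs", "exons_per_gene"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class Cohort:
    """One simulated cohort: shared genotypes, per-cell-type molecular data."""

    genotypes: GenotypeMatrix
    methylation: dict[str, MethylationData]
    expression: dict[str, ExpressionData]
    covariates: dict[str, pd.DataFrame]
    features: dict[str, object]
    truth: pd.DataFrame
    config: SimConfig

    @property
    def cell_types(self) -> list[str]:
        return list(self.expression)


def _hwe_genotypes(rng, n_ind: int, mafs: np.ndarray) -> np.ndarray:
    """Hardy-Weinberg dosages: two independent Bernoulli(maf) alleles."""
    u = rng.random((n_ind, mafs.size, 2))
    return (u < mafs[None, :, None]).sum(axis=2).astype(float)


def _nb_counts(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draws with var = m + dispersion * m^2."""
    if dispersion <= 0:
        return rng.poisson(mean).astype(float)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam).astype(float)


def simulate_cohort(config: SimConfig) -> Cohort:
    """Generate the full synthetic cohort with planted, recorded effects."""
    cfg = config
    seed = cfg.seed
    individuals = pd.Index(
        [f"ind{i:03d}" for i in range(cfg.n_individuals)], name="individual"
    )
    cell_types = list(CELL_TYPES[: cfg.n_cell_types])

    # --- genome layout -----------------------------------------------------
    rng = stage_rng(seed, "layout")
    gene_ids = [f"gene{g:04d}" for g in range(cfg.n_genes)]
    gene_chrom = [f"chr{g // cfg.genes_per_chrom + 1}" for g in range(cfg.n_genes)]
    gene_tss = np.array(
        [100_000 + (g % cfg.genes_per_chrom) * cfg.gene_spacing_bp for g in range(cfg.n_genes)]
    )
    gene_strand = np.where(rng.random(cfg.n_genes) < 0.5, "+", "-")
    exon_len = 200
    genes: dict[str, GeneModel] = {}
    exon_rows = []
    for g, gid in enumerate(gene_ids):
        sgn = 1 if gene_strand[g] == "+" else -1
        units = []
        for k in range(cfg.exons_per_gene):
            s = gene_tss[g] + sgn * (500 + 1000 * k)
            lo, hi = sorted((s, s + sgn * exon_len))
            units.append(GenomicInterval(gene_chrom[g], lo, hi, gene_strand[g]))
            exon_rows.append((f"{gid}_e{k}", gid, gene_chrom[g], lo, hi, hi - lo))
        genes[gid] = GeneModel(gid, int(gene_tss[g]), gene_strand[g], gene_chrom[g], units)
    exons = pd.DataFrame(
        exon_rows, columns=["exon_id", "gene_id", "chrom", "start", "end", "length"]
    ).set_index("exon_id")

    # CpGs: most near a promoter, the rest spread along the chromosome.
    cpg_ids = [f"cg{c:05d}" for c in range(cfg.n_cpgs)]
    owner = rng.integers(0, cfg.n_genes, size=cfg.n_cpgs)
    near = rng.random(cfg.n_cpgs) < 0.7
    offset = np.where(
        near,
        rng.integers(-1000, 2000, size=cfg.n_cpgs),
        rng.integers(-40_000, 40_000, size=cfg.n_cpgs),
    )
    cpg_pos = np.maximum(gene_tss[owner] + offset, 10)
    cpg_chrom = np.array(gene_chrom, dtype=object)[owner]
    probe_type = np.where(rng.random(cfg.n_cpgs) < 0.3, 1, 2)
    channel = np.where(rng.random(cfg.n_cpgs) < 0.5, "green", "red")
    channel = np.where(probe_type == 1, channel, "")
    sites = pd.DataFrame(
        {
            "chrom": cpg_chrom,
            "pos": cpg_pos,
            "probe_type": probe_type,
            "channel": channel,
            "gene_id": np.array(gene_ids, dtype=object)[owner],
        },
        index=pd.Index(cpg_ids, name="cpg_id"),
    )

    # --- planted effect assignment ----------------------------------------
    rng = stage_rng(seed, "truth")
    n_eqtl = int(round((1 - cfg.fraction_null) * cfg.n_genes))
    n_mqtl = int(round((1 - cfg.fraction_null) * cfg.n_cpgs))
    n_eqtm = int(round((1 - cfg.fraction_null) * 0.5 * cfg.n_genes))
    n_planted_snps = n_eqtl + n_mqtl
    if n_planted_snps > cfg.n_snps:
        raise ValueError(
            f"more planted effects ({n_planted_snps}) than SNPs ({cfg.n_snps})"
        )
    eqtl_genes = rng.choice(cfg.n_genes, size=n_eqtl, replace=False)
    mqtl_cpgs = rng.choice(cfg.n_cpgs, size=n_mqtl, replace=False)
    # eQTM genes drawn among genes, linked to a promoter CpG of that gene that
    # carries no mQTL (so the eQTM is a methylation->expression coupling only).
    free_cpgs = np.setdiff1d(np.arange(cfg.n_cpgs), mqtl_cpgs)
    eqtm_pairs = []
    used = set()
    order = rng.permutation(free_cpgs)
    for c in order:
        g = owner[c]
        if g in used:
            continue
        used.add(g)
        eqtm_pairs.append((c, g))
        if len(eqtm_pairs) >= n_eqtm:
            break

    # SNP placement: one dedicated SNP per planted eQTL (within 1 Mb of the
    # TSS) and per planted mQTL (within 5 kb of the CpG); the rest background.
    snp_rows = []
    truth_rows = []
    for j, g in enumerate(eqtl_genes):
        pos = int(gene_tss[g] + rng.integers(-200_000, 200_000))
        snp_rows.append((f"snp{j:05d}", gene_chrom[g], max(pos, 1)))
        truth_rows.append(("eQTL", f"snp{j:05d}", gene_ids[g], cfg.eqtl_beta, "", ""))
    for j, c in enumerate(mqtl_cpgs, start=n_eqtl):
        pos = int(cpg_pos[c] + rng.integers(-4000, 4000))
        snp_rows.append((f"snp{j:05d}", cpg_chrom[c], max(pos, 1)))
        truth_rows.append(("mQTL", f"snp{j:05d}", cpg_ids[c], cfg.mqtl_beta, "", ""))
    for j in range(n_planted_snps, cfg.n_snps):
        g = int(rng.integers(0, cfg.n_genes))
        pos = int(gene_tss[g] + rng.integers(-500_000, 500_000))
        snp_rows.append((f"snp{j:05d}", gene_chrom[g], max(pos, 1)))
    snps = pd.DataFrame(snp_rows, columns=["snp_id", "chrom", "pos"]).set_index("snp_id")
    snps["ref"] = "A"
    snps["alt"] = "G"
    eqtm_signs = rng.random(len(eqtm_pairs)) < 0.5
    for (c, g), pos_sign in zip(eqtm_pairs, eqtm_signs):
        truth_rows.append(
            (
                "eQTM",
                cpg_ids[c],
                gene_ids[g],
                cfg.eqtm_beta * (1 if pos_sign else -1),
                "SME",
                "pos" if pos_sign else "neg",
            )
        )

    # --- genotypes ---------------------------------------------------------
    rng = stage_rng(seed, "genotypes")
    lo, hi = cfg.maf_range
    mafs = rng.uniform(lo, hi, size=cfg.n_snps)
    dosage = _hwe_genotypes(rng, cfg.n_individuals, mafs)
    genotypes = GenotypeMatrix(
        pd.DataFrame(dosage, index=individuals, columns=snps.index), snps
    )

    # --- methylation -------------------------------------------------------
    rng = stage_rng(seed, "methylation")
    base_mu = np.where(rng.random(cfg.n_cpgs) < 0.5, -2.0, 2.0) + rng.normal(
        0, 0.5, cfg.n_cpgs
    )
    differentiated = rng.random(cfg.n_cpgs) < cfg.differentiated_fraction
    shifts = {
        ct: np.where(differentiated, rng.normal(0, cfg.shift_sd, cfg.n_cpgs), 0.0)
        for ct in cell_types
    }
    for c in np.where(differentiated)[0]:
        truth_rows.append(("differentiated", cpg_ids[c], "", cfg.shift_sd, "", ""))
    mqtl_effect = np.zeros(cfg.n_cpgs)
    mqtl_snp = np.full(cfg.n_cpgs, -1)
    for j, c in enumerate(mqtl_cpgs, start=n_eqtl):
        mqtl_effect[c] = cfg.mqtl_beta
        mqtl_snp[c] = j
    latent = {}
    methylation = {}
    for ct in cell_types:
        z = (
            base_mu[None, :]
            + shifts[ct][None, :]
            + rng.normal(0, cfg.meth_noise_sd, (cfg.n_individuals, cfg.n_cpgs))
        )
        has = mqtl_snp >= 0
        z[:, has] += mqtl_effect[has][None, :] * dosage[:, mqtl_snp[has]]
        latent[ct] = z
        beta = pd.DataFrame(
            expit(z).T, index=sites.index, columns=individuals
        )
        if cfg.simulate_intensities:
            meth, unmeth = _intensities(rng, expit(z).T, sites)
            methylation[ct] = MethylationData(
                sites.copy(), beta=beta, meth=meth, unmeth=unmeth
            )
        else:
            methylation[ct] = MethylationData(sites.copy(), beta=beta)

    # --- expression --------------------------------------------------------
    rng = stage_rng(seed, "expression")
    gene_log_mean = rng.normal(np.log(50), 0.8, cfg.n_genes)
    exon_factor = rng.normal(0, 0.3, (cfg.n_genes, cfg.exons_per_gene))
    eqtl_effect = np.zeros(cfg.n_genes)
    eqtl_snp = np.full(cfg.n_genes, -1)
    for j, g in enumerate(eqtl_genes):
        eqtl_effect[g] = cfg.eqtl_beta
        eqtl_snp[g] = j
    eqtm_gene_cpg = {g: c for c, g in eqtm_pairs}
    eqtm_sign_by_gene = {
        g: (1.0 if s else -1.0) for (c, g), s in zip(eqtm_pairs, eqtm_signs)
    }
    expression = {}
    covariates = {}
    for ct in cell_types:
        mean_gc = rng.normal(0.45, 0.02, cfg.n_individuals)
        run_date = rng.choice(["d1", "d2", "d3"], cfg.n_individuals)
        primer_index = rng.choice([f"p{i}" for i in range(6)], cfg.n_individuals)
        insert_size = rng.normal(200, 10, cfg.n_individuals).round().astype(int)
        lib_factor = np.exp(rng.normal(0, 0.2, cfg.n_individuals))
        cov = pd.DataFrame(
            {
                "mean_gc": mean_gc,
                "run_date": run_date,
                "primer_index": primer_index,
                "insert_size_mode": insert_size,
            },
            index=individuals,
        )
        covariates[ct] = cov
        # per-individual per-gene log mean
        lm = gene_log_mean[None, :] + cfg.gc_slope * (mean_gc[:, None] - 0.45)
        has = eqtl_snp >= 0
        lm[:, has] = lm[:, has] + eqtl_effect[has][None, :] * dosage[:, eqtl_snp[has]]
        for g, c in eqtm_gene_cpg.items():
            centered = latent[ct][:, c] - latent[ct][:, c].mean()
            lm[:, g] = lm[:, g] + eqtm_sign_by_gene[g] * abs(cfg.eqtm_beta) * centered
        # rows are gene-major (gene0_e0, gene0_e1, gene1_e0, ...), matching the
        # exon annotation order: row g*epg + k is exon k of gene g.
        counts = np.empty((cfg.n_genes * cfg.exons_per_gene, cfg.n_individuals))
        for k in range(cfg.exons_per_gene):
            mean = np.exp(lm + exon_factor[:, k][None, :]) * lib_factor[:, None]
            counts[k :: cfg.exons_per_gene, :] = _nb_counts(
                rng, mean, cfg.nb_dispersion
            ).T
        expression[ct] = ExpressionData(
            pd.DataFrame(counts, index=exons.index, columns=individuals),
            exons.copy(),
            genes,
        )

    # --- genomic features --------------------------------------------------
    rng = stage_rng(seed, "features")
    promoters, cgis = [], []
    for g, gid in enumerate(gene_ids):
        tss = int(gene_tss[g])
        if gene_strand[g] == "+":
            promoters.append(GenomicInterval(gene_chrom[g], max(tss - 1000, 0), tss + 2000, "+"))
        else:
            promoters.append(GenomicInterval(gene_chrom[g], max(tss - 2000, 0), tss + 1000, "-"))
        if rng.random() < 0.6:
            cgis.append(GenomicInterval(gene_chrom[g], max(tss - 500, 0), tss + 500))
    tf_peaks = {}
    for t in range(cfg.n_tfs):
        picks = rng.choice(cfg.n_cpgs, size=max(cfg.n_cpgs // 10, 1), replace=False)
        tf_peaks[f"TF{t}"] = [
            GenomicInterval(cpg_chrom[c], max(int(cpg_pos[c]) - 150, 0), int(cpg_pos[c]) + 150)
            for c in picks
        ]
    chrom_names = sorted(set(gene_chrom), key=lambda c: int(c[3:]))
    recomb = []
    for chrom in chrom_names:
        span = 200_000 + cfg.genes_per_chrom * cfg.gene_spacing_bp
        for s in range(0, span, cfg.recomb_interval_bp):
            recomb.append(GenomicInterval(chrom, s, s + cfg.recomb_interval_bp))
    enhancers = [
        GenomicInterval(
            gene_chrom[g], int(gene_tss[g]) + 5000, int(gene_tss[g]) + 6000
        )
        for g in rng.choice(cfg.n_genes, size=cfg.n_genes // 4 or 1, replace=False)
    ]
    ctcf = [
        GenomicInterval(
            gene_chrom[g], max(int(gene_tss[g]) - 3000, 0), max(int(gene_tss[g]) - 2600, 1)
        )
        for g in rng.choice(cfg.n_genes, size=cfg.n_genes // 4 or 1, replace=False)
    ]
    features = {
        "promoter": promoters,
        "CGI": cgis,
        "enhancer": enhancers,
        "CTCF": ctcf,
        "recombination": recomb,
        "tf_peaks": tf_peaks,
    }

    truth = pd.DataFrame(
        truth_rows,
        columns=["type", "feature_id", "target_id", "effect", "model", "sign"],
    )
    return Cohort(genotypes, methylation, expression, covariates, features, truth, cfg)


def _intensities(rng, beta: np.ndarray, sites: pd.DataFrame):
    """Raw (M, U) fluorescence with probe-type/channel affine distortions."""
    n_sites, n_ind = beta.shape
    total = rng.lognormal(np.log(5000), 0.3, size=(n_sites, n_ind))
    m_true = beta * total
    u_true = (1 - beta) * total
    gains = {(1, "green"): (1.0, 0.0), (1, "red"): (1.3, 100.0),
             (2, "green"): (0.9, 50.0), (2, "red"): (1.25, 80.0)}
    m_obs = np.empty_like(m_true)
    u_obs = np.empty_like(u_true)
    ptype = sites["probe_type"].to_numpy()
    chan = sites["channel"].to_numpy()
    for i in range(n_sites):
        if ptype[i] == 1:
            gm = gu = gains[(1, chan[i])]
        else:
            gm, gu = gains[(2, "green")], gains[(2, "red")]
        m_obs[i] = gm[0] * m_true[i] + gm[1]
        u_obs[i] = gu[0] * u_true[i] + gu[1]
    idx, cols = sites.index, [f"ind{i:03d}" for i in range(n_ind)]
    return (
        pd.DataFrame(m_obs, index=idx, columns=cols),
        pd.DataFrame(u_obs, index=idx, columns=cols),
    )


# ---------------------------------------------------------------------------
# Causal triplets
# ---------------------------------------------------------------------------

TRIPLET_MODELS = ("INDEP", "SME", "SEM")


@dataclass
class SimTriplets:
    """Simulated (S, M, E) triplets, one row per triplet, columns=individuals."""

    s: np.ndarray
    m: np.ndarray
    e: np.ndarray
    truth: pd.DataFrame


def simulate_triplets(
    model: str,
    n: int,
    betas: tuple[float, float] = (1.0, 1.0),
    noise_sd: float = 0.5,
    seed: int = 0,
    n_triplets: int = 1,
    maf: float = 0.3,
) -> SimTriplets:
    """Triplets under one of the three causal structures.

    INDEP: M = b1*S + e1 and E = b2*S + e2 with independent Gaussian noise;
    SME:   M = b1*S + e1, E = b2*M + e2 (methylation mediates);
    SEM:   E = b1*S + e1, M = b2*E + e2 (expression mediates).
    S ~ Binomial(2, maf).
    """
    if model not in TRIPLET_MODELS:
        raise ValueError(f"model must be one of {TRIPLET_MODELS}")
    if n < 10:
        raise ValueError("n must be >= 10")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive (zero-variance inputs)")
    b1, b2 = betas
    rng = stage_rng(seed, f"triplets-{model}")
    s = rng.binomial(2, maf, size=(n_triplets, n)).astype(float)
    # guard against constant genotype draws at small n
    for i in range(n_triplets):
        while s[i].std() == 0:
            s[i] = rng.binomial(2, maf, size=n)
    e1 = rng.normal(0, noise_sd, (n_triplets, n))
    e2 = rng.normal(0, noise_sd, (n_triplets, n))
    if model == "INDEP":
        m = b1 * s + e1
        e = b2 * s + e2
    elif model == "SME":
        m = b1 * s + e1
        e = b2 * m + e2
    else:  # SEM
        e = b1 * s + e1
        m = b2 * e + e2
    truth = pd.DataFrame(
        {
            "triplet": [f"{model}_{i}" for i in range(n_triplets)],
            "type": model,
            "b1": b1,
            "b2": b2,
            "noise_sd": noise_sd,
            "model": model,
        }
    )
    return SimTriplets(s, m, e, truth)


# ---------------------------------------------------------------------------
# Allelic read counts
# ---------------------------------------------------------------------------


def simulate_allelic_counts(
    n_sites: int,
    n_individuals: int,
    skew_map: dict | None = None,
    coverage_nb_params: tuple[float, float] = (40.0, 0.3),
    bias_map: dict | None = None,
    seed: int = 0,
    n_cell_types: int = 1,
    individual_bias_sd: float = 0.005,
):
    """Binomial reference/alternate read counts at heterozygous sites.

    ``skew_map`` maps (site, individual) or site index to the reference-allele
    probability (default 0.5 everywhere); ``bias_map`` maps site index to a
    (mapability, sim_bias) pair so alignment-bias filters can be exercised.
    Returns (counts, sites): a long table with one row per
    site x individual x cell type, and per-site metadata.
    """
    skew_map = skew_map or {}
    bias_map = bias_map or {}
    rng = stage_rng(seed, "allelic")
    mean_cov, disp = coverage_nb_params
    site_ids = [f"ase{s:04d}" for s in range(n_sites)]
    ind_ids = [f"ind{i:03d}" for i in range(n_individuals)]
    ind_bias = rng.normal(0, individual_bias_sd, n_individuals)
    rows = []
    for ct in range(n_cell_types):
        cell = f"ct{ct}"
        for s in range(n_sites):
            for i in range(n_individuals):
                total = int(_nb_counts(rng, np.array([mean_cov]), disp)[0])
                skew = skew_map.get((s, i), skew_map.get(s, 0.5))
                p = min(max(skew + ind_bias[i], 1e-3), 1 - 1e-3)
                ref = int(rng.binomial(total, p)) if total > 0 else 0
                rows.append((site_ids[s], ind_ids[i], cell, ref, total - ref))
    counts = pd.DataFrame(
        rows, columns=["site_id", "individual", "cell_type", "ref", "alt"]
    )
    counts["coverage"] = counts["ref"] + counts["alt"]
    meta = []
    for s in range(n_sites):
        mapability, sim_bias = bias_map.get(s, (1.0, 0.0))
        meta.append((site_ids[s], "chr1", 1000 + 500 * s, "A", "G", mapability, sim_bias))
    sites = pd.DataFrame(
        meta,
        columns=["site_id", "chrom", "pos", "ref_allele", "alt_allele", "mapability", "sim_bias"],
    ).set_index("site_id")
    return counts, sites
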