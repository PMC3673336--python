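"""Cell-type differentiation of methylation and genomic-context enrichment.

The differentiation metric is the coefficient of variation of a CpG site's
per-cell-type median beta-values — a between-cell-type variability measure
that controls for the mean methylation level.  Enrichment analyses compare
significant association sets against covariate-matched null pairs or against
non-associated sites, with Fisher exact tests.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .association import spearman_test
from .datamodel import intersect_features

log = logging.getLogger(__name__)


def differentiation_cv(beta_by_cell_type: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-site coefficient of variation of per-cell-type median beta.

    cv = sd(medians, n-1 denominator) / mean(medians); sites where the mean of
    the medians is zero get NaN (undefined marker).
    """
    if len(beta_by_cell_type) < 2:
        raise ValueError("need >= 2 cell types")
    for ct, b in beta_by_cell_type.items():
        if b.shape[1] < 3:
            raise ValueError(f"cell type {ct} has fewer than 3 individuals")
    medians = pd.DataFrame(
        {ct: b.median(axis=1) for ct, b in beta_by_cell_type.items()}
    )
    mean = medians.mean(axis=1)
    sd = medians.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = sd / mean
    cv = cv.where(mean != 0)
    out = medians.add_prefix("median_")
    out["cv"] = cv
    return out


def decile_enrichment(
    scores: pd.Series, flags: pd.Series, n_bins: int = 10
) -> tuple[pd.DataFrame, float]:
    """Proportion of flagged sites per differentiation decile + Wilcoxon p.

    Sites are ranked by score into ``n_bins`` equal-count bins; the returned
    p-value is the two-sided rank-sum comparison of scores between flagged
    and unflagged sites.
    """
    scores = scores.dropna()
    flags = flags.loc[scores.index].astype(bool)
    if len(scores) < n_bins:
        raise ValueError(f"need >= {n_bins} sites")
    ranks = stats.rankdata(scores.to_numpy(), method="average")
    bins = np.minimum((ranks - 1) / len(scores) * n_bins, n_bins - 1).astype(int)
    table = (
        pd.DataFrame({"bin": bins + 1, "flag": flags.to_numpy()})
        .groupby("bin")["flag"]
        .agg(proportion="mean", n="size")
        .reset_index()
    )
    if flags.any() and (~flags).any():
        p = float(
            stats.mannwhitneyu(
                scores[flags], scores[~flags], alternative="two-sided"
            ).pvalue
        )
    else:
        p = float("nan")
    return table, p


# ---------------------------------------------------------------------------
# Matched-null feature enrichment
# ---------------------------------------------------------------------------


def _strata(df: pd.DataFrame, match_on, pooled: pd.DataFrame, bins: dict) -> pd.Series:
    """Joint stratum label from binned matching covariates."""
    labels = pd.Series("", index=df.index)
    for cov in match_on:
        edges = bins[cov]
        idx = np.clip(
            np.searchsorted(edges, df[cov].to_numpy(), side="right") - 1,
            0,
            len(edges) - 2,
        )
        labels = labels + "|" + idx.astype(str)
    return labels


def _bin_edges(pooled: pd.DataFrame, match_on, n_bins: dict) -> dict:
    edges = {}
    for cov in match_on:
        v = pooled[cov].to_numpy(dtype=float)
        if cov == "maf":
            edges[cov] = np.arange(0.0, 0.5 + 1e-9, 0.5 / n_bins.get(cov, 10))
        elif cov == "distance":
            a = np.abs(v) + 1.0
            edges[cov] = np.exp(
                np.linspace(np.log(a.min()), np.log(a.max()) + 1e-9, n_bins.get(cov, 10) + 1)
            )
        else:
            qs = np.quantile(v, np.linspace(0, 1, n_bins.get(cov, 10) + 1))
            edges[cov] = np.unique(qs)
            if len(edges[cov]) < 2:
                edges[cov] = np.array([v.min() - 1, v.max() + 1])
    return edges


def sample_matched_null(
    significant: pd.DataFrame,
    null_pool: pd.DataFrame,
    match_on=("maf", "distance", "level"),
    n_bins: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample one null pair per significant pair from matching covariate strata.

    Strata are joint bins of the matching covariates (MAF in 5% bins,
    |distance| in log-spaced bins, phenotype level in deciles by default).
    Empty strata fall back to coarser (halved) bins, then to the full pool,
    with a log entry.  With ``match_on`` empty this is simple random sampling.
    """
    rng = np.random.default_rng(seed)
    if not match_on:
        take = rng.choice(null_pool.index, size=len(significant), replace=True)
        return null_pool.loc[take]
    n_bins = dict(n_bins or {"maf": 10, "distance": 10, "level": 10})
    pooled = pd.concat([significant, null_pool])
    edges = _bin_edges(pooled, match_on, n_bins)
    sig_strata = _strata(significant, match_on, pooled, edges)
    null_strata = _strata(null_pool, match_on, pooled, edges)
    coarse_bins = {k: max(v // 2, 1) for k, v in n_bins.items()}
    coarse_edges = _bin_edges(pooled, match_on, coarse_bins)
    sig_coarse = _strata(significant, match_on, pooled, coarse_edges)
    null_coarse = _strata(null_pool, match_on, pooled, coarse_edges)
    groups = {s: idx.to_numpy() for s, idx in null_pool.groupby(null_strata).groups.items()}
    groups_c = {s: idx.to_numpy() for s, idx in null_pool.groupby(null_coarse).groups.items()}
    picks = []
    n_coarsened = 0
    for i in significant.index:
        pool = groups.get(sig_strata[i])
        if pool is None or len(pool) == 0:
            pool = groups_c.get(sig_coarse[i])
            n_coarsened += 1
        if pool is None or len(pool) == 0:
            pool = null_pool.index.to_numpy()
        picks.append(rng.choice(pool))
    if n_coarsened:
        log.info("sample_matched_null: %d strata coarsened", n_coarsened)
    return null_pool.loc[picks]


def matched_null_enrichment(
    significant: pd.DataFrame,
    null_pool: pd.DataFrame,
    features: dict[str, list],
    match_on=("maf", "distance", "level"),
    n_bins: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Odds ratio and Fisher exact p per feature class, vs a matched null.

    ``significant`` and ``null_pool`` carry one row per pair with the pair's
    genomic anchor (chrom, pos) and the matching covariates.  The 2x2 table
    per feature is (significant vs matched null) x (overlapping vs not).
    """
    null = sample_matched_null(significant, null_pool, match_on, n_bins, seed)
    rows = []
    for name, ivs in features.items():
        sig_in = int(intersect_features(significant, ivs).sum())
        null_in = int(intersect_features(null, ivs).sum())
        table = [
            [sig_in, len(significant) - sig_in],
            [null_in, len(null) - null_in],
        ]
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append((name, sig_in, len(significant), null_in, len(null), odds, p))
    return pd.DataFrame(
        rows,
        columns=["feature", "sig_in", "sig_n", "null_in", "null_n", "odds_ratio", "p"],
    )


def eqtm_sign_context(
    pos_sites: pd.DataFrame,
    neg_sites: pd.DataFrame,
    non_eqtm_sites: pd.DataFrame,
    features: dict[str, list],
) -> pd.DataFrame:
    """Overlap of positive/negative eQTM sites vs the non-eQTM expectation.

    For each feature class, the overlap proportion of pos-eQTM, neg-eQTM and
    non-eQTM (expected) sites, with Fisher tests of pos vs expected and neg
    vs expected.
    """
    rows = []
    for name, ivs in features.items():
        counts = {}
        for label, sites in (
            ("pos", pos_sites),
            ("neg", neg_sites),
            ("expected", non_eqtm_sites),
        ):
            inside = int(intersect_features(sites, ivs).sum()) if len(sites) else 0
            counts[label] = (inside, len(sites))
        def fisher(a, b):
            table = [[a[0], a[1] - a[0]], [b[0], b[1] - b[0]]]
            if a[1] == 0 or b[1] == 0:
                return float("nan"), float("nan")
            return stats.fisher_exact(table, alternative="two-sided")
        or_pos, p_pos = fisher(counts["pos"], counts["expected"])
        or_neg, p_neg = fisher(counts["neg"], counts["expected"])
        rows.append(
            (
                name,
                counts["pos"][0] / counts["pos"][1] if counts["pos"][1] else np.nan,
                counts["neg"][0] / counts["neg"][1] if counts["neg"][1] else np.nan,
                counts["expected"][0] / counts["expected"][1]
                if counts["expected"][1]
                else np.nan,
                or_pos,
                p_pos,
                or_neg,
                p_neg,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "feature",
            "prop_pos",
            "prop_neg",
            "prop_expected",
            "or_pos",
            "p_pos",
            "or_neg",
            "p_neg",
        ],
    )


def promoter_methylation_vs_expression(
    beta: pd.DataFrame,
    rpkm: pd.DataFrame,
    site_gene: pd.Series,
    expressed_genes=None,
    eqtm_sign: pd.Series | None = None,
) -> dict:
    """Promoter methylation vs expression, across genes.

    Per individual: Spearman of (median promoter beta per gene) against the
    gene's RPKM over expressed genes.  When eQTM signs are supplied, also the
    across-gene Spearman of across-individual median beta vs median RPKM,
    separately for positive and negative eQTM sites.  Genes without promoter
    probes are excluded; fewer than 2 genes yields a no-test marker (NaN).
    """
    site_gene = site_gene.dropna()
    sites = beta.index.intersection(site_gene.index)
    site_gene = site_gene.loc[sites]
    gene_beta = beta.loc[sites].groupby(site_gene).median()
    genes = gene_beta.index.intersection(rpkm.index)
    if expressed_genes is not None:
        genes = genes.intersection(pd.Index(expressed_genes))
    gene_beta = gene_beta.loc[genes]
    expr = rpkm.loc[genes]
    per_individual = {}
    common = gene_beta.columns.intersection(expr.columns)
    for ind in common:
        if len(genes) < 2:
            per_individual[ind] = (float("nan"), float("nan"))
            continue
        per_individual[ind] = spearman_test(gene_beta[ind], expr[ind])
    out = {
        "per_individual": pd.DataFrame(
            per_individual, index=["rho", "p"]
        ).T.rename_axis("individual")
    }
    if eqtm_sign is not None:
        by_sign = {}
        med_beta = beta.median(axis=1)
        med_rpkm = rpkm.median(axis=1)
        for sign in ("pos", "neg"):
            s = eqtm_sign.index[eqtm_sign == sign]
            s = s.intersection(site_gene.index)
            g = site_gene.loc[s]
            ok = g.isin(med_rpkm.index)
            s, g = s[ok], g[ok]
            if len(s) < 8:
                by_sign[sign] = (float("nan"), float("nan"), len(s))
                continue
            rho, p = spearman_test(med_beta.loc[s], med_rpkm.loc[g].to_numpy())
            by_sign[sign] = (rho, p, len(s))
        out["by_sign"] = by_sign
    return out
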