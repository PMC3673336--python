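"""Interaction effects: SNP x methylation on expression, TF abundance on
methylation, and SNP x TF abundance on methylation.

The interaction model is ordinary least squares with a product term,
expr ~ snp + meth + snp*meth (variables mean-centered before forming the
product to tame collinearity; the product-term t test is unchanged by the
centering).  Enrichment of true interactions over the whole triplet set is
quantified by Storey's pi1 with a permutation null: expression is permuted
jointly across triplets, a pi1 is computed per round, and the observed pi1 is
located in that null distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import pi1_fixed_lambda, qvalues, spearman_test, storey_pi1
from .datamodel import intersect_features

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# The interaction test
# ---------------------------------------------------------------------------


def interaction_test(
    expr, snp, meth, center: bool = True
) -> tuple[float, float, float]:
    """OLS of expr on {snp, meth, snp*meth}; two-sided t test on the product.

    Returns (beta_interaction, t, p); a collinear design yields NaNs
    (no-test marker).  Requires >= 20 complete cases.
    """
    y = np.asarray(expr, dtype=float)
    s = np.asarray(snp, dtype=float)
    m = np.asarray(meth, dtype=float)
    ok = ~(np.isnan(y) | np.isnan(s) | np.isnan(m))
    y, s, m = y[ok], s[ok], m[ok]
    n = y.size
    if n < 20:
        raise ValueError(f"need >= 20 complete cases, got {n}")
    if center:
        s = s - s.mean()
        m = m - m.mean()
    x = np.column_stack([np.ones(n), s, m, s * m])
    if np.linalg.matrix_rank(x) < 4:
        return float("nan"), float("nan"), float("nan")
    g = np.linalg.inv(x.T @ x)
    beta = g @ x.T @ y
    resid = y - x @ beta
    dof = n - 4
    s2 = resid @ resid / dof
    se = np.sqrt(s2 * g[3, 3])
    t = beta[3] / se if se > 0 else float("nan")
    p = 2.0 * stats.t.sf(abs(t), dof) if np.isfinite(t) else float("nan")
    return float(beta[3]), float(t), float(p)


@dataclass
class InteractionBatch:
    """Aligned triplet arrays (rows = triplets, columns = individuals)."""

    expr: np.ndarray
    snp: np.ndarray
    meth: np.ndarray

    def __post_init__(self):
        if not (self.expr.shape == self.snp.shape == self.meth.shape):
            raise ValueError("expr, snp, meth must share a shape")

    @property
    def n_triplets(self) -> int:
        return self.expr.shape[0]


def _batch_product_p(batch: InteractionBatch, y: np.ndarray) -> np.ndarray:
    """Product-term p per triplet for an (T x n) expression matrix ``y``."""
    t_n, n = batch.snp.shape
    s = batch.snp - batch.snp.mean(axis=1, keepdims=True)
    m = batch.meth - batch.meth.mean(axis=1, keepdims=True)
    ps = np.empty(t_n)
    for i in range(t_n):
        x = np.column_stack([np.ones(n), s[i], m[i], s[i] * m[i]])
        try:
            g = np.linalg.inv(x.T @ x)
        except np.linalg.LinAlgError:
            ps[i] = np.nan
            continue
        beta = g @ x.T @ y[i]
        resid = y[i] - x @ beta
        s2 = resid @ resid / (n - 4)
        se = np.sqrt(s2 * g[3, 3])
        tval = beta[3] / se if se > 0 else np.nan
        ps[i] = 2.0 * stats.t.sf(abs(tval), n - 4) if np.isfinite(tval) else np.nan
    return ps


def _precompute_designs(batch: InteractionBatch):
    """Per-triplet hat matrix and product-coefficient row for fast permutation."""
    t_n, n = batch.snp.shape
    s = batch.snp - batch.snp.mean(axis=1, keepdims=True)
    m = batch.meth - batch.meth.mean(axis=1, keepdims=True)
    hats = np.empty((t_n, n, n))
    a_rows = np.empty((t_n, n))
    c = np.empty(t_n)
    for i in range(t_n):
        x = np.column_stack([np.ones(n), s[i], m[i], s[i] * m[i]])
        g = np.linalg.pinv(x.T @ x)
        a = g @ x.T
        hats[i] = x @ a
        a_rows[i] = a[3]
        c[i] = g[3, 3]
    return hats, a_rows, c


def _perm_product_p(hats, a_rows, c, yp: np.ndarray) -> np.ndarray:
    """Vectorized product-term p for permuted expression ``yp`` (T x B x n)."""
    t_n, b, n = yp.shape
    beta3 = np.einsum("tn,tbn->tb", a_rows, yp)
    fitted = np.matmul(yp, hats.transpose(0, 2, 1))  # (T, B, n)
    sse = np.einsum("tbn,tbn->tb", yp, yp) - np.einsum("tbn,tbn->tb", yp, fitted)
    s2 = np.maximum(sse, 0.0) / (n - 4)
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = beta3 / np.sqrt(s2 * c[:, None])
    return 2.0 * stats.t.sf(np.abs(tval), n - 4)


def _pi1_raw(pvalues, lam: float = 0.5) -> float:
    """Unclipped fixed-lambda pi1 (permutation comparison statistic)."""
    p = np.asarray(pvalues, dtype=float)
    p = p[~np.isnan(p)]
    return float(1.0 - np.sum(p > lam) / ((1 - lam) * p.size))


@dataclass
class Pi1Envelope:
    observed_pi1: float
    null_pi1: np.ndarray
    empirical_p: float
    qq_bands: pd.DataFrame  # rank, expected, lo05, hi95
    observed_p: np.ndarray


def permutation_pi1_envelope(
    batch: InteractionBatch,
    n_perm: int = 1000,
    seed: int = 0,
    full_smoother_in_null: bool = False,
) -> Pi1Envelope:
    """Observed pi1 of interaction p-values vs a joint-permutation null.

    Expression vectors are permuted jointly (one individual-label permutation
    per round across all triplets); each round yields a pi1, giving a null
    pi1 distribution, an empirical p = (1 + #{null >= observed}) / (B + 1),
    and pointwise 5%/95% order-statistic bands for QQ plotting.  The null
    rounds use the fast fixed-lambda pi1 estimator unless
    ``full_smoother_in_null`` is set; the observed pi1 always uses the full
    smoother when enough tests are available.
    """
    if batch.n_triplets < 100:
        raise ValueError("need >= 100 triplets")
    rng = np.random.default_rng(seed)
    obs_p = _batch_product_p(batch, batch.expr)
    valid = obs_p[~np.isnan(obs_p)]
    observed_pi1 = storey_pi1(valid)[1] if valid.size >= 100 else pi1_fixed_lambda(valid)
    hats, a_rows, c = _precompute_designs(batch)
    n = batch.expr.shape[1]
    perm_idx = np.array([rng.permutation(n) for _ in range(n_perm)])
    # permutations processed in chunks to bound the (T, chunk, n) workspace
    chunk = max(1, int(5e7 / (batch.n_triplets * n)))
    parts = []
    for b0 in range(0, n_perm, chunk):
        yp = batch.expr[:, perm_idx[b0 : b0 + chunk]]  # (T, b, n)
        parts.append(_perm_product_p(hats, a_rows, c, yp))
    null_p = np.concatenate(parts, axis=1)  # (T, B)
    if full_smoother_in_null:
        null_pi1 = np.array([storey_pi1(null_p[:, b])[1] for b in range(n_perm)])
    else:
        null_pi1 = np.array([pi1_fixed_lambda(null_p[:, b]) for b in range(n_perm)])
    # the empirical p compares exchangeable raw (unclipped, fixed-lambda)
    # statistics on both sides; clipping to [0, 1] would pile observed and
    # null estimates onto an atom at zero and break uniformity under the null
    obs_raw = _pi1_raw(valid)
    null_raw = np.array([_pi1_raw(null_p[:, b]) for b in range(n_perm)])
    empirical_p = (1 + np.sum(null_raw >= obs_raw)) / (n_perm + 1)
    sorted_null = np.sort(null_p, axis=0)  # per round
    lo = np.quantile(sorted_null, 0.05, axis=1)
    hi = np.quantile(sorted_null, 0.95, axis=1)
    t_n = batch.n_triplets
    qq = pd.DataFrame(
        {
            "rank": np.arange(1, t_n + 1),
            "expected": (np.arange(1, t_n + 1) - 0.5) / t_n,
            "lo05": lo,
            "hi95": hi,
        }
    )
    return Pi1Envelope(float(observed_pi1), null_pi1, float(empirical_p), qq, obs_p)


# ---------------------------------------------------------------------------
# Triplet selection
# ---------------------------------------------------------------------------


def minor_hom_count(dosage: np.ndarray) -> int:
    """Number of individuals homozygous for the minor allele."""
    d = np.asarray(dosage, dtype=float)
    d = d[~np.isnan(d)]
    n_ref_hom = int(np.sum(d == 0))
    n_alt_hom = int(np.sum(d == 2))
    p_alt = d.mean() / 2 if d.size else 0.0
    return n_alt_hom if p_alt <= 0.5 else n_ref_hom


def _interval_index(positions: pd.DataFrame, intervals) -> pd.Series:
    """Index of the recombination interval containing each position (-1 if none)."""
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for i, iv in enumerate(intervals):
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, i))
    for c in by_chrom:
        by_chrom[c].sort()
    out = np.full(len(positions), -1)
    for row_i, (chrom, pos) in enumerate(zip(positions["chrom"], positions["pos"])):
        ivs = by_chrom.get(chrom, [])
        starts = [s for s, _, _ in ivs]
        j = np.searchsorted(starts, pos, side="right") - 1
        if j >= 0 and pos < ivs[j][1]:
            out[row_i] = ivs[j][2]
    return pd.Series(out, index=positions.index)


def select_interaction_triplets(
    eqtl_records: pd.DataFrame,
    eqtm_records: pd.DataFrame,
    genotypes,
    beta: pd.DataFrame,
    recomb_intervals=None,
    eqtl_p_max: float = 1e-4,
    eqtm_p_max: float = 1e-3,
    snp_meth_p_min: float = 0.05,
    min_minor_homs: int = 4,
) -> pd.DataFrame:
    """Exon-SNP-CpG triplets for the synergistic-interaction scan.

    Per exon: every eQTL SNP with p < ``eqtl_p_max``, thinned to the best SNP
    per independent recombination interval, crossed with every eQTM CpG of
    that exon with p < ``eqtm_p_max``.  Triplets where the SNP and the
    methylation site correlate (Spearman p < 0.05) or where fewer than four
    individuals are homozygous for the SNP's minor allele are removed.
    """
    if recomb_intervals is None:
        log.warning("no recombination intervals supplied: each SNP its own interval")
    eqtl = eqtl_records[eqtl_records["p"] < eqtl_p_max].copy()
    eqtm = eqtm_records[eqtm_records["p"] < eqtm_p_max].copy()
    if eqtl.empty or eqtm.empty:
        return pd.DataFrame(
            columns=[
                "exon_id", "snp_id", "cpg_id", "eqtl_p", "eqtm_p",
                "snp_meth_p", "n_minor_hom",
            ]
        )
    if recomb_intervals is not None:
        snp_pos = genotypes.snps.loc[eqtl["feature_id"].unique(), ["chrom", "pos"]]
        interval_of = _interval_index(snp_pos, recomb_intervals)
        eqtl["interval"] = eqtl["feature_id"].map(interval_of)
    else:
        eqtl["interval"] = pd.factorize(eqtl["feature_id"])[0]
    best = (
        eqtl.sort_values("p")
        .groupby(["target_id", "interval"], sort=False)
        .head(1)
    )
    rows = []
    for exon, snp_sub in best.groupby("target_id"):
        meth_sub = eqtm[eqtm["target_id"] == exon]
        for _, srow in snp_sub.iterrows():
            dos = genotypes.dosage[srow["feature_id"]].to_numpy(dtype=float)
            n_minor = minor_hom_count(dos)
            if n_minor < min_minor_homs:
                continue
            for _, mrow in meth_sub.iterrows():
                bvec = beta.loc[mrow["feature_id"]]
                common = genotypes.dosage.index.intersection(bvec.index)
                rho, p_sm = spearman_test(
                    genotypes.dosage.loc[common, srow["feature_id"]], bvec[common]
                )
                if not np.isnan(p_sm) and p_sm < snp_meth_p_min:
                    continue
                rows.append(
                    (
                        exon, srow["feature_id"], mrow["feature_id"],
                        srow["p"], mrow["p"], p_sm, n_minor,
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "exon_id", "snp_id", "cpg_id", "eqtl_p", "eqtm_p", "snp_meth_p", "n_minor_hom",
        ],
    )


def build_interaction_batch(
    triplets: pd.DataFrame, expr: pd.DataFrame, genotypes, beta: pd.DataFrame
) -> InteractionBatch:
    """Assemble aligned arrays for the triplet table (shared individuals)."""
    common = expr.columns.intersection(genotypes.dosage.index).intersection(beta.columns)
    e = expr.loc[triplets["exon_id"], common].to_numpy(dtype=float)
    s = genotypes.dosage.loc[common, triplets["snp_id"]].to_numpy(dtype=float).T
    m = beta.loc[triplets["cpg_id"], common].to_numpy(dtype=float)
    return InteractionBatch(e, s, m)


# ---------------------------------------------------------------------------
# TF abundance vs methylation
# ---------------------------------------------------------------------------


def tf_meth_correlation(
    tf_expr: pd.DataFrame,
    tf_info: pd.DataFrame,
    eqtm_beta: pd.DataFrame,
    cpg_meta: pd.DataFrame,
    tf_peaks: dict[str, list],
    exclusion_bp: float = 1e6,
    fdr: float = 0.10,
    seed: int = 0,
) -> dict:
    """Spearman of TF expression vs eQTM methylation at the TF's binding sites.

    ``tf_expr`` has one row per TF exon; ``tf_info`` maps each exon to its TF
    name and the TF gene's chrom/TSS.  CpGs within ``exclusion_bp`` of the TF
    TSS are excluded so local mQTL/eQTM structure cannot masquerade as a
    trans effect.  Returns per-pair records, per-TF pi1 and significant-count
    (q <= fdr) summaries, the overall pi1, and a one-permutation expected
    p-value distribution.
    """
    rng = np.random.default_rng(seed)
    rows = []
    perm_rows = []
    common = tf_expr.columns.intersection(eqtm_beta.columns)
    for tf, peaks in tf_peaks.items():
        exons = tf_info.index[tf_info["tf"] == tf]
        exons = exons.intersection(tf_expr.index)
        if len(exons) == 0:
            continue
        in_peak = intersect_features(cpg_meta[["chrom", "pos"]], peaks)
        targets = cpg_meta.index[in_peak].intersection(eqtm_beta.index)
        if len(targets) == 0:
            log.info("tf_meth_correlation: TF %s has no in-peak eQTM sites", tf)
            continue
        tss_chrom = tf_info.loc[exons[0], "chrom"]
        tss = tf_info.loc[exons[0], "tss"]
        keep = []
        for cpg in targets:
            same = cpg_meta.loc[cpg, "chrom"] == tss_chrom
            if same and abs(cpg_meta.loc[cpg, "pos"] - tss) <= exclusion_bp:
                continue
            keep.append(cpg)
        for exon in exons:
            x = tf_expr.loc[exon, common].to_numpy(dtype=float)
            xp = rng.permutation(x)
            for cpg in keep:
                y = eqtm_beta.loc[cpg, common].to_numpy(dtype=float)
                rho, p = spearman_test(x, y)
                rows.append((tf, exon, cpg, rho, p))
                perm_rows.append(spearman_test(xp, y)[1])
    records = pd.DataFrame(rows, columns=["tf", "exon_id", "cpg_id", "rho", "p"])
    out = {"records": records, "perm_p": np.asarray(perm_rows, dtype=float)}
    if len(records):
        valid = records["p"].dropna().to_numpy()
        out["pi1"] = storey_pi1(valid)[1] if valid.size >= 100 else pi1_fixed_lambda(valid)
        per_tf = []
        for tf, sub in records.groupby("tf"):
            p = sub["p"].dropna().to_numpy()
            pi1 = storey_pi1(p)[1] if p.size >= 100 else pi1_fixed_lambda(p)
            q = qvalues(p, pi0=None if p.size >= 100 else 1.0)
            per_tf.append((tf, len(p), pi1, int(np.sum(q <= fdr))))
        out["per_tf"] = pd.DataFrame(
            per_tf, columns=["tf", "n_tests", "pi1", "n_significant"]
        )
    return out


def snp_tf_interaction(
    mqtl_records: pd.DataFrame,
    tf_meth: dict,
    genotypes,
    tf_expr: pd.DataFrame,
    tf_info: pd.DataFrame,
    beta: pd.DataFrame,
    tf_peaks: dict[str, list],
    fdr: float = 0.10,
    min_minor_homs: int = 4,
    snp_tf_p_min: float = 0.05,
) -> dict:
    """SNP x TF-abundance interaction effects on methylation.

    Takes the top (best-p) significant mQTL SNP per CpG, requires the SNP to
    fall in a TF's binding peak and the CpG to correlate with that TF's
    expression at the given FDR, excludes SNP-TF-correlated cases (p < 0.05)
    and SNPs with fewer than four minor-allele homozygotes, then fits
    meth ~ snp + tf + snp*tf per triplet and summarizes the product-term
    p-values with pi1.
    """
    sig = mqtl_records[mqtl_records["significant"]]
    top = sig.sort_values("p").groupby("target_id", sort=False).head(1)
    records = tf_meth.get("records", pd.DataFrame())
    if len(records) == 0 or top.empty:
        return {"triplets": pd.DataFrame(), "pi1": float("nan")}
    q = qvalues(
        records["p"].to_numpy(),
        pi0=None if len(records) >= 100 else 1.0,
    )
    sig_pairs = records.assign(q=q)
    sig_pairs = sig_pairs[sig_pairs["q"] <= fdr]
    rows = []
    common = tf_expr.columns.intersection(genotypes.dosage.index).intersection(beta.columns)
    for _, row in top.iterrows():
        snp, cpg = row["feature_id"], row["target_id"]
        snp_pos = genotypes.snps.loc[[snp], ["chrom", "pos"]]
        for tf, peaks in tf_peaks.items():
            if not intersect_features(snp_pos, peaks).iloc[0]:
                continue
            hits = sig_pairs[(sig_pairs["tf"] == tf) & (sig_pairs["cpg_id"] == cpg)]
            for _, hit in hits.iterrows():
                dos = genotypes.dosage.loc[common, snp].to_numpy(dtype=float)
                if minor_hom_count(dos) < min_minor_homs:
                    continue
                tfx = tf_expr.loc[hit["exon_id"], common].to_numpy(dtype=float)
                _, p_st = spearman_test(dos, tfx)
                if not np.isnan(p_st) and p_st < snp_tf_p_min:
                    continue
                y = beta.loc[cpg, common].to_numpy(dtype=float)
                b, t, p = interaction_test(y, dos, tfx)
                rows.append((snp, tf, hit["exon_id"], cpg, b, t, p))
    triplets = pd.DataFrame(
        rows, columns=["snp_id", "tf", "exon_id", "cpg_id", "beta", "t", "p"]
    )
    pvals = triplets["p"].dropna().to_numpy()
    pi1 = (
        storey_pi1(pvals)[1]
        if pvals.size >= 100
        else (pi1_fixed_lambda(pvals) if pvals.size else float("nan"))
    )
    return {"triplets": triplets, "pi1": pi1}
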