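"""Allele-specific expression: site filtering, expected reference ratio,
allelic imbalance and group comparisons.

Imbalance at an assayable heterozygous site is the absolute distance of the
reference-allele read fraction from the individual- and allele-pair-specific
expected ratio (approximately 0.5, after correcting residual mapping and GC
bias).  Group comparisons contrast imbalance between eQTL heterozygotes and
homozygotes, between semimethylated and homomethylated eQTM carriers, and
against imprinted genes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

HOMOMETH = "HOMOMETH"
SEMIMETH = "SEMIMETH"


def filter_ase_sites(
    counts: pd.DataFrame,
    sites: pd.DataFrame,
    mapability_min: float = 1.0,
    bias_max: float = 0.05,
    coverage_min: int = 16,
    require_both_alleles: bool = True,
) -> pd.DataFrame:
    """Retain assayable (site, individual) pairs.

    ``counts`` is long-form with columns site_id, individual, cell_type, ref,
    alt, coverage (read counts already restricted to mapping/base quality >=
    10 upstream); ``sites`` carries per-site mapability and the simulated-read
    mapping-bias difference.  A pair is kept iff mapability >= mapability_min,
    sim_bias <= bias_max and coverage >= coverage_min.  Genotype verification
    (both alleles seen in at least one cell type for the individual) is
    skipped in imprinted-gene mode (``require_both_alleles=False``).
    """
    meta = sites.loc[counts["site_id"], ["mapability", "sim_bias"]].reset_index(drop=True)
    ok = (
        (meta["mapability"].to_numpy() >= mapability_min)
        & (meta["sim_bias"].to_numpy() <= bias_max)
        & (counts["coverage"].to_numpy() >= coverage_min)
    )
    kept = counts[ok].copy()
    if require_both_alleles and len(kept):
        both = (
            counts.assign(both=(counts["ref"] > 0) & (counts["alt"] > 0))
            .groupby(["site_id", "individual"])["both"]
            .any()
        )
        key = pd.MultiIndex.from_frame(kept[["site_id", "individual"]])
        kept = kept[both.reindex(key).to_numpy()]
    return kept.reset_index(drop=True)


def _downsample_ref(rng, ref: int, total: int, target: int) -> tuple[int, int]:
    """Sample ``target`` reads without replacement from ref/alt reads."""
    if total <= target:
        return ref, total
    new_ref = int(rng.hypergeometric(ref, total - ref, target))
    return new_ref, target


def expected_ref_ratio(
    retained: pd.DataFrame,
    sites: pd.DataFrame,
    downsample_quantile: float = 0.75,
    seed: int = 0,
) -> pd.DataFrame:
    """Per (individual, allele pair) expected reference-allele read fraction.

    Reads are summed across a given individual's retained sites separately for
    each ref/alt allele combination, after down-sampling sites above the
    individual's 75th coverage percentile to that percentile (seeded, without
    replacement) so the deepest sites do not dominate the pooled ratio.
    Combinations with zero total fall back to the individual-wide ratio.
    """
    rng = np.random.default_rng(seed)
    df = retained.copy()
    pair = sites.loc[df["site_id"], ["ref_allele", "alt_allele"]].agg("/".join, axis=1)
    df["allele_pair"] = pair.to_numpy()
    rows = []
    for ind, sub in df.groupby("individual", sort=True):
        cap = float(np.quantile(sub["coverage"], downsample_quantile))
        ds_ref, ds_tot = [], []
        for r, t in zip(sub["ref"], sub["coverage"]):
            nr, nt = _downsample_ref(rng, int(r), int(t), int(np.floor(cap)))
            ds_ref.append(nr)
            ds_tot.append(nt)
        sub = sub.assign(ds_ref=ds_ref, ds_total=ds_tot)
        ind_total = sub["ds_total"].sum()
        ind_ratio = sub["ds_ref"].sum() / ind_total if ind_total else 0.5
        for ap, grp in sub.groupby("allele_pair"):
            tot = grp["ds_total"].sum()
            if tot == 0:
                log.info("expected_ref_ratio: empty combination %s/%s", ind, ap)
                ratio = ind_ratio
            else:
                ratio = grp["ds_ref"].sum() / tot
            rows.append((ind, ap, ratio))
    return pd.DataFrame(rows, columns=["individual", "allele_pair", "expected_ratio"])


def allelic_imbalance(
    retained: pd.DataFrame,
    expected: pd.DataFrame,
    sites: pd.DataFrame,
    strict_half: bool = False,
) -> pd.DataFrame:
    """imbalance = |ref/total - expected ratio| per retained site/individual.

    With ``strict_half`` the expected ratio is fixed at 0.5 instead of the
    individual- and allele-pair-specific estimate.
    """
    df = retained.copy()
    pair = sites.loc[df["site_id"], ["ref_allele", "alt_allele"]].agg("/".join, axis=1)
    df["allele_pair"] = pair.to_numpy()
    df = df.merge(expected, on=["individual", "allele_pair"], how="left")
    df["expected_ratio"] = df["expected_ratio"].fillna(0.5)
    if strict_half:
        df["expected_ratio"] = 0.5
    df["ref_ratio"] = df["ref"] / df["coverage"]
    df["imbalance"] = (df["ref_ratio"] - df["expected_ratio"]).abs()
    return df


def classify_methylation_state(beta) -> np.ndarray:
    """HOMOMETH for beta < 0.3 or > 0.7, SEMIMETH strictly in between.

    Values exactly at a boundary come back as the empty string (unclassified).
    """
    b = np.asarray(beta, dtype=float)
    out = np.full(b.shape, "", dtype=object)
    out[(b < 0.3) | (b > 0.7)] = HOMOMETH
    out[(b > 0.3) & (b < 0.7)] = SEMIMETH
    return out


def per_gene_imbalance(records: pd.DataFrame, site_gene: pd.Series) -> pd.Series:
    """One imbalance value per gene: mean across a gene's sites per individual,
    then the median across qualifying individuals."""
    df = records.copy()
    df["gene_id"] = site_gene.reindex(df["site_id"]).to_numpy()
    df = df.dropna(subset=["gene_id"])
    per_ind = df.groupby(["gene_id", "individual"])["imbalance"].mean()
    return per_ind.groupby(level="gene_id").median()


def compare_imbalance_groups(
    group_a: pd.Series, group_b: pd.Series
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum on per-gene imbalance values.

    Returns (statistic, p); an empty group yields a no-test marker (NaN).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        return float("nan"), float("nan")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
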