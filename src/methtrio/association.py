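"""Spearman cis mapping with per-unit permutation FDR, and pi0/pi1 utilities.

eQTL, mQTL and eQTM scans share a single code path: an x-matrix (SNP dosages
or CpG beta-values), a y-matrix (exon levels or beta-values), a table of
candidate cis pairs, and a permutation scheme.  Significance is controlled by
permuting the y-variable's individual labels (jointly for all of a unit's
tests), summarizing each unit by its minimum p-value, and choosing the
largest nominal threshold whose estimated false-discovery proportion stays at
or below the target.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Spearman primitives
# ---------------------------------------------------------------------------


def _rho_to_p(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-value for a Spearman coefficient via the t approximation."""
    rho = np.clip(np.asarray(rho, dtype=float), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.where(np.abs(rho) >= 1.0, 0.0, p)


def spearman_test(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks and t-approximation p.

    Pairs with a missing value in either vector are dropped; at least 8
    complete pairs are required.  A constant vector yields (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = x.size
    if n < 8:
        raise ValueError(f"need >= 8 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (float("nan"), float("nan"))
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    rho = float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))
    return rho, float(_rho_to_p(rho, n))


def _standardized_ranks(mat: np.ndarray) -> np.ndarray:
    """Column-wise average ranks, centered and L2-normalized.

    Missing values are assigned the column's mean rank (they then contribute
    nothing to the correlation).  Constant columns come back as zeros.
    """
    n, k = mat.shape
    out = np.empty_like(mat, dtype=float)
    for j in range(k):
        col = mat[:, j]
        nan = np.isnan(col)
        if nan.any():
            r = np.empty(n)
            r[~nan] = stats.rankdata(col[~nan])
            r[nan] = (np.sum(~nan) + 1) / 2.0
        else:
            r = stats.rankdata(col)
        r = r - r.mean()
        norm = np.sqrt(r @ r)
        out[:, j] = r / norm if norm > 0 else 0.0
    return out


# ---------------------------------------------------------------------------
# Permutation scheme and cis mapping
# ---------------------------------------------------------------------------


@dataclass
class PermutationScheme:
    n_perm: int = 1000
    unit: str = "gene"  # "gene" (min-p over exons) or "cpg"
    sample_of_units: int = 1000
    fdr_target: float = 0.10
    seed: int = 0
    summary: str = "median"  # expected false-count summary across permutations

    def __post_init__(self):
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if not (0 < self.fdr_target < 1):
            raise ValueError("fdr_target must be in (0, 1)")
        if self.summary not in ("median", "mean"):
            raise ValueError("summary must be 'median' or 'mean'")


@dataclass
class MapCisResult:
    records: pd.DataFrame  # feature_id, target_id, unit_id, rho, p, distance, significant
    units: pd.DataFrame  # unit_id, min_p, empirical_p, significant
    threshold: float
    scheme: PermutationScheme = field(repr=False, default=None)

    @property
    def n_significant_units(self) -> int:
        return int(self.units["significant"].sum())


def map_cis(
    feature_matrix: pd.DataFrame,
    target_matrix: pd.DataFrame,
    pairs: pd.DataFrame,
    scheme: PermutationScheme,
    unit_map: pd.Series | None = None,
) -> MapCisResult:
    """Spearman scan of candidate cis pairs with permutation FDR control.

    ``feature_matrix`` (x) and ``target_matrix`` (y) are feature x individual
    frames; ``pairs`` has columns anchor_id (feature), target_id, distance.
    ``unit_map`` maps target ids to the unit over which minimum p-values are
    taken (for expression scans, the owning gene); by default each target is
    its own unit.  The y labels are permuted jointly for a unit's tests, so
    the correlation structure of the x side is preserved under the null.
    """
    common = feature_matrix.columns.intersection(target_matrix.columns)
    x = feature_matrix[common]
    y = target_matrix[common]
    n = len(common)
    pairs = pairs[
        pairs["anchor_id"].isin(x.index) & pairs["target_id"].isin(y.index)
    ].reset_index(drop=True)
    if unit_map is None:
        unit_ids = pairs["target_id"]
    else:
        unit_ids = pairs["target_id"].map(unit_map)
    pairs = pairs.assign(unit_id=unit_ids.to_numpy())
    units = pairs["unit_id"].unique()
    if len(units) < 10:
        raise ValueError(f"need >= 10 units for a stable threshold, got {len(units)}")

    f_index = {fid: i for i, fid in enumerate(x.index)}
    t_index = {tid: i for i, tid in enumerate(y.index)}
    zx = _standardized_ranks(x.to_numpy(dtype=float).T)  # n x F
    zy = _standardized_ranks(y.to_numpy(dtype=float).T)  # n x T

    fi = pairs["anchor_id"].map(f_index).to_numpy()
    ti = pairs["target_id"].map(t_index).to_numpy()
    rho = np.einsum("ij,ij->j", zx[:, fi], zy[:, ti])
    p = _rho_to_p(rho, n)
    records = pairs.assign(rho=rho, p=p).rename(columns={"anchor_id": "feature_id"})

    obs_min_p = records.groupby("unit_id")["p"].min()

    # --- permutation null over a sample of units ---------------------------
    rng = np.random.default_rng(scheme.seed)
    n_sample = min(scheme.sample_of_units, len(units))
    sampled = rng.choice(units, size=n_sample, replace=False)
    perm_idx = np.array([rng.permutation(n) for _ in range(scheme.n_perm)])
    by_unit = records.groupby("unit_id", sort=False)
    null_min_p = np.empty((n_sample, scheme.n_perm))
    unit_groups = {u: g for u, g in by_unit}
    for ui, u in enumerate(sampled):
        g = unit_groups[u]
        fcols = np.unique(g["feature_id"].map(f_index).to_numpy())
        tcols = np.unique(g["target_id"].map(t_index).to_numpy())
        f_pos = {f: i for i, f in enumerate(fcols)}
        t_pos = {t: i for i, t in enumerate(tcols)}
        zx_u = zx[:, fcols]  # n x k
        zy_u = zy[:, tcols]  # n x m
        m = len(tcols)
        # y permuted jointly across the unit's targets
        ybig = zy_u[perm_idx]  # n_perm x n x m
        ybig = np.ascontiguousarray(ybig.transpose(1, 0, 2)).reshape(n, -1)
        r = zx_u.T @ ybig  # k x (n_perm*m)
        r = r.reshape(len(fcols), scheme.n_perm, m)
        pf = g["feature_id"].map(f_index).map(f_pos).to_numpy()
        pt = g["target_id"].map(t_index).map(t_pos).to_numpy()
        max_abs = np.abs(r[pf, :, pt]).max(axis=0)
        null_min_p[ui] = _rho_to_p(max_abs, n)

    # --- global nominal threshold ------------------------------------------
    candidates = np.sort(obs_min_p.to_numpy())
    null_sorted = np.sort(null_min_p, axis=0)  # per perm, sorted unit min-p
    counts = np.empty((scheme.n_perm, candidates.size))
    for b in range(scheme.n_perm):
        counts[b] = np.searchsorted(null_sorted[:, b], candidates, side="right")
    summary = np.median if scheme.summary == "median" else np.mean
    expected_false = summary(counts, axis=0) * (len(units) / n_sample)
    obs_count = np.searchsorted(candidates, candidates, side="right")
    fdr_hat = expected_false / np.maximum(obs_count, 1)
    passing = candidates[fdr_hat <= scheme.fdr_target]
    threshold = float(passing.max()) if passing.size else 0.0

    # --- per-unit empirical p ----------------------------------------------
    pooled = np.sort(null_min_p.ravel())
    sampled_pos = {u: i for i, u in enumerate(sampled)}
    emp = np.empty(len(obs_min_p))
    for i, (u, mp) in enumerate(obs_min_p.items()):
        if u in sampled_pos:
            row = null_min_p[sampled_pos[u]]
            emp[i] = (1 + np.sum(row <= mp)) / (scheme.n_perm + 1)
        else:
            emp[i] = (1 + np.searchsorted(pooled, mp, side="right")) / (pooled.size + 1)
    unit_table = pd.DataFrame(
        {
            "unit_id": obs_min_p.index,
            "min_p": obs_min_p.to_numpy(),
            "empirical_p": emp,
            "significant": obs_min_p.to_numpy() <= threshold,
        }
    ).reset_index(drop=True)
    records["significant"] = records["p"].to_numpy() <= threshold
    return MapCisResult(records=records, units=unit_table, threshold=threshold, scheme=scheme)


# ---------------------------------------------------------------------------
# Storey pi0 / pi1 and q-values
# ---------------------------------------------------------------------------

LAMBDA_GRID = np.round(np.arange(0.05, 0.951, 0.05), 2)


def storey_pi1(pvalues, lambda_grid=LAMBDA_GRID) -> tuple[float, float]:
    """Estimate (pi0, pi1) from a p-value collection.

    pi0(lambda) = #{p > lambda} / ((1 - lambda) n) is extrapolated to
    lambda -> 1 with a weighted cubic fit (weights from the binomial variance
    of each point), then clipped to [0, 1].  With fewer than 100 p-values the
    single-lambda (0.5) estimate is used instead.
    """
    p = np.asarray(pvalues, dtype=float)
    p = p[~np.isnan(p)]
    n = p.size
    if n == 0:
        raise ValueError("no p-values")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if n < 100:
        warnings.warn("fewer than 100 p-values: using fixed lambda=0.5 estimator")
        pi0 = np.sum(p > 0.5) / (0.5 * n)
        pi0 = float(np.clip(pi0, 0.0, 1.0))
        return pi0, 1.0 - pi0
    lam = np.asarray(lambda_grid, dtype=float)
    pi0_lam = np.array([np.sum(p > v) / ((1 - v) * n) for v in lam])
    # binomial variance of the raw estimates; low-lambda points are stabler
    w = (1 - lam) * n / np.maximum(lam, 1e-6)
    coef = np.polyfit(lam, pi0_lam, deg=3, w=np.sqrt(w))
    pi0 = float(np.clip(np.polyval(coef, lam.max()), 0.0, 1.0))
    return pi0, 1.0 - pi0


def pi1_fixed_lambda(pvalues, lam: float = 0.5) -> float:
    """Single-lambda pi1 estimate (fast path for permutation loops)."""
    p = np.asarray(pvalues, dtype=float)
    pi0 = np.sum(p > lam) / ((1 - lam) * p.size)
    return float(1.0 - np.clip(pi0, 0.0, 1.0))


def qvalues(pvalues, pi0: float | None = None) -> np.ndarray:
    """Storey q-values: monotone step-up pi0 * n * p(j) / j.

    With pi0 = 1 this reduces to Benjamini-Hochberg adjusted p-values.
    """
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    if pi0 is None:
        pi0 = storey_pi1(p)[0] if n >= 100 else 1.0
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * pi0 * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q
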