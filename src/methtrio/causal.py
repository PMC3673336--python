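"""Causal-structure inference for (SNP, CpG, exon) triplets.

Three directed structures are compared: INDEP (the SNP affects methylation
and expression independently), SME (SNP -> methylation -> expression) and
SEM (SNP -> expression -> methylation).  Each is scored as a Gaussian
Bayesian network: by the Markov property the joint likelihood factorizes into
per-node linear regressions on parents, AIC = 2k - 2 ln L compares the fits,
and exp((AIC_best - AIC_other)/2) is the relative likelihood of the weaker
model.  An independent causal inference test (CIT) — an intersection-union
test of marginal, conditional and conditional-independence components, the
last via within-stratum permutation — corroborates the network call and
gates the high-confidence set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .association import spearman_test

MODELS = ("INDEP", "SME", "SEM")

# node -> parent per structure; S is a root in all three so its marginal
# term is common and omitted from the comparison.
STRUCTURES = {
    "INDEP": (("M", "S"), ("E", "S")),
    "SME": (("M", "S"), ("E", "M")),
    "SEM": (("E", "S"), ("M", "E")),
}


@dataclass
class CausalModelFit:
    model: str
    loglik: float
    k: int
    aic: float
    coefficients: dict = field(default_factory=dict)


@dataclass
class CausalTripletCall:
    fits: dict[str, CausalModelFit]
    relative_likelihood: dict[str, float]
    bn_call: str
    p_sme: float
    p_sem: float
    cit_call: str
    eqtm_sign: str
    margin: float  # AIC(second best) - AIC(best)
    hc_flag: bool = False
    hc_rule_used: str = ""


def _node_loglik(y: np.ndarray, parent: np.ndarray) -> tuple[float, tuple]:
    """Maximized Gaussian log-likelihood of y ~ intercept + parent."""
    n = y.size
    x = np.column_stack([np.ones(n), parent])
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    sigma2 = resid @ resid / n  # MLE variance
    if sigma2 <= 0:
        return float("nan"), tuple(beta)
    ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    return float(ll), tuple(beta)


def fit_gaussian_bn(
    structure: str, s, m, e, k_convention: str = "shared_variance"
) -> CausalModelFit:
    """Fit one of the three candidate networks by per-node OLS.

    The log-likelihood is the sum of the two conditional nodes' maximized
    Gaussian log-likelihoods (the S root term is identical across structures
    and omitted).  ``k_convention`` sets the AIC parameter count: the default
    books intercept+slope per modeled node plus one variance (k = 5); the
    ``per_node_variance`` alternative books two variances (k = 6).  The
    convention shifts all three AICs equally, so the model ranking is
    unaffected.
    """
    if structure not in STRUCTURES:
        raise ValueError(f"unknown structure {structure}")
    s = np.asarray(s, dtype=float)
    m = np.asarray(m, dtype=float)
    e = np.asarray(e, dtype=float)
    ok = ~(np.isnan(s) | np.isnan(m) | np.isnan(e))
    s, m, e = s[ok], m[ok], e[ok]
    if s.size < 20:
        raise ValueError(f"need >= 20 complete observations, got {s.size}")
    values = {"S": s, "M": m, "E": e}
    for name, v in values.items():
        if np.ptp(v) == 0:
            return CausalModelFit(structure, float("nan"), 0, float("nan"))
    k = 5 if k_convention == "shared_variance" else 6
    loglik = 0.0
    coefs = {}
    for child, parent in STRUCTURES[structure]:
        ll, beta = _node_loglik(values[child], values[parent])
        if np.isnan(ll):
            return CausalModelFit(structure, float("nan"), k, float("nan"))
        loglik += ll
        coefs[f"{child}|{parent}"] = beta
    return CausalModelFit(structure, loglik, k, 2 * k - 2 * loglik, coefs)


def relative_likelihood(aic_a: float, aic_b: float) -> float:
    """Evidence ratio exp((AIC_a - AIC_b) / 2) of model b against model a.

    Requires aic_a <= aic_b (a is the better or equal model); returns a value
    in (0, 1].
    """
    if aic_a > aic_b:
        raise ValueError("first AIC must be <= second (better model first)")
    return float(np.exp((aic_a - aic_b) / 2.0))


# ---------------------------------------------------------------------------
# Causal inference test
# ---------------------------------------------------------------------------


def _partial_f(y: np.ndarray, covariates: np.ndarray | None, x: np.ndarray):
    """F statistic (1 df) for adding ``x`` to an intercept+covariates model."""
    n = y.size
    base = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), covariates]
    )
    q, _ = np.linalg.qr(base)
    ry = y - q @ (q.T @ y)
    rx = x - q @ (q.T @ x)
    den = rx @ rx
    if den <= 1e-12 * max(1.0, x @ x):
        return float("nan"), 0
    bhat = (rx @ ry) / den
    ss_exp = bhat**2 * den
    df2 = n - base.shape[1] - 1
    sse = ry @ ry - ss_exp
    if sse <= 0:
        return float("inf"), df2
    return float(ss_exp / (sse / df2)), df2


def _mediator_strata(mediator: np.ndarray, n_strata: int) -> np.ndarray:
    """Decile-style strata of the mediator; strata under 2 members merged."""
    ranks = stats.rankdata(mediator, method="average")
    lab = np.minimum(((ranks - 1) / ranks.size * n_strata).astype(int), n_strata - 1)
    # merge any stratum with < 2 observations into its left neighbour
    for v in range(n_strata):
        if 0 < np.sum(lab == v) < 2:
            lab[lab == v] = max(v - 1, 0) if v > 0 else v + 1
    return lab


def cit(
    s,
    mediator,
    outcome,
    n_perm: int = 1000,
    strata: int = 10,
    seed: int = 0,
) -> dict:
    """Causal inference test for S -> mediator -> outcome.

    Four component p-values:
      p1: S -> outcome (F test, outcome ~ S);
      p2: S -> mediator | outcome (F of S in mediator ~ outcome + S);
      p3: mediator -> outcome | S (F of mediator in outcome ~ S + mediator);
      p4: conditional independence of S and outcome given the mediator — the
          observed F of S in outcome ~ mediator + S is located within its
          within-mediator-stratum permutation distribution (which preserves
          the S-mediator association while enforcing independence), mapped
          back to an F scale, and compared against the no-mediation
          alternative (noncentral F with noncentrality estimated from the
          marginal S -> outcome F), so that small p4 supports independence.
    The omnibus p is the maximum of the four.  Collinear mediator/outcome
    yields NaN components (no-test marker).
    """
    s = np.asarray(s, dtype=float)
    m = np.asarray(mediator, dtype=float)
    y = np.asarray(outcome, dtype=float)
    ok = ~(np.isnan(s) | np.isnan(m) | np.isnan(y))
    s, m, y = s[ok], m[ok], y[ok]
    n = s.size
    if n < 20:
        raise ValueError(f"need >= 20 observations, got {n}")
    rng = np.random.default_rng(seed)

    f1, df2_1 = _partial_f(y, None, s)
    p1 = float(stats.f.sf(f1, 1, df2_1)) if np.isfinite(f1) else float("nan")
    f2, df2_2 = _partial_f(m, y, s)
    p2 = float(stats.f.sf(f2, 1, df2_2)) if np.isfinite(f2) else float("nan")
    f3, df2_3 = _partial_f(y, s, m)
    p3 = float(stats.f.sf(f3, 1, df2_3)) if np.isfinite(f3) else float("nan")

    f_obs, df2_4 = _partial_f(y, m, s)
    if not np.isfinite(f_obs) or not np.isfinite(f3) or df2_4 <= 0:
        return {
            "p1": p1, "p2": p2, "p3": p3, "p4": float("nan"),
            "omnibus": float("nan"),
        }
    labels = _mediator_strata(m, strata)
    # residual projections for the conditional model, reused per permutation
    base = np.column_stack([np.ones(n), m])
    q, _ = np.linalg.qr(base)
    ry = y - q @ (q.T @ y)
    ryy = ry @ ry
    s_perm = np.tile(s, (n_perm, 1))
    for lab in np.unique(labels):
        idx = np.where(labels == lab)[0]
        for b in range(n_perm):
            s_perm[b, idx] = s_perm[b, idx[rng.permutation(idx.size)]]
    rs = s_perm.T - q @ (q.T @ s_perm.T)  # n x B
    den = np.einsum("ij,ij->j", rs, rs)
    num = (ry @ rs) ** 2 / np.maximum(den, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_perm = num / np.maximum((ryy - num) / df2_4, 1e-300)
    # empirical placement of the observed F in the independence reference
    u = (0.5 + np.sum(f_perm < f_obs) + 0.5 * np.sum(f_perm == f_obs)) / (n_perm + 1)
    f_star = stats.f.ppf(u, 1, df2_4)
    ncp = max(0.0, f1 - 1.0)  # no-mediation alternative from the marginal F
    if ncp > 0:
        p4 = float(stats.ncf.cdf(f_star, 1, df2_4, ncp))
    else:
        p4 = float(u)
    ps = [p1, p2, p3, p4]
    omnibus = float("nan") if any(np.isnan(v) for v in ps) else float(max(ps))
    return {"p1": p1, "p2": p2, "p3": p3, "p4": p4, "omnibus": omnibus}


# ---------------------------------------------------------------------------
# Triplet calls
# ---------------------------------------------------------------------------


def call_triplet(
    s,
    m,
    e,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    k_convention: str = "shared_variance",
) -> CausalTripletCall:
    """BN and CIT calls for one (S, M, E) triplet.

    The BN call is the minimum-AIC structure.  The CIT is run twice — with M
    as mediator (supporting SME) and with E as mediator (supporting SEM) —
    and calls SME or SEM when exactly one omnibus p is below ``alpha``, no
    model when both are, and INDEP when neither is.  The eQTM sign is the
    sign of the marginal Spearman correlation of M and E.
    """
    fits = {mod: fit_gaussian_bn(mod, s, m, e, k_convention) for mod in MODELS}
    aics = {mod: f.aic for mod, f in fits.items()}
    if any(np.isnan(v) for v in aics.values()):
        return CausalTripletCall(
            fits, {}, "", float("nan"), float("nan"), "", "", float("nan")
        )
    bn_call = min(aics, key=aics.get)
    best = aics[bn_call]
    rel = {mod: relative_likelihood(best, aics[mod]) for mod in MODELS}
    second = min(v for mod, v in aics.items() if mod != bn_call)
    margin = second - best
    res_sme = cit(s, m, e, n_perm=n_perm, seed=seed)
    res_sem = cit(s, e, m, n_perm=n_perm, seed=seed + 1)
    p_sme, p_sem = res_sme["omnibus"], res_sem["omnibus"]
    sig_sme = (not np.isnan(p_sme)) and p_sme < alpha
    sig_sem = (not np.isnan(p_sem)) and p_sem < alpha
    if sig_sme and sig_sem:
        cit_call = "none"
    elif sig_sme:
        cit_call = "SME"
    elif sig_sem:
        cit_call = "SEM"
    else:
        cit_call = "INDEP"
    rho, _ = spearman_test(m, e)
    sign = "" if np.isnan(rho) else ("pos" if rho >= 0 else "neg")
    return CausalTripletCall(
        fits, rel, bn_call, p_sme, p_sem, cit_call, sign, margin
    )


def high_confidence_calls(calls: list[CausalTripletCall]) -> list[CausalTripletCall]:
    """Flag high-confidence calls by BN/CIT agreement (+ margin rule for INDEP).

    SME and SEM are high confidence when the BN and CIT calls agree on the
    model.  INDEP requires agreement and an AIC margin (best vs second best)
    at least the median margin of the high-confidence SME/SEM calls; when no
    such calls exist the margin rule is undefined and INDEP falls back to
    agreement only (recorded in ``hc_rule_used``).
    """
    hc_margins = []
    for c in calls:
        if c.bn_call in ("SME", "SEM") and c.bn_call == c.cit_call:
            c.hc_flag = True
            c.hc_rule_used = "agreement"
            hc_margins.append(c.margin)
        else:
            c.hc_flag = False
            c.hc_rule_used = ""
    median_margin = float(np.median(hc_margins)) if hc_margins else None
    for c in calls:
        if c.bn_call == "INDEP" and c.cit_call == "INDEP":
            if median_margin is None:
                c.hc_flag = True
                c.hc_rule_used = "agreement_only_no_margin_reference"
            elif c.margin >= median_margin:
                c.hc_flag = True
                c.hc_rule_used = "agreement+margin"
    return calls


def calls_to_frame(triplet_ids, calls: list[CausalTripletCall]) -> pd.DataFrame:
    """Per-triplet output table (ids, AICs, relative likelihoods, CIT, calls)."""
    rows = []
    for ids, c in zip(triplet_ids, calls):
        row = dict(ids)
        for mod in MODELS:
            fit = c.fits.get(mod)
            row[f"aic_{mod}"] = fit.aic if fit else float("nan")
            row[f"rl_{mod}"] = c.relative_likelihood.get(mod, float("nan"))
        row.update(
            bn_call=c.bn_call,
            p_sme=c.p_sme,
            p_sem=c.p_sem,
            cit_call=c.cit_call,
            eqtm_sign=c.eqtm_sign,
            margin=c.margin,
            hc=c.hc_flag,
            hc_rule=c.hc_rule_used,
        )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Triplet selection from association results
# ---------------------------------------------------------------------------


def select_triplet_datasets(
    eqtl_records: pd.DataFrame,
    mqtl_records: pd.DataFrame,
    eqtm_records: pd.DataFrame,
    seed: int = 0,
) -> pd.DataFrame:
    """Three selection sets of (snp, cpg, exon) triplets, merged and
    size-normalized.

    Set 1: per exon the best significant eQTM, and for that CpG the best
    significant mQTL (eQTL significance not required) — enriches for SME.
    Set 2: per exon its best significant eQTL and best significant eQTM
    (mQTL not required) — enriches for SEM.  Set 3: per exon its best
    significant eQTL, kept when that SNP is the best significant mQTL of some
    CpG (eQTM not required) — enriches for INDEP.  The three sets are
    down-sampled to the smallest set's size (seeded) and merged.
    """
    rng = np.random.default_rng(seed)

    def best_per(df, by):
        sig = df[df["significant"]]
        return sig.sort_values("p").groupby(by, sort=False).head(1)

    best_eqtm = best_per(eqtm_records, "target_id")  # per exon
    best_mqtl = best_per(mqtl_records, "target_id")  # per cpg
    best_eqtl = best_per(eqtl_records, "target_id")  # per exon

    sets = []
    # set 1: best eQTM per exon, best mQTL for that CpG
    rows = []
    mqtl_by_cpg = best_mqtl.set_index("target_id")
    for _, r in best_eqtm.iterrows():
        cpg, exon = r["feature_id"], r["target_id"]
        if cpg in mqtl_by_cpg.index:
            rows.append((mqtl_by_cpg.loc[cpg, "feature_id"], cpg, exon, 1))
    sets.append(rows)
    # set 2: best eQTL + best eQTM per exon
    rows = []
    eqtm_by_exon = best_eqtm.set_index("target_id")
    for _, r in best_eqtl.iterrows():
        exon = r["target_id"]
        if exon in eqtm_by_exon.index:
            rows.append((r["feature_id"], eqtm_by_exon.loc[exon, "feature_id"], exon, 2))
    sets.append(rows)
    # set 3: best eQTL per exon where that SNP is also a best mQTL
    rows = []
    snp_to_cpgs = best_mqtl.groupby("feature_id")["target_id"].apply(list)
    for _, r in best_eqtl.iterrows():
        snp, exon = r["feature_id"], r["target_id"]
        for cpg in snp_to_cpgs.get(snp, []):
            rows.append((snp, cpg, exon, 3))
    sets.append(rows)

    non_empty = [s for s in sets if s]
    if not non_empty:
        return pd.DataFrame(columns=["snp_id", "cpg_id", "exon_id", "selection_set"])
    size = min(len(s) for s in non_empty)
    merged = []
    for s in sets:
        if not s:
            continue
        take = rng.choice(len(s), size=size, replace=False)
        merged.extend(s[i] for i in sorted(take))
    return pd.DataFrame(merged, columns=["snp_id", "cpg_id", "exon_id", "selection_set"])
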