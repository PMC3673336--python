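"""Stage orchestration: run the synthetic cohort through every analysis stage
with one structured config, deterministic per-stage seeds, and tab-delimited
outputs plus a machine-readable run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import ase as ase_mod
from . import association, causal, context, interactions, preprocess
from .datamodel import cis_pairs, write_bed, write_matrix
from .simulate import SimConfig, simulate_allelic_counts, simulate_cohort

log = logging.getLogger(__name__)

STAGES = [
    "simulate",
    "preprocess",
    "map-qtl",
    "context",
    "ase",
    "interactions",
    "tf",
    "causal",
    "report",
]

DEPENDS = {
    "preprocess": "simulate",
    "map-qtl": "preprocess",
    "context": "map-qtl",
    "ase": "map-qtl",
    "interactions": "map-qtl",
    "tf": "map-qtl",
    "causal": "map-qtl",
    "report": "map-qtl",
}

DEFAULT_CONFIG = {
    "seed": 0,
    "cohort": {},
    "preprocess": {"min_exonic_reads": 0},
    "map_qtl": {
        "n_perm": 200,
        "fdr_target": 0.10,
        "eqtl_window": 1_000_000,
        "mqtl_window": 5_000,
        "eqtm_window": 50_000,
    },
    "interactions": {"n_perm": 200},
    "causal": {"n_perm": 200, "max_triplets": 200},
    "ase": {"n_sites": 40, "n_individuals": 30},
}


def stage_seed(global_seed: int, name: str) -> int:
    return (int(global_seed) * 1_000_003 + zlib.crc32(name.encode())) % (2**31)


def _merge_config(user: dict | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (user or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _write(df: pd.DataFrame, path: Path, index=False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def _checksum(path: Path) -> str:
    return hashlib.md5(path.read_bytes()).hexdigest()


class PipelineState(dict):
    """In-memory artifacts passed between stages."""


def run_pipeline(config: dict | None, stages=None, out_dir="pipeline_out") -> PipelineState:
    """Run the requested stages in order; each writes TSV outputs + manifest.

    Stage dependencies must be satisfied within the same invocation; a stage
    whose prerequisite has not run raises an error naming it.  Re-running
    with the same config and seed is byte-identical.
    """
    cfg = _merge_config(config)
    seed = int(cfg["seed"])
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(stages or STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}")
    stages = [s for s in STAGES if s in stages]
    state = PipelineState()
    written: list[Path] = []
    done = set()
    for stage in stages:
        dep = DEPENDS.get(stage)
        if dep is not None and dep not in done:
            raise RuntimeError(f"stage '{stage}' requires prior stage '{dep}'")
        log.info("running stage %s", stage)
        _STAGE_FUNCS[stage](state, cfg, seed, out, written)
        done.add(stage)
    manifest = {
        "config": cfg,
        "stages": stages,
        "stage_seeds": {s: stage_seed(seed, s) for s in stages},
        "outputs": {str(p.relative_to(out)): _checksum(p) for p in written},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    state["manifest"] = manifest
    return state


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_simulate(state, cfg, seed, out, written):
    sim_cfg = SimConfig(**cfg["cohort"], seed=stage_seed(seed, "simulate"))
    cohort = simulate_cohort(sim_cfg)
    state["cohort"] = cohort
    for ct in cohort.cell_types:
        p = out / f"beta_{ct}.tsv"
        write_matrix(cohort.methylation[ct].beta, p)
        written.append(p)
        p = out / f"counts_{ct}.tsv"
        write_matrix(cohort.expression[ct].counts, p)
        written.append(p)
    p = out / "dosage.tsv"
    write_matrix(cohort.genotypes.dosage.T, p)
    written.append(p)
    p = out / "truth.tsv"
    _write(cohort.truth, p)
    written.append(p)
    for name in ("promoter", "CGI", "enhancer", "CTCF", "recombination"):
        p = out / f"features_{name}.bed"
        write_bed(cohort.features[name], p)
        written.append(p)


def _stage_preprocess(state, cfg, seed, out, written):
    cohort = state["cohort"]
    qc, report = preprocess.qc_genotypes(cohort.genotypes)
    state["genotypes"] = qc
    p = out / "genotype_qc.tsv"
    _write(report.to_frame(), p)
    written.append(p)
    state["expression"] = {}
    for ct in cohort.cell_types:
        e, dropped = preprocess.process_expression(
            cohort.expression[ct],
            cohort.covariates[ct],
            min_exonic_reads=cfg["preprocess"]["min_exonic_reads"],
        )
        state["expression"][ct] = e
    state["methylation"] = {}
    for ct in cohort.cell_types:
        m = cohort.methylation[ct]
        if m.meth is not None:
            m = preprocess.normalize_methylation_450k(m)
        state["methylation"][ct] = m


def _stage_map_qtl(state, cfg, seed, out, written):
    cohort = state["cohort"]
    g = state["genotypes"]
    mq = cfg["map_qtl"]
    snp_pos = g.snps[["chrom", "pos"]]
    state["qtl"] = {}
    for ct in cohort.cell_types:
        e = state["expression"][ct]
        m = state["methylation"][ct]
        expr = e.exon_values()
        gene_of = e.exons["gene_id"]
        tss = pd.DataFrame(
            {
                "chrom": [gm.chrom for gm in e.genes.values()],
                "pos": [gm.tss for gm in e.genes.values()],
                "strand": [gm.strand for gm in e.genes.values()],
            },
            index=pd.Index(list(e.genes), name="gene_id"),
        )
        exon_anchor = e.exons.join(tss[["pos"]].rename(columns={"pos": "tss"}), on="gene_id")
        exon_pos = pd.DataFrame(
            {"chrom": exon_anchor["chrom"], "pos": exon_anchor["tss"]},
            index=e.exons.index,
        )
        cpg_pos = m.sites[["chrom", "pos"]]
        scheme = lambda unit, s: association.PermutationScheme(
            n_perm=mq["n_perm"],
            unit=unit,
            fdr_target=mq["fdr_target"],
            seed=stage_seed(seed, f"map-{ct}-{s}"),
        )
        res = {}
        pairs = cis_pairs(snp_pos, exon_pos, mq["eqtl_window"])
        res["eqtl"] = association.map_cis(
            g.dosage.T, expr, pairs, scheme("gene", "eqtl"), unit_map=gene_of
        )
        pairs = cis_pairs(snp_pos, cpg_pos, mq["mqtl_window"])
        res["mqtl"] = association.map_cis(
            g.dosage.T, m.beta, pairs, scheme("cpg", "mqtl"))
        pairs = cis_pairs(cpg_pos, exon_pos, mq["eqtm_window"])
        res["eqtm"] = association.map_cis(
            m.beta, expr, pairs, scheme("gene", "eqtm"), unit_map=gene_of
        )
        state["qtl"][ct] = res
        for kind, r in res.items():
            p = out / f"{kind}_{ct}.tsv"
            _write(r.records[r.records["significant"]], p)
            written.append(p)


def _stage_context(state, cfg, seed, out, written):
    cohort = state["cohort"]
    beta_by_ct = {ct: m.beta for ct, m in state["methylation"].items()}
    scores = context.differentiation_cv(beta_by_ct)
    ct0 = cohort.cell_types[0]
    res = state["qtl"][ct0]
    mqtl_sites = set(res["mqtl"].records.loc[res["mqtl"].records["significant"], "feature_id"])
    eqtm_sites = set(res["eqtm"].records.loc[res["eqtm"].records["significant"], "feature_id"])
    flags = pd.Series(scores.index.isin(mqtl_sites | eqtm_sites), index=scores.index)
    table, wilcoxon_p = context.decile_enrichment(scores["cv"], flags)
    table["wilcoxon_p"] = wilcoxon_p
    p = out / "differentiation_deciles.tsv"
    _write(table, p)
    written.append(p)
    p = out / "differentiation_cv.tsv"
    _write(scores.reset_index(), p)
    written.append(p)
    sites = state["methylation"][ct0].sites
    sig = res["eqtm"].records[res["eqtm"].records["significant"]]
    signs = sig.groupby("feature_id")["rho"].mean()
    pos = sites.loc[sites.index.intersection(signs.index[signs > 0]), ["chrom", "pos"]]
    neg = sites.loc[sites.index.intersection(signs.index[signs < 0]), ["chrom", "pos"]]
    non = sites.loc[sites.index.difference(signs.index), ["chrom", "pos"]]
    feats = {
        "promoter": cohort.features["promoter"],
        "CGI": cohort.features["CGI"],
        "enhancer": cohort.features["enhancer"],
        "CTCF": cohort.features["CTCF"],
    }
    tab = context.eqtm_sign_context(pos, neg, non, feats)
    p = out / "eqtm_sign_context.tsv"
    _write(tab, p)
    written.append(p)
    state["context"] = {"scores": scores, "deciles": table, "sign_context": tab}


def _stage_ase(state, cfg, seed, out, written):
    acfg = cfg["ase"]
    counts, sites = simulate_allelic_counts(
        acfg["n_sites"], acfg["n_individuals"], seed=stage_seed(seed, "ase")
    )
    kept = ase_mod.filter_ase_sites(counts, sites)
    expected = ase_mod.expected_ref_ratio(kept, sites, seed=stage_seed(seed, "ase-ds"))
    records = ase_mod.allelic_imbalance(kept, expected, sites)
    p = out / "ase_imbalance.tsv"
    _write(records, p)
    written.append(p)
    state["ase"] = records


def _stage_interactions(state, cfg, seed, out, written):
    cohort = state["cohort"]
    ct = cohort.cell_types[0]
    res = state["qtl"][ct]
    triplets = interactions.select_interaction_triplets(
        res["eqtl"].records,
        res["eqtm"].records,
        state["genotypes"],
        state["methylation"][ct].beta,
        recomb_intervals=cohort.features["recombination"],
    )
    state["interaction_triplets"] = triplets
    if len(triplets) >= 100:
        batch = interactions.build_interaction_batch(
            triplets,
            state["expression"][ct].exon_values(),
            state["genotypes"],
            state["methylation"][ct].beta,
        )
        env = interactions.permutation_pi1_envelope(
            batch,
            n_perm=cfg["interactions"]["n_perm"],
            seed=stage_seed(seed, "interactions"),
        )
        state["interaction_envelope"] = env
        summary = pd.DataFrame(
            {"observed_pi1": [env.observed_pi1], "empirical_p": [env.empirical_p]}
        )
    else:
        summary = pd.DataFrame({"observed_pi1": [np.nan], "empirical_p": [np.nan]})
        log.info("interactions: only %d triplets, envelope skipped", len(triplets))
    p = out / "interaction_summary.tsv"
    _write(summary, p)
    written.append(p)
    p = out / "interaction_triplets.tsv"
    _write(triplets, p)
    written.append(p)


def _stage_tf(state, cfg, seed, out, written):
    cohort = state["cohort"]
    ct = cohort.cell_types[0]
    e = state["expression"][ct]
    m = state["methylation"][ct]
    res = state["qtl"][ct]
    tf_names = list(cohort.features["tf_peaks"])
    gene_ids = list(e.genes)[: len(tf_names)]
    info_rows = []
    for tf, gid in zip(tf_names, gene_ids):
        gm = e.genes[gid]
        for exon in e.exons.index[e.exons["gene_id"] == gid]:
            info_rows.append((exon, tf, gm.chrom, gm.tss))
    tf_info = pd.DataFrame(
        info_rows, columns=["exon_id", "tf", "chrom", "tss"]
    ).set_index("exon_id")
    eqtm_sites = res["eqtm"].records.loc[res["eqtm"].records["significant"], "feature_id"]
    eqtm_beta = m.beta.loc[m.beta.index.intersection(pd.Index(eqtm_sites.unique()))]
    tfm = interactions.tf_meth_correlation(
        e.exon_values().loc[e.exon_values().index.intersection(tf_info.index)],
        tf_info,
        eqtm_beta,
        m.sites[["chrom", "pos"]],
        cohort.features["tf_peaks"],
        seed=stage_seed(seed, "tf"),
    )
    state["tf_meth"] = tfm
    p = out / "tf_meth.tsv"
    _write(tfm["records"], p)
    written.append(p)
    sti = interactions.snp_tf_interaction(
        res["mqtl"].records,
        tfm,
        state["genotypes"],
        e.exon_values(),
        tf_info,
        m.beta,
        cohort.features["tf_peaks"],
    )
    state["snp_tf"] = sti
    p = out / "snp_tf_interactions.tsv"
    _write(sti["triplets"], p)
    written.append(p)


def _stage_causal(state, cfg, seed, out, written):
    cohort = state["cohort"]
    ct = cohort.cell_types[0]
    res = state["qtl"][ct]
    sel = causal.select_triplet_datasets(
        res["eqtl"].records,
        res["mqtl"].records,
        res["eqtm"].records,
        seed=stage_seed(seed, "causal-sel"),
    )
    sel = sel.head(cfg["causal"]["max_triplets"])
    g = state["genotypes"]
    expr = state["expression"][ct].exon_values()
    beta = state["methylation"][ct].beta
    common = expr.columns.intersection(g.dosage.index).intersection(beta.columns)
    calls, ids = [], []
    for i, row in sel.iterrows():
        s = g.dosage.loc[common, row["snp_id"]].to_numpy(dtype=float)
        m = beta.loc[row["cpg_id"], common].to_numpy(dtype=float)
        e = expr.loc[row["exon_id"], common].to_numpy(dtype=float)
        call = causal.call_triplet(
            s, m, e, n_perm=cfg["causal"]["n_perm"], seed=stage_seed(seed, f"cit{i}")
        )
        calls.append(call)
        ids.append(
            {"snp_id": row["snp_id"], "cpg_id": row["cpg_id"], "exon_id": row["exon_id"]}
        )
    causal.high_confidence_calls(calls)
    table = causal.calls_to_frame(ids, calls)
    state["causal_calls"] = table
    p = out / "causal_calls.tsv"
    _write(table, p)
    written.append(p)


def _stage_report(state, cfg, seed, out, written):
    cohort = state["cohort"]
    rows = []
    windows = {"eqtl": "1 Mb", "mqtl": "5 kb", "eqtm": "50 kb"}
    units = {"eqtl": "gene", "mqtl": "cpg", "eqtm": "gene"}
    for ct, res in state.get("qtl", {}).items():
        for kind, r in res.items():
            rows.append(
                (
                    kind,
                    ct,
                    windows[kind],
                    units[kind],
                    cfg["map_qtl"]["fdr_target"] * 100,
                    r.threshold,
                    r.n_significant_units,
                )
            )
    summary = pd.DataFrame(
        rows,
        columns=["test", "cell_type", "window", "unit", "fdr_pct", "nominal_p", "n_significant"],
    )
    p = out / "summary_associations.tsv"
    _write(summary, p)
    written.append(p)
    state["report"] = {"associations": summary}
    if "causal_calls" in state and len(state["causal_calls"]):
        calls = state["causal_calls"]
        mosaic = (
            calls.groupby(["bn_call", "eqtm_sign"]).size().unstack(fill_value=0)
        )
        mosaic = mosaic.div(mosaic.to_numpy().sum())
        p = out / "causal_mosaic.tsv"
        _write(mosaic.reset_index(), p)
        written.append(p)
        state["report"]["mosaic"] = mosaic
    truth = cohort.truth
    if "qtl" in state and len(truth):
        ct0 = cohort.cell_types[0]
        rec = []
        for kind, ttype, unit_of in (
            ("eqtl", "eQTL", "target"),
            ("mqtl", "mQTL", "target"),
            ("eqtm", "eQTM", "target"),
        ):
            planted = truth[truth["type"] == ttype]
            r = state["qtl"][ct0][kind]
            sig_units = set(r.units.loc[r.units["significant"], "unit_id"])
            if kind == "mqtl":
                hit = planted["target_id"].isin(sig_units)
            else:
                hit = planted["target_id"].isin(sig_units)
            rec.append((ttype, len(planted), int(hit.sum())))
        recovery = pd.DataFrame(rec, columns=["type", "n_planted", "n_recovered"])
        p = out / "recovery.tsv"
        _write(recovery, p)
        written.append(p)
        state["report"]["recovery"] = recovery


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "map-qtl": _stage_map_qtl,
    "context": _stage_context,
    "ase": _stage_ase,
    "interactions": _stage_interactions,
    "tf": _stage_tf,
    "causal": _stage_causal,
    "report": _stage_report,
}
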