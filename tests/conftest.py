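import numpy as np
import pandas as pd
import pytest

from methtrio.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Small mixed cohort with planted eQTLs/mQTLs/eQTMs shared by tests."""
    cfg = SimConfig(
        n_individuals=80,
        n_genes=60,
        n_snps=240,
        n_cpgs=150,
        fraction_null=0.5,
        genes_per_chrom=30,
        seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def exon_tss_positions(expr):
    """Anchor every exon at its gene's TSS (cis windows are TSS-relative)."""
    tss = pd.Series({g: gm.tss for g, gm in expr.genes.items()})
    return pd.DataFrame(
        {
            "chrom": expr.exons["chrom"],
            "pos": expr.exons["gene_id"].map(tss),
        },
        index=expr.exons.index,
    )
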