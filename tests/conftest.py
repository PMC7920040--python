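import numpy as np
import pandas as pd
import pytest

import poolscan as ps


@pytest.fixture
def tiny_sites():
    """A handful of hand-written sync sites covering the calling cases."""
    return [
        # fixed difference A vs T
        ps.SyncSite("scaf1", 42, "A", (10, 0, 0, 0, 0, 0), (0, 10, 0, 0, 0, 0)),
        # monomorphic
        ps.SyncSite("scaf1", 50, "A", (10, 0, 0, 0, 0, 0), (10, 0, 0, 0, 0, 0)),
        # intermediate frequencies p1=0.4, p2=0.8 (T minor)
        ps.SyncSite("scaf1", 60, "A", (6, 4, 0, 0, 0, 0), (2, 8, 0, 0, 0, 0)),
        # low coverage in pool 2
        ps.SyncSite("scaf2", 10, "C", (5, 0, 5, 0, 0, 0), (2, 0, 3, 0, 0, 0)),
    ]


@pytest.fixture(scope="session")
def desk_config():
    return ps.SimulationConfig(
        n_scaffolds=2,
        scaffold_length=400_000,
        n_genes=120,
        snp_density=0.004,
        monomorphic_density=0.0005,
        n_candidates=12,
        n_terms=15,
        seed=20260901,
    )


@pytest.fixture(scope="session")
def desk_dataset(desk_config):
    """One small simulated dataset shared by read-only tests."""
    ann = ps.simulate_annotation(desk_config)
    sites, truth = ps.simulate_divergence(desk_config, annotation=ann)
    snp_df, rejections = ps.call_snps(sites)
    snp_df = ps.add_fst_columns(snp_df)
    gene_df = ps.gene_fst_table(
        list(ann.genes), snp_df, flank=5000,
        scaffold_lengths=desk_config.scaffold_lengths,
    )
    return {
        "config": desk_config,
        "annotation": ann,
        "sites": sites,
        "truth": truth,
        "snp_df": snp_df,
        "gene_df": gene_df,
        "rejections": rejections,
    }


@pytest.fixture(scope="session")
def cohort_tables():
    cfg = ps.CohortConfig(n_per_group=11, seed=77)
    cells, thc, truth = ps.simulate_cohort(cfg)
    return cfg, cells, thc, truth
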