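import numpy as np
import pandas as pd
import pytest

from cnvselect import (
    SimulationConfig,
    filter_counts,
    generate_bulk,
    generate_sc,
    infer_cnv,
    lognormalize,
    order_genes,
)


def amplified_marker_genes(config, positions):
    """Gene ids inside fold-change > 1 segments (the planted bulk markers)."""
    return sorted(
        {
            positions["gene_id"].iloc[g]
            for _clone, _chrom, start, end, fold in config.cnv_segments
            if fold > 1.0
            for g in range(start, end)
        }
    )


@pytest.fixture(scope="session")
def sim_config():
    """The default study conditions: 600 cells, 2000 genes, 22 chromosomes."""
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def sim_dataset(sim_config):
    adata, positions, truth = generate_sc(sim_config)
    return adata, positions, truth


@pytest.fixture(scope="session")
def sim_profile(sim_config, sim_dataset):
    """Normalized, ordered data plus its CNV profile (shared across tests)."""
    adata, positions, truth = sim_dataset
    normalized = lognormalize(filter_counts(adata, 3, 200))
    ordered = order_genes(normalized, positions)
    profile = infer_cnv(ordered)
    truth_aligned = truth.set_index("cell_id").reindex(ordered.obs_names)
    return ordered, profile, truth_aligned


@pytest.fixture(scope="session")
def sim_bulk(sim_config, sim_dataset):
    _, positions, _ = sim_dataset
    markers = amplified_marker_genes(sim_config, positions)
    return generate_bulk(sim_config, markers)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def tiny_cohort():
    """4 genes, 1 sample, expression already in rank order."""
    from cnvselect import BulkCohort

    values = pd.DataFrame(
        [[4.0, 3.0, 2.0, 1.0]], index=["s1"], columns=["g1", "g2", "g3", "g4"]
    )
    return BulkCohort(values, pd.Series(["tumor"], index=["s1"]))
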