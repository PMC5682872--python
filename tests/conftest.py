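import numpy as np
import pandas as pd
import pytest

from stressdeg.io import AnalysisConfig, CountTable
from stressdeg.simulate import GenomeSpec, SimulationConfig, simulate_all


@pytest.fixture
def config():
    return AnalysisConfig()


@pytest.fixture
def tiny_table():
    """Six genes, four libraries, equal library sizes of one million."""
    genes = [f"g{i}" for i in range(6)]
    counts = pd.DataFrame(
        {
            "WT_ctrl": [100, 50, 0, 400, 10, 0],
            "WT_Cd": [800, 55, 0, 50, 11, 0],
            "pmk1_ctrl": [100, 48, 0, 410, 9, 0],
            "pmk1_Cd": [210, 52, 0, 200, 12, 0],
        },
        index=pd.Index(genes, name="gene_id"),
    )
    sizes = pd.Series(1_000_000, index=counts.columns)
    return CountTable(counts, sizes)


@pytest.fixture
def tiny_annotation(tiny_table):
    genes = tiny_table.gene_ids
    n = len(genes)
    starts = np.arange(n) * 5000 + 3000
    return pd.DataFrame(
        {
            "transcript_length_bp": [1000, 500, 800, 2000, 1500, 600],
            "kog_code": ["T", "P", "", "T", "O", "S"],
            "chrom": "chrI",
            "gene_start": starts,
            "gene_end": starts + 1200,
            "strand": ["+", "-", "+", "+", "-", "+"],
            "start_codon_pos": starts,
            "stop_codon_pos": starts + 1199,
        },
        index=genes,
    )


@pytest.fixture(scope="session")
def planted_sim():
    """A seeded study-structured simulation shared across test modules."""
    cfg = SimulationConfig(
        n_genes=2000,
        genome=GenomeSpec(n_genes=30),
        rng_seed=5,
    )
    return simulate_all(cfg)


@pytest.fixture(scope="session")
def planted_contrasts(planted_sim):
    from stressdeg.deg import CANONICAL_CONTRASTS, run_contrast

    cfg = AnalysisConfig()
    wt = run_contrast(
        planted_sim.counts, planted_sim.annotation,
        CANONICAL_CONTRASTS["WT_Cd_vs_WT_ctrl"], cfg,
    )
    pk = run_contrast(
        planted_sim.counts, planted_sim.annotation,
        CANONICAL_CONTRASTS["pmk1_Cd_vs_pmk1_ctrl"], cfg,
    )
    return wt, pk
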