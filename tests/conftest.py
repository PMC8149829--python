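import pandas as pd
import pytest

from regarch.pipeline import annotate_bundle, architecture_table
from regarch.synthetic import SimulationConfig, simulate_epigenome


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete synthetic dataset shared across test modules."""
    config = SimulationConfig(n_genes=12, n_elements=80, seed=7)
    bundle, truth = simulate_epigenome(config)
    return config, bundle, truth


@pytest.fixture(scope="session")
def annotated(small_sim):
    _, bundle, _ = small_sim
    return annotate_bundle(bundle)


@pytest.fixture(scope="session")
def arch_table(small_sim, annotated):
    _, bundle, _ = small_sim
    return architecture_table(bundle, annotated)


@pytest.fixture()
def genes_frame():
    """Two genes on opposite strands for proximity-rule tests."""
    df = pd.DataFrame(
        {
            "gene_id": ["A", "B"],
            "chrom": ["chr1", "chr1"],
            "start": [100_000, 300_000],
            "end": [150_000, 340_000],
            "strand": ["+", "-"],
            "gene_type": ["protein_coding", "protein_coding"],
        }
    )
    df["tss"] = df["start"].where(df["strand"] == "+", df["end"] - 1)
    return df
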