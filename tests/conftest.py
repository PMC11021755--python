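import numpy as np
import pandas as pd
import pytest

from madcpop.io import MadcTable, MarkerLocus, PanelDefinition
from madcpop.simulate import SimulationConfig, SpeciesGroup, simulate_dataset


def make_table(loci: dict, counts: dict, samples: list[str], panel: PanelDefinition | None = None) -> MadcTable:
    """Build a MadcTable from {locus: {hap: seq}} and {(locus, hap): [counts]}."""
    index = pd.MultiIndex.from_tuples(list(counts), names=("locus_id", "hap_id"))
    df = pd.DataFrame([counts[k] for k in counts], index=index, columns=samples, dtype=np.int64)
    seqs = pd.Series([loci[l][h] for l, h in counts], index=index, name="sequence")
    return MadcTable(df, seqs, panel=panel)


@pytest.fixture(scope="session")
def three_species_config() -> SimulationConfig:
    return SimulationConfig(
        n_loci=200,
        species_spec=(
            SpeciesGroup("M. alpha", 0.3, 6, "Collection"),
            SpeciesGroup("M. alpha", 0.3, 2, "Genebank"),
            SpeciesGroup("M. beta", 0.6, 6, "Collection"),
            SpeciesGroup("M. gamma", 0.9, 6, "Genebank"),
        ),
        seed=42,
    )


@pytest.fixture(scope="session")
def three_species_dataset(three_species_config):
    return simulate_dataset(three_species_config)


@pytest.fixture
def toy_panel() -> PanelDefinition:
    return PanelDefinition(
        [
            MarkerLocus("L1", "chr1.1", 1000, "ACGTACGTAC", 4),
            MarkerLocus("L2", "chr2.1", 2000, "TTGGCCAATT", 2),
        ]
    )
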