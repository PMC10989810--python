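import numpy as np
import pytest

from ribovelo import riboseq
from ribovelo.synthetic import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """20 genes with planted default effects, moderate depth."""
    cfg = SimulationConfig(
        seed=1, n_genes=20, gene_length_range=(100, 200), mean_depth=30
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_joint(small_dataset):
    """Joint table built from the planted counts (true offsets)."""
    from ribovelo import integrate

    ds = small_dataset
    occ = {g: riboseq.CodonOccupancy(g, c) for g, c in ds.counts.items()}
    profiles = {g: riboseq.scale_footprints(o, 5, 5) for g, o in occ.items()}
    kept = riboseq.coverage_filter(occ)
    return integrate.build_joint_table(profiles, ds.features, ds.usage, kept)


def make_reads(rows):
    import pandas as pd

    return pd.DataFrame(rows, columns=["gene_id", "five_prime_pos", "length"])


def make_gene_table(lengths: dict[str, int]):
    """lengths: gene_id -> protein length (codons)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "gene_id": list(lengths),
            "cds_length": [3 * (L + 1) for L in lengths.values()],
        }
    )
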