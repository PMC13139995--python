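import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from methylant.gene_methylation import ClassificationConfig
from methylant.simulate import (
    SimulationConfig,
    generate_annotation,
    generate_site_calls,
)
from methylant.site_io import make_site_table

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def small_config(**overrides) -> SimulationConfig:
    """A compact genome: one 400 kb chromosome, 30 genes, one TE island."""
    base = dict(
        seed=7,
        n_chrom=1,
        chrom_length=400_000,
        n_genes=30,
        gene_length_mean=4_000,
        n_te_islands_per_chrom=1,
        island_width=100_000,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_sim():
    """Annotation + site table + reads for a compact simulated genome."""
    config = small_config()
    genes, repeats, truth = generate_annotation(config)
    reads, sites = generate_site_calls(genes, truth, config, emit_reads=True)
    return {
        "config": config,
        "genes": genes,
        "repeats": repeats,
        "truth": truth,
        "reads": reads,
        "sites": sites,
        "classification": ClassificationConfig(),
    }


def site_table(rows):
    """Build a site table from (chrom, pos, strand, called, methylated) rows."""
    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "called_reads", "methylated_reads"]
    )
    return make_site_table(df)


@pytest.fixture()
def tiny_table():
    return site_table(
        [
            ("chr1", 100, "+", 10, 5),
            ("chr1", 101, "-", 10, 3),
            ("chr1", 200, "+", 10, 2),
            ("chr2", 50, "+", 9, 0),
        ]
    )


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
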