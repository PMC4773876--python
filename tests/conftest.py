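import numpy as np
import pytest

from promarch import (
    GeneModel,
    Scaffold,
    SimulationConfig,
    simulate_genome,
)


@pytest.fixture()
def toy_scaffold():
    rng = np.random.default_rng(11)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=30_000)])
    return Scaffold(id="s1", sequence=seq)


@pytest.fixture()
def toy_genes():
    """Two divergent genes with 5' UTRs plus one UTR-less tandem gene."""
    return [
        GeneModel(
            id="gA", scaffold_id="s1", strand="-", tx_start=2_000, tx_end=5_000,
            cds_start=2_000, cds_end=4_900, exons=((2_000, 3_000), (3_500, 5_000)),
        ),
        GeneModel(
            id="gB", scaffold_id="s1", strand="+", tx_start=5_600, tx_end=9_000,
            cds_start=5_700, cds_end=9_000, exons=((5_600, 6_400), (7_000, 9_000)),
        ),
        GeneModel(
            id="gC", scaffold_id="s1", strand="+", tx_start=15_000, tx_end=18_000,
            cds_start=15_000, cds_end=18_000,
        ),
    ]


@pytest.fixture(scope="session")
def sim_default():
    """A moderate synthetic genome under default (sponge-like) structure."""
    cfg = SimulationConfig(
        seed=101, n_scaffolds=2, scaffold_length_bp=500_000, n_genes=120
    )
    return cfg, *simulate_genome(cfg)


def compact_config(**overrides) -> SimulationConfig:
    """Compact gene structure so many genes fit per megabase."""
    base = dict(
        seed=7,
        n_scaffolds=4,
        scaffold_length_bp=500_000,
        n_genes=2_000,
        mean_introns_per_gene=1.0,
        exon_size_median_bp=120.0,
        intron_size_median_bp=150.0,
        intergenic_median_bp=300.0,
        intergenic_sigma=0.5,
        tss_distance_median_bp=500.0,
        cassette_separation_bp=200,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def sparse_config(**overrides) -> SimulationConfig:
    """Anchors spaced beyond the 500 bp scan span, so per-anchor flank
    windows are disjoint and planted per-anchor rates are measured without
    double counting."""
    base = dict(
        seed=7,
        n_scaffolds=4,
        scaffold_length_bp=1_200_000,
        n_genes=2_000,
        mean_introns_per_gene=1.0,
        exon_size_median_bp=120.0,
        intron_size_median_bp=150.0,
        intergenic_median_bp=800.0,
        intergenic_sigma=0.6,
        tss_distance_median_bp=600.0,
        cassette_separation_bp=1_500,
    )
    base.update(overrides)
    return SimulationConfig(**base)
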