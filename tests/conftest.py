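import numpy as np
import pytest

from qtlconverge.genome_model import GeneRecord, QtlInterval, sort_catalog
from qtlconverge.synthetic_data import (
    Hotspot,
    MappingPopulationConfig,
    PlantedQtl,
    SimulationConfig,
)


def random_catalog(rng, n_genes=600, n_chrom=3, length=10_000_000):
    """A small random, sorted gene catalog for interval/window tests."""
    records = []
    for c in range(n_chrom):
        starts = np.sort(rng.integers(0, length - 10_000, size=n_genes // n_chrom))
        for j, s in enumerate(starts):
            records.append(
                GeneRecord(
                    id=f"g{c + 1}_{j:04d}",
                    chromosome=f"chr{c + 1}",
                    start_bp=int(s),
                    end_bp=int(s) + int(rng.integers(500, 8_000)),
                    categories=frozenset(
                        rng.choice(["catA", "catB", "catC"], size=rng.integers(0, 3),
                                   replace=False)
                    ),
                )
            )
    return sort_catalog(records)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_catalog(rng):
    return random_catalog(rng)


@pytest.fixture
def small_config():
    """A reduced study layout: 3 chromosomes x 10 Mb, 900 genes, one hotspot."""
    hotspot = Hotspot(QtlInterval("hs1", "chr2", 3_000_000, 4_000_000), 0.75)
    qtl = PlantedQtl(QtlInterval("q1", "chr2", 3_000_000, 4_000_000), 0.13)
    return SimulationConfig(
        seed=7,
        n_chromosomes=3,
        chromosome_length_bp=10_000_000,
        n_genes=900,
        background_deg_rate=0.01,
        hotspots=(hotspot,),
        polymorphic_blocks=(QtlInterval("blk1", "chr2", 3_000_000, 4_000_000),),
        mapping_pop=MappingPopulationConfig(
            n_individuals=200, marker_spacing_bp=1_000_000, planted_qtl=(qtl,)
        ),
    )
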