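import numpy as np
import pytest

from luxcart import (
    GeneRecord,
    PlantedArrangement,
    ProteinRecord,
    SyntheticConfig,
)

CATEGORIES = ("canonical_pair", "luxR_solo", "luxI_solo", "double_luxR_luxI")


def make_gene(gene_id, start, end, strand="+", contig="ctg1", product="", genome="gnm"):
    return GeneRecord(
        genome_id=genome,
        contig_id=contig,
        start=start,
        end=end,
        strand=strand,
        gene_id=gene_id,
        product=product,
    )


def random_config(rng: np.random.Generator, decoy_rate: float = 0.0) -> SyntheticConfig:
    """A randomized generator configuration with 1-5 planted arrangements."""
    n_arr = int(rng.integers(1, 6))
    planted = []
    for _ in range(n_arr):
        category = CATEGORIES[int(rng.integers(len(CATEGORIES)))]
        topology = None
        if category == "double_luxR_luxI" and rng.random() < 0.5:
            topology = "T"
        planted.append(PlantedArrangement(category, topology))
    if rng.random() < 0.3:
        planted.append(PlantedArrangement("truncated_luxR"))
    return SyntheticConfig(
        n_contigs=int(rng.integers(1, 4)),
        n_background_genes=int(rng.integers(5, 30)),
        planted_arrangements=tuple(planted),
        mutation_rate=0.0,
        decoy_rate=decoy_rate,
        seed=int(rng.integers(2**31)),
    )


@pytest.fixture
def small_bundle():
    """One contig, one canonical pair, one solo, deterministic."""
    from luxcart import generate_bundle

    cfg = SyntheticConfig(
        n_contigs=1,
        n_background_genes=6,
        planted_arrangements=(
            PlantedArrangement("canonical_pair"),
            PlantedArrangement("luxR_solo"),
        ),
        seed=11,
    )
    return cfg, generate_bundle(cfg)
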