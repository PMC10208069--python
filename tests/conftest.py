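import numpy as np
import pytest

from bulkmap.simulate import (F2Population, Individual, SimConfig,
                              build_variant_map)


@pytest.fixture
def tiny_config():
    """One small chromosome; fast to simulate."""
    return SimConfig(n_chromosomes=1, chrom_length_bp=1_000_000,
                     chrom_length_cM=50.0, n_variants_per_chrom=5,
                     n_f2=40, bulk_size=5, mean_depth=30.0,
                     seq_error_rate=0.0, causal_chrom=0,
                     causal_pos_bp=450_000, gq_fail_fraction=0.0, seed=123)


def make_population(config, genotype_rows, phenotypes=None):
    """Build an F2Population with prescribed genotypes (0/1/2 per variant).

    Hets are phased hap1=0/hap2=1; phenotypes default to the dominance rule.
    """
    vmap = build_variant_map(config)
    individuals = []
    for i, row in enumerate(genotype_rows):
        row = np.asarray(row, dtype=np.int8)
        assert len(row) == vmap.n_variants
        hap1 = (row == 2).astype(np.int8)
        hap2 = (row >= 1).astype(np.int8)
        if phenotypes is not None:
            ph = phenotypes[i]
        else:
            ph = "yellow" if row[vmap.causal_index] == 2 else "green"
        individuals.append(Individual(id=f"F2_{i + 1:03d}", hap1=hap1,
                                      hap2=hap2, phenotype=ph))
    return F2Population(config=config, vmap=vmap, individuals=individuals)
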