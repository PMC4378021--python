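import pytest

from genopolish import synthetic_data as sd


@pytest.fixture(scope="session")
def bundle():
    """Default 150 kb three-chromosome genome with genes, repeats and gaps."""
    return sd.generate_genome(seed=11)


@pytest.fixture(scope="session")
def plain_genome():
    """Single-chromosome 100 kb genome without repeats or gaps."""
    cfg = sd.GenomeConfig(
        chromosome_lengths=(100_000,), n_genes=40, repeat_fraction=0.0, n_gaps=0
    )
    return sd.generate_genome(cfg, seed=7)


@pytest.fixture(scope="session")
def strain_pair(plain_genome):
    """A derived strain with the 8 substitutions / 2 deletions / 1 insertion
    inventory plus one tandem duplication, and pileups of both strains."""
    spec = sd.MutationSpec(substitutions=8, deletions=2, insertions=1, duplications=1)
    derived, truth = sd.mutate_strain(
        plain_genome.genome, spec, seed=21, genes=plain_genome.genes
    )
    track_a, pairs_a = sd.simulate_pileup(plain_genome.genome, 175, 0.002, seed=22)
    track_b, pairs_b = sd.simulate_pileup(
        plain_genome.genome, 205, 0.002, seed=23, truth=truth
    )
    return {
        "bundle": plain_genome,
        "derived": derived,
        "truth": truth,
        "track_a": track_a,
        "track_b": track_b,
        "pairs_b": pairs_b,
    }
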