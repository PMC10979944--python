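import pytest

from flavscreen.synthetic import gen_genome, gen_helix_bundle


@pytest.fixture(scope="session")
def small_genome():
    """10 single-contig genomes with 3 substrate, 3 decoy, 1 cytochrome clusters."""
    return gen_genome(
        n_contigs=10,
        genes_per_contig=40,
        n_substrate_clusters=3,
        n_decoys=3,
        n_cytochrome_clusters=1,
        seed=7,
    )


@pytest.fixture(scope="session")
def bundle():
    """6-helix TM bundle with 2 central bis-His pairs and 3 decoy His."""
    return gen_helix_bundle(
        n_helices=6,
        residues_per_helix=30,
        his_pair_depths=[0.0, 0.0],
        n_decoy_his=3,
        seed=7,
    )
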