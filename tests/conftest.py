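import pytest

from chronohelix.synthetic_data import SynthGenomeConfig, generate_genome


@pytest.fixture(scope="session")
def small_genome():
    """A small annotated synthetic genome shared by pipeline-level tests."""
    config = SynthGenomeConfig(length=40_000, n_regions=8, seed=11)
    genome, features, partition = generate_genome(config)
    return genome, features, partition


@pytest.fixture()
def fasta_gff_files(tmp_path):
    """Write a tiny synthetic genome to FASTA + GFF3 and return the paths."""
    config = SynthGenomeConfig(length=3_000, n_regions=3, seed=5)
    fasta = tmp_path / "genome.fasta"
    gff = tmp_path / "genome.gff3"
    genome, features, partition = generate_genome(
        config, fasta_path=fasta, gff_path=gff
    )
    return fasta, gff, genome, features, partition
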