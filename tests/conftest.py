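import pytest

from tucall.synthetic_data import SimParams, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One default-parameter synthetic dataset shared across tests."""
    return simulate_dataset(SimParams(seed=7))


@pytest.fixture()
def tiny_genome_files(tmp_path):
    """A minimal FASTA + GFF3 pair on disk."""
    fasta = tmp_path / "g.fasta"
    fasta.write_text(">chr1\n" + "ACGT" * 250 + "\n")
    gff = tmp_path / "g.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "chr1\ttest\tCDS\t101\t400\t.\t+\t0\tID=geneA\n"
        "chr1\ttest\tCDS\t501\t700\t.\t-\t0\tID=geneB\n"
    )
    return fasta, gff
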