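import numpy as np
import pytest
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from codonbias import synthetic
from codonbias.sequence_io import parse_host_codon_table


@pytest.fixture(scope="session")
def host_table_path():
    from importlib import resources

    return str(resources.files("codonbias.data").joinpath(
        "citrus_sinensis_synthetic.kazusa.txt"
    ))


@pytest.fixture(scope="session")
def host(host_table_path):
    return parse_host_codon_table(host_table_path, species="citrus")


@pytest.fixture(scope="session")
def pooled_counts_fixture():
    return synthetic.load_pooled_ctv_counts()


@pytest.fixture(scope="session")
def default_cohort():
    """The default 20-isolate, 3-group CTV-like cohort at seed 1 (shared
    across tests; treat as read-only)."""
    return synthetic.simulate_cohort(synthetic.default_cohort_spec(seed=1))


def write_genbank(path, isolate_id, cds_list):
    """Write a minimal single-record GenBank flat file.

    ``cds_list``: list of (orf_name, dna_cds_including_stop). ORFs are laid
    head-to-tail on the genome.
    """
    genome = "".join(seq for _, seq in cds_list)
    record = SeqRecord(Seq(genome), id=isolate_id, name=isolate_id[:16],
                       description="synthetic test genome")
    record.annotations["molecule_type"] = "ss-RNA"
    offset = 0
    for name, seq in cds_list:
        loc = FeatureLocation(offset, offset + len(seq), strand=1)
        record.features.append(
            SeqFeature(loc, type="CDS", qualifiers={"gene": [name]})
        )
        offset += len(seq)
    SeqIO.write([record], str(path), "genbank")
    return path


@pytest.fixture()
def genbank_writer():
    return write_genbank


def random_codon_counts(rng, lo=0, hi=50):
    """A random codon count table over all 64 codons (stops zeroed)."""
    from codonbias.composition import CodonCountTable
    from codonbias.genetic_code import SENSE_CODONS

    counts = {c: int(rng.integers(lo, hi + 1)) for c in SENSE_CODONS}
    return CodonCountTable(counts=counts, source_id="random")
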