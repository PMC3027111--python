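import numpy as np
import pytest

from prolang import AlphabetPolicy, Proteome


@pytest.fixture
def aa_policy():
    return AlphabetPolicy()


@pytest.fixture
def nt_policy():
    return AlphabetPolicy("ACGT")


@pytest.fixture
def worked_proteome():
    """The worked bigram-counting example sequence."""
    return Proteome("worked", ["AAANTSDSQKE"])


def random_proteome(rng, organism_id="rand", n_proteins=5, min_len=3,
                    max_len=60, alphabet="ACDEFGHIKLMNPQRSTVWY"):
    letters = list(alphabet)
    proteins = [
        "".join(rng.choice(letters, size=rng.integers(min_len, max_len + 1)))
        for _ in range(n_proteins)
    ]
    return Proteome(organism_id, proteins)


@pytest.fixture
def make_random_proteome():
    return random_proteome


def write_fasta(path, records, width=60):
    """Minimal FASTA writer independent of the package's own I/O."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@pytest.fixture
def fasta_writer():
    return write_fasta
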