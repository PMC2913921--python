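import numpy as np
import pytest

from hdpr.chem import RESIDUE_FORMULAS
from hdpr.incorporation import calibrate_from_peptides
from hdpr.simulate import AA_FREQUENCIES, generate_synthetic_peptides


@pytest.fixture(scope="session")
def reference_peptides():
    """A mid-sized synthetic reference set shared across tests."""
    return generate_synthetic_peptides(8000, seed=11)


@pytest.fixture(scope="session")
def reference(reference_peptides):
    return calibrate_from_peptides(
        reference_peptides,
        source="synthetic(8000, seed=11)",
        filters={"mz_min": 300.0, "mz_max": 6000.0, "len_min": 2, "len_max": 40},
    )


@pytest.fixture(scope="session")
def toy_fasta(tmp_path_factory):
    """A small synthetic proteome FASTA yielding a few hundred reference peptides."""
    rng = np.random.default_rng(42)
    letters = list(AA_FREQUENCIES)
    probs = np.array([AA_FREQUENCIES[a] for a in letters], dtype=float)
    probs /= probs.sum()
    path = tmp_path_factory.mktemp("data") / "toy_proteome.fasta"
    with open(path, "w") as fh:
        for i in range(40):
            seq = "".join(rng.choice(letters, size=400, p=probs))
            fh.write(f">synthetic_protein_{i}\n")
            for j in range(0, len(seq), 60):
                fh.write(seq[j : j + 60] + "\n")
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_sequence(rng, length):
    return "".join(rng.choice(list(RESIDUE_FORMULAS), size=length))
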