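import numpy as np
import pytest

from mtel.arrival import ECOLI
from mtel.binding import AffinityModel
from mtel.genetic_code import TRNASpecies


@pytest.fixture(scope="session")
def geom():
    return ECOLI


@pytest.fixture
def asp_trna():
    return TRNASpecies(id="Asp-GUC", anticodon="GUC", amino_acid="D", abundance=1000.0)


@pytest.fixture
def small_pool():
    """Four species decoding a Lys/Asn codon box, mixed cognate/near-cognate."""
    return [
        TRNASpecies(id="Lys-UUU", anticodon="UUU", amino_acid="K", abundance=20000.0),
        TRNASpecies(id="Asn-GUU", anticodon="GUU", amino_acid="N", abundance=8000.0),
        TRNASpecies(id="Glu-UUC", anticodon="UUC", amino_acid="E", abundance=15000.0),
        TRNASpecies(id="Thr-UGU", anticodon="UGU", amino_acid="T", abundance=5000.0),
    ]


@pytest.fixture
def wc_model():
    """A hand-built Watson-Crick-favoring affinity model."""
    model = AffinityModel(s1=1.5, s2=1.2)
    for c, ac in (("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")):
        model.set_affinity(c, ac, -2.0)
    for c in "ACGU":
        for ac in "ACGUL":
            if model.affinity(c, ac) == 0.0 and (c, ac) not in (
                ("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")
            ):
                model.set_affinity(c, ac, 1.0)
    return model


def random_pool(rng, n_species):
    """A random pool of distinct-anticodon species for property tests."""
    from mtel.genetic_code import SENSE_CODONS, cognate_anticodon, translate

    codons = rng.choice(len(SENSE_CODONS), size=n_species, replace=False)
    pool = []
    for i in codons:
        codon = SENSE_CODONS[i]
        pool.append(
            TRNASpecies(
                id=f"t{codon}",
                anticodon=cognate_anticodon(codon),
                amino_acid=translate(codon),
                abundance=float(np.exp(rng.uniform(np.log(1e3), np.log(1e5)))),
            )
        )
    return pool


def random_model(rng):
    return AffinityModel(rng.normal(scale=1.5, size=(4, 5)),
                         float(rng.uniform(0.5, 3)), float(rng.uniform(0.5, 3)))
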