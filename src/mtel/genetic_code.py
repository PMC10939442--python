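"""Canonical genetic-code tables and codon/anticodon geometry.

Everything downstream works in the RNA alphabet (A, C, G, U), codons and
anticodons both written 5'->3'.  Anticodons may additionally carry ``L``
(lysidine, a modified cytidine found at the wobble slot of bacterial
Ile-tRNA(CAU), which lets it decode AUA).  Because codon and anticodon run
antiparallel, codon position k pairs with anticodon position 4-k; the
wobble interaction is codon position 3 against anticodon position 1.

Residue masses are monoisotopic, in Daltons, to five decimal places.
Leucine and isoleucine share an elemental composition and therefore a
mass; mass spectrometry cannot distinguish a misincorporation of one from
the other, so they are merged into a single ``I/L`` category wherever
error destinations are tallied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

from Bio.Data import CodonTable

CODON_ALPHABET = "ACGU"
ANTICODON_ALPHABET = "ACGUL"
LYSIDINE = "L"

_STANDARD = CodonTable.unambiguous_rna_by_id[1]

#: codon -> one-letter amino acid, sense codons only (61 entries)
GENETIC_CODE = dict(_STANDARD.forward_table)
SENSE_CODONS: Tuple[str, ...] = tuple(sorted(GENETIC_CODE))
STOP_CODONS: Tuple[str, ...] = tuple(sorted(_STANDARD.stop_codons))

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

IL_MERGED = "I/L"

#: monoisotopic residue masses (Da), five decimals
RESIDUE_MASS = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

#: Watson-Crick pairs as (codon nucleotide, anticodon nucleotide)
WC_PAIRS = frozenset({("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")})

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


def merge_il(aa: str) -> str:
    """Collapse I and L into the shared mass-ambiguous category label."""
    return IL_MERGED if aa in ("I", "L") else aa


#: the 19 destination/correct categories after I/L merging, sorted
AA_CATEGORIES: Tuple[str, ...] = tuple(sorted({merge_il(a) for a in AMINO_ACIDS}))


class InvalidSequenceError(ValueError):
    """A codon or anticodon contains characters outside its alphabet."""


def validate_codon(codon: str) -> str:
    if len(codon) != 3:
        raise InvalidSequenceError(f"codon {codon!r} is not 3 nucleotides long")
    for ch in codon:
        if ch not in CODON_ALPHABET:
            raise InvalidSequenceError(
                f"codon {codon!r} contains invalid character {ch!r}"
            )
    return codon


def validate_anticodon(anticodon: str) -> str:
    if len(anticodon) != 3:
        raise InvalidSequenceError(
            f"anticodon {anticodon!r} is not 3 nucleotides long"
        )
    for i, ch in enumerate(anticodon):
        if ch not in ANTICODON_ALPHABET:
            raise InvalidSequenceError(
                f"anticodon {anticodon!r} contains invalid character {ch!r}"
            )
        if ch == LYSIDINE and i != 0:
            # lysidine sits in the anticodon wobble slot (position 1) only
            raise InvalidSequenceError(
                f"anticodon {anticodon!r}: lysidine permitted only at position 1"
            )
    if anticodon.count(LYSIDINE) > 1:
        raise InvalidSequenceError(f"anticodon {anticodon!r} has multiple lysidines")
    return anticodon


def translate(codon: str) -> str:
    """One-letter amino acid encoded by a sense codon."""
    validate_codon(codon)
    try:
        return GENETIC_CODE[codon]
    except KeyError:
        raise InvalidSequenceError(f"{codon} is a stop codon") from None


def cognate_anticodon(codon: str) -> str:
    """The perfectly Watson-Crick-matching anticodon (reverse complement)."""
    validate_codon(codon)
    return "".join(_COMPLEMENT[ch] for ch in reversed(codon))


@dataclass(frozen=True)
class TRNASpecies:
    """One tRNA species: anticodon, carried amino acid, cellular abundance.

    Abundance is in molecules per cell (as RNA-seq-derived pools report it);
    only ratios matter for arrival competition.
    """

    id: str
    anticodon: str
    amino_acid: str
    abundance: float

    def __post_init__(self) -> None:
        validate_anticodon(self.anticodon)
        if self.amino_acid not in AMINO_ACIDS:
            raise ValueError(f"unknown amino acid {self.amino_acid!r}")
        if self.abundance < 0:
            raise ValueError("abundance must be non-negative")


def align_codon_anticodon(codon: str, anticodon: str) -> List[Tuple[str, str]]:
    """Antiparallel alignment of a codon against an anticodon.

    Returns the three nucleotide pairs ``(codon[k], anticodon[4-k])`` for
    codon positions k = 1..3, so the last pair is the wobble interaction.
    """
    validate_codon(codon)
    validate_anticodon(anticodon)
    return [(codon[k], anticodon[2 - k]) for k in range(3)]


@dataclass(frozen=True)
class PairingClass:
    category: str  # cognate-WC | cognate-wobble | near-cognate | non-cognate
    mismatches: int


def classify_pairing(codon: str, trna: TRNASpecies) -> PairingClass:
    """Classify a codon/tRNA pairing by geometry and amino-acid identity.

    Cognate requires the tRNA's amino acid to equal the codon's translation:
    all-Watson-Crick pairing is cognate-WC, anything else cognate-wobble.
    With the wrong amino acid, one non-WC pair is near-cognate and more are
    non-cognate.  Non-WC pairs are counted literally, including wobble-style
    G:U and lysidine pairs.
    """
    pairs = align_codon_anticodon(codon, trna.anticodon)
    mismatches = sum(1 for p in pairs if p not in WC_PAIRS)
    if translate(codon) == trna.amino_acid:
        category = "cognate-WC" if mismatches == 0 else "cognate-wobble"
    else:
        category = "near-cognate" if mismatches <= 1 else "non-cognate"
    return PairingClass(category, mismatches)


def substitution_mass_delta(orig_aa: str, dest_aa: str) -> float:
    """Monoisotopic residue-mass difference dest - orig, in Da."""
    try:
        m_orig = RESIDUE_MASS[orig_aa]
        m_dest = RESIDUE_MASS[dest_aa]
    except KeyError as exc:
        raise KeyError(f"unknown residue code {exc.args[0]!r}") from None
    return m_dest - m_orig
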