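"""Effective codon/anticodon binding affinities and binding probabilities.

The effective binding affinity of codon i against anticodon j is a
positionally additive score

    dA_ij = sum_k a[c_k, ac_k] * s_k ,        k = 1..3,  s_3 = 1

built from a small nucleotide-pair affinity matrix ``a`` (codon nucleotide
x anticodon nucleotide, the anticodon side including lysidine) and two
site-importance weights s_1, s_2 expressed relative to the wobble position.
"Effective" means the score absorbs proofreading and conformational
contributions, not just hybridisation energy; it is unit-less and lower
values mean stronger binding.

Binding probabilities are Boltzmann weights over the tRNA pool at a codon,

    Pb_ij = exp(-dA_ij) / sum_k exp(-dA_ik) ,

so any transformation that shifts dA_i* by a codon-dependent constant is
unobservable.  Because each alignment uses exactly one matrix entry per
position, adding a constant to one *row* of ``a`` (one codon nucleotide)
is such a transformation: the likelihood fixes only within-row contrasts.
We therefore anchor one entry per row (column U) to zero and report
gauge-invariant quantities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Iterable, Sequence, Tuple

import numpy as np
from scipy.special import softmax

from .genetic_code import (
    ANTICODON_ALPHABET,
    CODON_ALPHABET,
    TRNASpecies,
    align_codon_anticodon,
    translate,
    validate_anticodon,
    validate_codon,
)

#: anchored (row, column) entries: one per codon-nucleotide row
GAUGE_ANCHORS: Tuple[Tuple[str, str], ...] = tuple((c, "U") for c in CODON_ALPHABET)

_C_IDX = {c: i for i, c in enumerate(CODON_ALPHABET)}
_AC_IDX = {c: i for i, c in enumerate(ANTICODON_ALPHABET)}


@dataclass
class AffinityModel:
    """Nucleotide-pair affinities plus positional weights.

    ``nucleotide_affinity`` is a 4x5 array indexed [codon nt, anticodon nt]
    with rows ordered A,C,G,U and columns A,C,G,U,L.  ``s1`` and ``s2``
    weight codon positions 1 and 2; position 3 (wobble) is the reference
    with weight fixed at 1.
    """

    nucleotide_affinity: np.ndarray = field(
        default_factory=lambda: np.zeros((4, 5), dtype=float)
    )
    s1: float = 1.0
    s2: float = 1.0

    def __post_init__(self) -> None:
        self.nucleotide_affinity = np.asarray(self.nucleotide_affinity, dtype=float)
        if self.nucleotide_affinity.shape != (4, 5):
            raise ValueError("nucleotide_affinity must be 4x5 (ACGU x ACGUL)")
        if not np.all(np.isfinite(self.nucleotide_affinity)):
            raise ValueError("nucleotide affinities must be finite")

    @property
    def site_weights(self) -> Tuple[float, float, float]:
        return (self.s1, self.s2, 1.0)

    def affinity(self, codon_nt: str, anticodon_nt: str) -> float:
        return float(self.nucleotide_affinity[_C_IDX[codon_nt], _AC_IDX[anticodon_nt]])

    def set_affinity(self, codon_nt: str, anticodon_nt: str, value: float) -> None:
        self.nucleotide_affinity[_C_IDX[codon_nt], _AC_IDX[anticodon_nt]] = value

    def gauge_fixed(self) -> "AffinityModel":
        """Return a copy with each row's anchored (column-U) entry at zero.

        Row shifts are unobservable (see module docstring); this picks the
        canonical representative of the gauge orbit.
        """
        a = self.nucleotide_affinity.copy()
        a -= a[:, [_AC_IDX["U"]]]
        return AffinityModel(a, self.s1, self.s2)

    def copy(self) -> "AffinityModel":
        return AffinityModel(self.nucleotide_affinity.copy(), self.s1, self.s2)

    def to_json(self) -> str:
        payload = {
            "nucleotide_affinity": {
                c: {ac: self.affinity(c, ac) for ac in ANTICODON_ALPHABET}
                for c in CODON_ALPHABET
            },
            "site_weights": {"s1": self.s1, "s2": self.s2},
            "gauge": "a[c][U]=0 per codon-nucleotide row",
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "AffinityModel":
        payload = json.loads(text)
        a = np.zeros((4, 5))
        for c, row in payload["nucleotide_affinity"].items():
            for ac, val in row.items():
                a[_C_IDX[c], _AC_IDX[ac]] = val
        sw = payload["site_weights"]
        return cls(a, float(sw["s1"]), float(sw["s2"]))


def effective_affinity(codon: str, anticodon: str, model: AffinityModel) -> float:
    """dA for one codon/anticodon pair (lower = stronger binding)."""
    pairs = align_codon_anticodon(codon, anticodon)
    weights = model.site_weights
    return float(
        sum(model.affinity(c, ac) * w for (c, ac), w in zip(pairs, weights))
    )


def affinity_matrix(
    codons: Sequence[str], anticodons: Sequence[str], model: AffinityModel
) -> np.ndarray:
    """dA for every codon x anticodon combination, vectorised.

    Computed for arbitrary anticodons, not only those of existing tRNAs,
    so hypothetical (missing) anticodons can be scored the same way.
    """
    for c in codons:
        validate_codon(c)
    for ac in anticodons:
        validate_anticodon(ac)
    C = np.array([[_C_IDX[ch] for ch in c] for c in codons])  # (nc, 3)
    # partner of codon position k (0-based) is anticodon position 2-k
    P = np.array([[_AC_IDX[ac[2 - k]] for k in range(3)] for ac in anticodons])
    w = np.asarray(model.site_weights)
    a = model.nucleotide_affinity
    dA = np.zeros((len(codons), len(anticodons)))
    for k in range(3):
        dA += a[np.ix_(C[:, k], P[:, k])] * w[k]
    return dA


def binding_probabilities(
    codon: str, pool: Sequence[TRNASpecies], model: AffinityModel
) -> Dict[str, float]:
    """Boltzmann binding probabilities over the pool at one codon.

    Softmax of -dA over all species present; species sharing an anticodon
    receive equal probability.  Max-subtraction inside the softmax guards
    against overflow without changing the result.
    """
    if len(pool) == 0:
        raise ValueError("empty tRNA pool")
    dA = affinity_matrix([codon], [t.anticodon for t in pool], model)[0]
    pb = softmax(-dA)
    return {t.id: float(p) for t, p in zip(pool, pb)}


def relative_affinity_profile(
    anticodon: str,
    amino_acid: str,
    codon_set: Iterable[str],
    model: AffinityModel,
) -> Dict[str, float]:
    """Per-codon dA offsets relative to the weakest synonymous interaction.

    Each codon in ``codon_set`` is scored as dA - min(dA over the codons
    synonymous with ``amino_acid``).  Negative values mean the anticodon
    binds that codon more strongly than its weakest synonymous codon —
    exactly the cross-reactivity a well-chosen tRNA repertoire avoids.
    The anticodon need not belong to an existing tRNA, which allows
    scoring hypothetical (missing) anticodons for in-silico pool swaps.
    """
    codons = list(codon_set)
    if not codons:
        raise ValueError("empty codon set")
    dA = affinity_matrix(codons, [anticodon], model)[:, 0]
    syn = [x for c, x in zip(codons, dA) if translate(c) == amino_acid]
    if not syn:
        raise ValueError(
            f"no codon in the set is synonymous with {amino_acid!r}"
        )
    ref = min(syn)
    return {c: float(x - ref) for c, x in zip(codons, dA)}
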