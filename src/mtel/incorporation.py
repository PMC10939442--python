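"""tRNA incorporation probabilities and the codon x amino-acid landscape.

A tRNA is incorporated either because it arrived first and bound, or
because every competitor that arrived earlier failed to bind.  With
exponential arrival times, competitor k is expected to arrive
lambda_k / lambda_i times before the focal species i, so

    PI_i(not first) = Pb_i * prod_{k != i} (1 - Pb_k)^(lambda_k / lambda_i)
    PI_i = Pb_i * Pfirst_i + PI_i(not first) * (1 - Pfirst_i) .

These raw PIs do not form a simplex; because observed misincorporation
counts are modelled as multinomial draws, the PIs are renormalised across
the pool per codon to define the category probabilities.  Aggregating the
normalised PIs by the amino acid each species carries (with I/L merged)
yields the mechanistic translation-error landscape: for every sense codon
the probability of incorporating each amino acid, and hence the per-codon
error probability and per-protein error-free translation probability

    Pf = prod_sites (1 - P_error(site)) .
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Sequence

import numpy as np
import pandas as pd

from .arrival import CellGeometry, pool_rates
from .binding import AffinityModel, affinity_matrix
from .genetic_code import (
    AA_CATEGORIES,
    SENSE_CODONS,
    TRNASpecies,
    merge_il,
    translate,
)

_CAT_IDX = {c: i for i, c in enumerate(AA_CATEGORIES)}

# Pb is clipped just below 1 before taking log(1 - Pb); the clip is far
# inside double precision and only matters when a competitor binds with
# certainty, where the exact product is 0 anyway.
_PB_CLIP = 1.0 - 1e-15


@dataclass
class ErrorLandscape:
    """Per-codon incorporation probabilities over amino-acid categories.

    ``probs[i, j]`` is the probability that codon ``codons[i]`` incorporates
    category ``categories[j]`` (I/L merged, so 19 categories).  Rows sum to
    one.  The correct-translation probability of a codon is the entry of
    its own (merged) amino acid.
    """

    codons: tuple
    categories: tuple
    probs: np.ndarray

    def _row(self, codon: str) -> np.ndarray:
        try:
            return self.probs[self.codons.index(codon)]
        except ValueError:
            raise KeyError(f"codon {codon!r} not in landscape") from None

    def p_correct(self, codon: str) -> float:
        aa = translate(codon)
        label = aa if aa in self.categories else merge_il(aa)
        return float(self._row(codon)[self.categories.index(label)])

    def p_error(self, codon: str) -> float:
        return 1.0 - self.p_correct(codon)

    def p_category(self, codon: str, category: str) -> float:
        return float(self._row(codon)[self.categories.index(category)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.probs, index=list(self.codons), columns=list(self.categories))

    def to_tsv(self, path) -> None:
        self.to_frame().rename_axis("codon").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "ErrorLandscape":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(tuple(df.index), tuple(df.columns), df.to_numpy(dtype=float))


class ForwardContext:
    """Pre-indexed pool/geometry state for fast repeated evaluation.

    Fitting re-evaluates the forward model tens of thousands of times, so
    the codon/anticodon alignment indices, arrival rates and the species ->
    amino-acid aggregation matrix are computed once per pool.  Species with
    zero abundance never arrive and are excluded up front.
    """

    def __init__(
        self,
        pool: Sequence[TRNASpecies],
        geom: CellGeometry,
        codons: Sequence[str] = SENSE_CODONS,
        merge: bool = True,
    ):
        pool = [t for t in pool if t.abundance > 0]
        if not pool:
            raise ValueError("pool is empty (or has zero total abundance)")
        self.pool = list(pool)
        self.geom = geom
        self.codons = tuple(codons)
        self.lam = pool_rates(self.pool, geom)
        self.p_first = self.lam / self.lam.sum()
        self.anticodons = [t.anticodon for t in self.pool]
        if merge:
            self.categories = AA_CATEGORIES
            labels = [merge_il(t.amino_acid) for t in self.pool]
        else:
            self.categories = tuple(sorted({t.amino_acid for t in self.pool}))
            labels = [t.amino_acid for t in self.pool]
        cat_idx = {c: i for i, c in enumerate(self.categories)}
        # species -> category one-hot, so probs @ agg aggregates per codon
        self.agg = np.zeros((len(self.pool), len(self.categories)))
        for j, lab in enumerate(labels):
            self.agg[j, cat_idx[lab]] = 1.0

    def incorporation(self, model: AffinityModel) -> np.ndarray:
        """Normalised incorporation probabilities, shape (codons, species)."""
        dA = affinity_matrix(self.codons, self.anticodons, model)
        shift = dA.min(axis=1, keepdims=True)
        w = np.exp(-(dA - shift))
        pb = w / w.sum(axis=1, keepdims=True)
        log1m = np.log1p(-np.minimum(pb, _PB_CLIP))
        total = (log1m * self.lam).sum(axis=1, keepdims=True)
        expo = (total - self.lam * log1m) / self.lam
        pi = pb * self.p_first + pb * np.exp(expo) * (1.0 - self.p_first)
        return pi / pi.sum(axis=1, keepdims=True)

    def landscape_probs(self, model: AffinityModel) -> np.ndarray:
        """Per-codon category probabilities, shape (codons, categories)."""
        return self.incorporation(model) @ self.agg


def incorporation_probabilities(
    codon: str,
    pool: Sequence[TRNASpecies],
    model: AffinityModel,
    geom: CellGeometry,
) -> Dict[str, float]:
    """Normalised per-species incorporation probabilities at one codon."""
    ctx = ForwardContext(pool, geom, codons=[codon])
    pi = ctx.incorporation(model)[0]
    return {t.id: float(p) for t, p in zip(ctx.pool, pi)}


def codon_error_probability(
    codon: str,
    pool: Sequence[TRNASpecies],
    model: AffinityModel,
    geom: CellGeometry,
) -> float:
    """Probability that the codon incorporates a non-synonymous amino acid.

    Synonymy is judged on the actual amino acid (no I/L merging): an
    isoleucine codon decoded with leucine counts as an error here even
    though mass spectrometry could not see it.
    """
    aa = translate(codon)
    if not any(t.amino_acid == aa for t in pool if t.abundance > 0):
        warnings.warn(
            f"no synonymous tRNA for codon {codon} in the pool; "
            "error probability will be large",
            stacklevel=2,
        )
    pi = incorporation_probabilities(codon, pool, model, geom)
    by_id = {t.id: t for t in pool}
    return float(sum(p for tid, p in pi.items() if by_id[tid].amino_acid != aa))


def build_landscape(
    pool: Sequence[TRNASpecies],
    model: AffinityModel,
    geom: CellGeometry,
    merge: bool = True,
) -> ErrorLandscape:
    """Assemble the full codon x amino-acid-category landscape.

    ``merge=True`` (default) folds I and L into the shared mass-ambiguous
    category, matching what proteomics can observe; ``merge=False`` keeps
    all 20 amino acids, which the fitness layer prefers since variant-effect
    scores distinguish I from L.
    """
    ctx = ForwardContext(pool, geom, merge=merge)
    return ErrorLandscape(ctx.codons, ctx.categories, ctx.landscape_probs(model))


def protein_error_free_probability(
    codon_sequence: Sequence[str], landscape: ErrorLandscape
) -> float:
    """Probability the whole protein is translated without a single error.

    Sites are independent, so this is the product of per-site synonymous-
    incorporation probabilities; an empty sequence gives 1.
    """
    pf = 1.0
    for codon in codon_sequence:
        pf *= landscape.p_correct(codon)
    return pf
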