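"""Error-aware fitness landscape: site costs, protein burdens, fixation.

Combining a misincorporation landscape with per-site variant-effect
scores dE (0 for the encoded residue, lower = more severe) gives the
expected fitness cost of mistranslating a site,

    dx_{s,p} = sum_a P_{s(c),a} * dE(sigma_a^{s,p}) ,

and, weighted by the protein's proteome fraction phi_p, the burden of a
protein's error-prone translation, dx_p = phi_p * sum_s dx_{s,p}.  Costs
feed the Sella-Hirsh relative fixation probability

    Theta = 2S / (1 - exp(-2S)),    S = q * Ne * dx ,

against the error-free reference; |Theta - 1| <= 0.05 is treated as the
nearly-neutral band.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import ranksums
from statsmodels.stats.multitest import multipletests

from .genetic_code import IL_MERGED, translate, validate_codon
from .incorporation import ErrorLandscape

Q_PROTEIN_COST = 4.19e-7  # scaling of protein-production cost into S


@dataclass(frozen=True)
class PopGenParams:
    """Effective population size and protein-production cost scaling."""

    ne: float
    q: float = Q_PROTEIN_COST

    def __post_init__(self) -> None:
        if self.ne < 1:
            raise ValueError("effective population size must be >= 1")
        if self.q <= 0:
            raise ValueError("q must be positive")


POPGEN_PRESETS = {
    "ecoli": PopGenParams(ne=1e8),
    "scerevisiae": PopGenParams(ne=8.6e6),
    "yeast": PopGenParams(ne=8.6e6),
}


@dataclass(frozen=True)
class ProteomeEntry:
    """A protein's codon sequence and its proteome fraction phi."""

    protein_id: str
    codons: Tuple[str, ...]
    phi: float

    def __post_init__(self) -> None:
        for c in self.codons:
            validate_codon(c)
            translate(c)  # rejects stop codons
        if self.phi < 0:
            raise ValueError("phi must be non-negative")

    @property
    def sequence(self) -> str:
        return "".join(translate(c) for c in self.codons)


@dataclass
class FitnessScores:
    """dE score tables: protein -> site (1-based) -> amino acid -> score."""

    scores: Dict[str, Dict[int, Dict[str, float]]] = field(default_factory=dict)

    def site(self, protein_id: str, position: int) -> Optional[Dict[str, float]]:
        return self.scores.get(protein_id, {}).get(position)

    def set(self, protein_id: str, position: int, amino_acid: str, value: float):
        self.scores.setdefault(protein_id, {}).setdefault(position, {})[
            amino_acid
        ] = value


def _category_score(category: str, site_scores: Mapping[str, float]) -> Optional[float]:
    if category == IL_MERGED:
        vals = [site_scores[a] for a in ("I", "L") if a in site_scores]
        return float(np.mean(vals)) if vals else None
    return site_scores.get(category)


def site_cost(
    codon: str,
    site_scores: Mapping[str, float],
    landscape: ErrorLandscape,
    missing: str = "error",
) -> float:
    """Probability-weighted expected dE of mistranslating one site.

    The encoded amino acid contributes 0 by definition, so the sum
    effectively runs over misincorporations.  With a merged landscape the
    I/L category uses the mean of the I and L scores.  ``missing``
    controls what happens when an amino acid with nonzero probability has
    no score: ``"error"`` raises, ``"renormalize"`` drops the category and
    rescales the remaining probabilities.
    """
    own = translate(codon)
    probs = []
    scores = []
    for cat in landscape.categories:
        p = landscape.p_category(codon, cat)
        if cat == own or (cat == IL_MERGED and own in ("I", "L")):
            probs.append(p)
            scores.append(0.0)
            continue
        s = _category_score(cat, site_scores)
        if s is None:
            if p > 0 and missing == "error":
                raise KeyError(
                    f"no dE score for category {cat} at a {codon} site"
                )
            continue  # renormalize: drop the category
        probs.append(p)
        scores.append(s)
    probs_arr = np.asarray(probs)
    total = probs_arr.sum()
    if missing == "renormalize" and total > 0:
        probs_arr = probs_arr / total
    return float(np.dot(probs_arr, scores))


def protein_site_costs(
    entry: ProteomeEntry,
    scores: FitnessScores,
    landscape: ErrorLandscape,
    missing: str = "error",
) -> List[float]:
    """Site costs along one protein; sites without any scores cost 0."""
    out = []
    for i, codon in enumerate(entry.codons, start=1):
        site_scores = scores.site(entry.protein_id, i)
        out.append(
            0.0
            if site_scores is None
            else site_cost(codon, site_scores, landscape, missing=missing)
        )
    return out


def protein_burden(entry: ProteomeEntry, site_costs: Sequence[float]) -> float:
    """Abundance-weighted total cost dx_p = phi_p * sum_s dx_{s,p}."""
    return entry.phi * float(np.sum(site_costs))


def organismal_burden(
    entries: Sequence[ProteomeEntry],
    scores: FitnessScores,
    landscape: ErrorLandscape,
    missing: str = "error",
) -> float:
    """Total dx = sum_p dx_p over the proteome."""
    return float(
        sum(
            protein_burden(e, protein_site_costs(e, scores, landscape, missing))
            for e in entries
        )
    )


def fixation_ratio(dx: float, popgen: PopGenParams) -> float:
    """Sella-Hirsh relative fixation probability Theta(dx).

    Theta = 2S / (1 - exp(-2S)) with S = q * Ne * dx, continuous at 0
    (limit 1, via series expansion for tiny |S|) and numerically stable
    for strongly deleterious costs, where Theta ~ -2S * exp(2S) underflows
    gracefully to 0.
    """
    if not math.isfinite(dx):
        raise ValueError("dx must be finite")
    s = popgen.q * popgen.ne * dx
    t = 2.0 * s
    if t == 0.0:
        return 1.0
    if t < -700.0:
        return -t * math.exp(t)  # exp(-t) would overflow; asymptotic form
    return t / (-math.expm1(-t))  # expm1 keeps precision near t = 0


def classify_effect(theta: float, band: float = 0.05) -> str:
    """'neutral' within the band around 1, else 'deleterious'/'advantageous'."""
    if theta < 0:
        raise ValueError("Theta is a probability ratio and cannot be negative")
    if theta < 1.0 - band:
        return "deleterious"
    if theta > 1.0 + band:
        return "advantageous"
    return "neutral"


def classify_sites(
    site_costs: Iterable[float],
    popgen: PopGenParams,
    band: float = 0.05,
    weights: Optional[Sequence[float]] = None,
) -> Dict[str, float]:
    """Fractions of sites per effect class, optionally weighted."""
    costs = list(site_costs)
    if not costs:
        raise ValueError("no site costs supplied")
    w = np.ones(len(costs)) if weights is None else np.asarray(weights, dtype=float)
    if len(w) != len(costs):
        raise ValueError("one weight per site required")
    labels = [classify_effect(fixation_ratio(dx, popgen), band) for dx in costs]
    total = w.sum()
    out = {"neutral": 0.0, "deleterious": 0.0, "advantageous": 0.0}
    for lab, wi in zip(labels, w):
        out[lab] += wi / total
    return out


def synonymous_cost_comparison(
    site_costs_by_codon: Mapping[str, Sequence[float]],
    rscu: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """Pairwise rank-sum comparisons of site costs between synonymous codons.

    Groups codons by encoded amino acid (families with a single observed
    codon are skipped), runs Wilcoxon's rank-sum test on every within-family
    codon pair, and reports raw p-values alongside Benjamini-Hochberg
    q-values across all pairs.  When RSCU values are given, each codon is
    annotated as preferred (RSCU > 1) or not.
    """
    by_aa: Dict[str, List[str]] = {}
    for codon, costs in site_costs_by_codon.items():
        if len(costs) == 0:
            raise ValueError(f"codon {codon} has an empty cost distribution")
        by_aa.setdefault(translate(codon), []).append(codon)

    rows = []
    for aa, codons in sorted(by_aa.items()):
        if len(codons) < 2:
            continue
        for ca, cb in combinations(sorted(codons), 2):
            xa = np.asarray(site_costs_by_codon[ca], dtype=float)
            xb = np.asarray(site_costs_by_codon[cb], dtype=float)
            stat, p = ranksums(xa, xb)
            row = {
                "amino_acid": aa,
                "codon_a": ca,
                "codon_b": cb,
                "n_a": len(xa),
                "n_b": len(xb),
                "median_a": float(np.median(xa)),
                "median_b": float(np.median(xb)),
                "statistic": float(stat),
                "pvalue": float(p),
            }
            if rscu is not None:
                row["rscu_a"] = rscu.get(ca)
                row["rscu_b"] = rscu.get(cb)
                row["preferred_a"] = rscu.get(ca, 0) > 1
                row["preferred_b"] = rscu.get(cb, 0) > 1
            rows.append(row)
    if not rows:
        warnings.warn("no multi-codon family with data; empty comparison", stacklevel=2)
        return pd.DataFrame(rows)
    df = pd.DataFrame(rows)
    df["qvalue"] = multipletests(df["pvalue"], method="fdr_bh")[1]
    return df
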