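"""Diffusion-limited tRNA arrival rates and arrival-order probabilities.

tRNAs reach the ribosomal A-site by diffusion alone.  The cell is
discretised into n = V / l^3 sites (V cell volume, l effective tRNA
length); a tRNA hops between neighbouring sites with transition time
tau = l^2 / (6 D).  A species with copy number [tRNA_i] occupies a given
site with probability [tRNA_i] / n, so its arrival rate at the A-site is

    lambda_i = ([tRNA_i] / n) / tau .

Arrival waiting times are exponential, which makes arrival-order
probabilities a simple rate race: P(i before j) = lambda_i / (lambda_i +
lambda_j), extending to sets of competitors by summing their rates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Sequence, Union

import numpy as np
import yaml

from .genetic_code import TRNASpecies


@dataclass(frozen=True)
class CellGeometry:
    """Cell volume, tRNA length and diffusion coefficient (SI units)."""

    volume: float  # m^3
    trna_length: float  # m
    diffusion_coeff: float  # m^2/s

    def __post_init__(self) -> None:
        if self.volume <= 0 or self.trna_length <= 0 or self.diffusion_coeff <= 0:
            raise ValueError("geometry parameters must be strictly positive")

    @property
    def n_sites(self) -> float:
        """Number of discrete tRNA-sized locations in the cell, V / l^3."""
        return self.volume / self.trna_length**3

    @property
    def transition_time(self) -> float:
        """Site-to-site diffusive transition time tau = l^2 / (6 D), in s."""
        return self.trna_length**2 / (6.0 * self.diffusion_coeff)


# species presets; volumes differ, tRNA length and diffusion are shared
ECOLI = CellGeometry(volume=0.6e-18, trna_length=1.58e-8, diffusion_coeff=8.42e-11)
SCEREVISIAE = CellGeometry(volume=4.2e-17, trna_length=1.58e-8, diffusion_coeff=8.42e-11)

GEOMETRY_PRESETS: Dict[str, CellGeometry] = {
    "ecoli": ECOLI,
    "scerevisiae": SCEREVISIAE,
    "yeast": SCEREVISIAE,
}


def geometry_from_yaml(path) -> CellGeometry:
    """Load a custom geometry from a YAML file.

    Expected keys: ``volume_m3``, ``trna_length_m``, ``diffusion_m2s``.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return CellGeometry(
        volume=float(cfg["volume_m3"]),
        trna_length=float(cfg["trna_length_m"]),
        diffusion_coeff=float(cfg["diffusion_m2s"]),
    )


def arrival_rate(trna: Union[TRNASpecies, float], geom: CellGeometry) -> float:
    """Arrival rate lambda (1/s) of one tRNA species at the A-site.

    Accepts either a :class:`TRNASpecies` or a bare abundance (molecules
    per cell).  Zero abundance gives a zero rate.
    """
    abundance = trna.abundance if isinstance(trna, TRNASpecies) else float(trna)
    if abundance < 0:
        raise ValueError("abundance must be non-negative")
    occupancy = abundance / geom.n_sites
    return occupancy / geom.transition_time


def pool_rates(pool: Sequence[TRNASpecies], geom: CellGeometry) -> np.ndarray:
    """Vector of arrival rates for a pool, in pool order."""
    if len(pool) == 0:
        raise ValueError("empty tRNA pool")
    return np.array([arrival_rate(t, geom) for t in pool], dtype=float)


def p_arrive_before(lam_i: float, lam_others: Union[float, Iterable[float]]) -> float:
    """Probability that the focal tRNA arrives before a competitor (or set).

    With exponential waiting times the race is decided by rates alone:
    lambda_i / (lambda_i + lambda_j), where lambda_j may be the summed rate
    of any competitor set.
    """
    lam_j = (
        float(np.sum(np.fromiter(lam_others, dtype=float)))
        if np.iterable(lam_others)
        else float(lam_others)
    )
    if lam_i < 0 or lam_j < 0:
        raise ValueError("rates must be non-negative")
    total = lam_i + lam_j
    if total == 0:
        raise ZeroDivisionError("both competing rates are zero; race undefined")
    return lam_i / total


def p_first(
    trna: TRNASpecies, pool: Sequence[TRNASpecies], geom: CellGeometry
) -> float:
    """Probability that ``trna`` arrives before every other pool member."""
    rates = pool_rates(pool, geom)
    total = rates.sum()
    if total == 0:
        raise ZeroDivisionError("pool has zero total abundance")
    lam_i = arrival_rate(trna, geom)
    return lam_i / total


def expected_arrivals_before(lam_k: float, lam_i: float) -> float:
    """Expected number of arrivals of competitor k per focal i arrival.

    This is lambda_k / lambda_i, used downstream as a continuous exponent
    counting how many times k gets a binding attempt before i shows up.
    """
    if lam_i <= 0:
        raise ZeroDivisionError("focal arrival rate must be positive")
    if lam_k < 0:
        raise ValueError("competitor rate must be non-negative")
    return lam_k / lam_i


def occupancy_probabilities(
    pool: Sequence[TRNASpecies], geom: CellGeometry
) -> Mapping[str, float]:
    """Per-species probability of occupying a given cell location."""
    n = geom.n_sites
    return {t.id: t.abundance / n for t in pool}
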