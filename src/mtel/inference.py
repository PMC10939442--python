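"""Multinomial likelihood of misincorporation counts and MCMC fitting.

Observed per-codon counts (correct translations plus misincorporations to
each destination amino acid, I/L merged) are modelled as one multinomial
draw per codon with category probabilities from the forward incorporation
model.  The affinity parameters are sampled by Metropolis-within-Gibbs:
one Gaussian random-walk update per scalar parameter per sweep, with
proposal scales adapted during burn-in only.  Priors are flat on a wide
box (affinities within +/-50, site weights in [0, 50]); the posterior is
proportional to the likelihood inside the box.

Only within-row contrasts of the nucleotide-affinity matrix are
identifiable (see :mod:`mtel.binding`), so one entry per codon-nucleotide
row is anchored at zero during sampling, and only entries that actually
occur in the pool's codon/anticodon alignments are treated as free
parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .arrival import CellGeometry
from .binding import AffinityModel, GAUGE_ANCHORS
from .genetic_code import (
    ANTICODON_ALPHABET,
    CODON_ALPHABET,
    TRNASpecies,
    merge_il,
    translate,
    validate_codon,
)
from .incorporation import ForwardContext

_AFFINITY_BOUND = 50.0
_S_BOUNDS = (0.0, 50.0)


@dataclass
class CodonObservation:
    """Counts for one codon: total PSM-level observations and errors.

    ``error_counts`` maps destination category (I/L merged) to the number
    of observed misincorporations; the correct count is the remainder.
    """

    codon: str
    total_count: int
    error_counts: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        validate_codon(self.codon)
        if self.total_count < 0:
            raise ValueError("total_count must be non-negative")
        own = merge_il(translate(self.codon))
        for dest, n in self.error_counts.items():
            if n < 0:
                raise ValueError("error counts must be non-negative")
            if dest == own:
                raise ValueError(
                    f"destination {dest} equals the codon's own amino acid"
                )
        if sum(self.error_counts.values()) > self.total_count:
            raise ValueError("error counts exceed total count")

    @property
    def correct_count(self) -> int:
        return self.total_count - sum(self.error_counts.values())


@dataclass
class MCMCConfig:
    """Chain configuration.

    ``steps`` counts all sweeps including burn-in; every ``thin``-th
    post-burn-in sweep is recorded and the last ``max_retained`` records
    form the posterior sample.  The defaults retain 500 draws.
    """

    steps: int = 10_000
    burnin: int = 5_000
    thin: int = 10
    max_retained: int = 500
    initial_scale: float = 0.3
    adapt_interval: int = 50
    target_acceptance: float = 0.3

    def __post_init__(self) -> None:
        if self.steps <= 0 or self.burnin < 0 or self.thin <= 0:
            raise ValueError("steps, burnin and thin must be positive")
        if self.burnin >= self.steps:
            raise ValueError("burn-in must be shorter than the chain")

    @property
    def n_retained(self) -> int:
        return min((self.steps - self.burnin) // self.thin, self.max_retained)


@dataclass
class PosteriorChain:
    """Retained posterior draws plus the full log-posterior trace."""

    samples: List[AffinityModel]
    log_posterior: np.ndarray
    seed: int
    config: MCMCConfig
    parameter_names: List[str]
    acceptance_rates: Dict[str, float]

    def parameter_array(self) -> np.ndarray:
        """Retained samples as an array, columns in ``parameter_names`` order."""
        return np.array(
            [_extract(m, self.parameter_names) for m in self.samples]
        )


def _extract(model: AffinityModel, names: Sequence[str]) -> List[float]:
    out = []
    for name in names:
        if name == "s1":
            out.append(model.s1)
        elif name == "s2":
            out.append(model.s2)
        else:  # "a[C][AC]"
            out.append(model.affinity(name[2], name[5]))
    return out


class _Likelihood:
    """Counts aligned to the forward model's category grid."""

    def __init__(
        self,
        observations: Sequence[CodonObservation],
        pool: Sequence[TRNASpecies],
        geom: CellGeometry,
        masked: Optional[Dict[str, Set[str]]] = None,
        on_unproducible: str = "error",
    ):
        if not observations:
            self.empty = True
            return
        self.empty = False
        codons = [o.codon for o in observations]
        if len(set(codons)) != len(codons):
            raise ValueError("duplicate codon in observations; pool them first")
        self.ctx = ForwardContext(pool, geom, codons=codons, merge=True)
        cats = self.ctx.categories
        cat_idx = {c: i for i, c in enumerate(cats)}
        self.counts = np.zeros((len(codons), len(cats)))
        self.include = np.ones_like(self.counts, dtype=bool)
        for i, obs in enumerate(observations):
            own = merge_il(translate(obs.codon))
            self.counts[i, cat_idx[own]] = obs.correct_count
            for dest, n in obs.error_counts.items():
                if dest not in cat_idx:
                    raise KeyError(f"unknown destination category {dest!r}")
                self.counts[i, cat_idx[dest]] = n
            if masked and obs.codon in masked:
                for dest in masked[obs.codon]:
                    self.include[i, cat_idx[dest]] = False
        # destinations no tRNA mismatch can produce have structural zero
        # probability; observing them is a data/model inconsistency
        producible = (self.ctx.agg.sum(axis=0) > 0)[None, :]
        bad = (self.counts > 0) & ~producible & self.include
        if bad.any():
            if on_unproducible == "drop":
                warnings.warn(
                    f"dropping {int(self.counts[bad].sum())} counts in "
                    "destinations no pool tRNA can produce",
                    stacklevel=3,
                )
                self.counts[bad] = 0.0
            else:
                raise ValueError(
                    "observations contain destinations no pool tRNA produces; "
                    "pass on_unproducible='drop' to discard them"
                )
        self.counts[~self.include] = 0.0
        totals = self.counts.sum(axis=1)
        # multinomial normalisation constant, fixed given the counts
        self.log_const = float(
            (gammaln(totals + 1.0) - gammaln(self.counts + 1.0).sum(axis=1)).sum()
        )

    def __call__(self, model: AffinityModel) -> float:
        if self.empty:
            return 0.0
        probs = self.ctx.landscape_probs(model)
        probs = np.where(self.include, probs, 0.0)
        probs /= probs.sum(axis=1, keepdims=True)
        mask = self.counts > 0
        with np.errstate(divide="ignore"):
            logp = np.log(probs[mask])
        return self.log_const + float((self.counts[mask] * logp).sum())


def log_likelihood(
    model: AffinityModel,
    observations: Sequence[CodonObservation],
    pool: Sequence[TRNASpecies],
    geom: CellGeometry,
    masked: Optional[Dict[str, Set[str]]] = None,
    on_unproducible: str = "error",
) -> float:
    """Multinomial log-likelihood of the observations under the model.

    Includes the multinomial coefficient, so an empty observation set
    scores exactly 0.  ``masked`` maps codon -> destination categories to
    exclude (e.g. substitutions indistinguishable from PTMs); the
    remaining categories are renormalised at likelihood time only.
    """
    return _Likelihood(observations, pool, geom, masked, on_unproducible)(model)


def _free_parameters(
    pool: Sequence[TRNASpecies],
) -> Tuple[List[Tuple[int, int]], List[str]]:
    """Affinity entries that occur in some codon/anticodon alignment.

    Anchored entries (one per used row) are excluded; entries never used
    by the pool would have a flat posterior and are left at zero.
    """
    c_idx = {c: i for i, c in enumerate(CODON_ALPHABET)}
    ac_idx = {c: i for i, c in enumerate(ANTICODON_ALPHABET)}
    used: Set[Tuple[int, int]] = set()
    anticodons = {t.anticodon for t in pool if t.abundance > 0}
    for ac in anticodons:
        for k in range(3):
            partner = ac[2 - k]
            for codon_nt in CODON_ALPHABET:  # codons span all nts at each k
                used.add((c_idx[codon_nt], ac_idx[partner]))
    anchors = set()
    for row_nt, col_nt in GAUGE_ANCHORS:
        entry = (c_idx[row_nt], ac_idx[col_nt])
        if entry in used:
            anchors.add(entry)
        else:
            # fall back to the first used entry of the row, if any
            row_used = sorted(e for e in used if e[0] == c_idx[row_nt])
            if row_used:
                anchors.add(row_used[0])
    free = sorted(used - anchors)
    names = [
        f"a[{CODON_ALPHABET[r]}][{ANTICODON_ALPHABET[c]}]" for r, c in free
    ]
    return free, names


def fit_mcmc(
    observations: Sequence[CodonObservation],
    pool: Sequence[TRNASpecies],
    geom: CellGeometry,
    config: Optional[MCMCConfig] = None,
    seed: int = 0,
    masked: Optional[Dict[str, Set[str]]] = None,
    on_unproducible: str = "error",
) -> PosteriorChain:
    """Fit the affinity model by Metropolis-within-Gibbs random walk.

    Deterministic given ``seed``.  Raises if no observation is supplied.
    """
    if not observations:
        raise ValueError("at least one observation is required")
    config = config or MCMCConfig()
    rng = np.random.default_rng(seed)
    loglik = _Likelihood(observations, pool, geom, masked, on_unproducible)

    free, names = _free_parameters(pool)
    all_names = names + ["s1", "s2"]
    n_par = len(all_names)

    model = AffinityModel()  # affinities 0, s1 = s2 = 1
    ll = loglik(model)
    attempts = 0
    while not np.isfinite(ll):
        attempts += 1
        if attempts > 20:
            raise RuntimeError("could not find a finite-likelihood start point")
        warnings.warn(
            f"non-finite likelihood at initialization; jittered restart {attempts}",
            stacklevel=2,
        )
        a = rng.normal(scale=0.5, size=(4, 5))
        model = AffinityModel(a, 1.0 + abs(rng.normal(scale=0.2)), 1.0 + abs(rng.normal(scale=0.2)))
        ll = loglik(model)

    # joint row-shift moves: contrasts within a row are sharply informed
    # while the offset of a row's free entries against its anchored entry
    # is only weakly constrained, so scalar updates crawl along that
    # ridge; shifting a whole row at once mixes the slow direction
    row_groups = [
        [i for i, (r, _) in enumerate(free) if r == row]
        for row in range(len(CODON_ALPHABET))
    ]
    row_groups = [g for g in row_groups if len(g) > 1]
    n_groups = len(row_groups)

    scales = np.full(n_par + n_groups, config.initial_scale)
    accepted = np.zeros(n_par + n_groups)
    proposed = np.zeros(n_par + n_groups)
    accepted_total = np.zeros(n_par + n_groups)
    proposed_total = np.zeros(n_par + n_groups)

    trace = np.empty(config.steps)
    records: List[AffinityModel] = []
    a = model.nucleotide_affinity  # mutated in place during sampling
    s = np.array([model.s1, model.s2])

    def set_param(p: int, value: float) -> float:
        if p < len(free):
            r, c = free[p]
            old = a[r, c]
            a[r, c] = value
        else:
            j = p - len(free)
            old = s[j]
            s[j] = value
            model.s1, model.s2 = s
        return old

    def get_param(p: int) -> float:
        if p < len(free):
            r, c = free[p]
            return a[r, c]
        return s[p - len(free)]

    def in_box(p: int, value: float) -> bool:
        if p < len(free):
            return abs(value) <= _AFFINITY_BOUND
        return _S_BOUNDS[0] <= value <= _S_BOUNDS[1]

    for step in range(config.steps):
        for p in range(n_par):
            proposed[p] += 1
            proposed_total[p] += 1
            current = get_param(p)
            candidate = current + rng.normal() * scales[p]
            if not in_box(p, candidate):
                continue
            old = set_param(p, candidate)
            ll_new = loglik(model)
            if np.log(rng.uniform()) < ll_new - ll:
                ll = ll_new
                accepted[p] += 1
                accepted_total[p] += 1
            else:
                set_param(p, old)
        for g, group in enumerate(row_groups):
            idx = n_par + g
            proposed[idx] += 1
            proposed_total[idx] += 1
            delta = rng.normal() * scales[idx]
            rows_cols = [free[p] for p in group]
            olds = [a[r, c] for r, c in rows_cols]
            if any(abs(v + delta) > _AFFINITY_BOUND for v in olds):
                continue
            for r, c in rows_cols:
                a[r, c] += delta
            ll_new = loglik(model)
            if np.log(rng.uniform()) < ll_new - ll:
                ll = ll_new
                accepted[idx] += 1
                accepted_total[idx] += 1
            else:
                for (r, c), v in zip(rows_cols, olds):
                    a[r, c] = v
        trace[step] = ll
        if step < config.burnin and (step + 1) % config.adapt_interval == 0:
            rates = accepted / np.maximum(proposed, 1)
            scales *= np.exp(rates - config.target_acceptance)
            scales = np.clip(scales, 1e-4, 10.0)
            accepted[:] = 0
            proposed[:] = 0
        if step >= config.burnin and (step - config.burnin + 1) % config.thin == 0:
            records.append(AffinityModel(a.copy(), float(s[0]), float(s[1])))

    retained = records[-config.n_retained :] if config.n_retained else []
    overall = accepted_total / np.maximum(proposed_total, 1)
    group_names = [f"row[{CODON_ALPHABET[free[g[0]][0]]}]" for g in row_groups]
    rate_map = dict(zip(all_names + group_names, overall.tolist()))
    mean_rate = float(overall[:n_par].mean())
    if not (0.1 <= mean_rate <= 0.6):
        warnings.warn(
            f"mean acceptance rate {mean_rate:.2f} outside the [0.1, 0.6] "
            "diagnostic band",
            stacklevel=2,
        )
    return PosteriorChain(
        samples=retained,
        log_posterior=trace,
        seed=seed,
        config=config,
        parameter_names=all_names,
        acceptance_rates=rate_map,
    )


def posterior_summary(chain: PosteriorChain, level: float = 0.95) -> pd.DataFrame:
    """Mean, sd and central credible interval per parameter.

    Computed on the retained samples only.
    """
    if not chain.samples:
        raise ValueError("chain has no retained samples")
    if not 0 < level < 1:
        raise ValueError("credible level must be in (0, 1)")
    arr = chain.parameter_array()
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(arr, [alpha, 1.0 - alpha], axis=0)
    return pd.DataFrame(
        {
            "mean": arr.mean(axis=0),
            "sd": arr.std(axis=0, ddof=1) if len(arr) > 1 else np.zeros(arr.shape[1]),
            "ci_low": lo,
            "ci_high": hi,
        },
        index=chain.parameter_names,
    )
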