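"""Independent reference implementations used only to check the package.

Everything here is written as a direct, slow transcription of the model
definitions (plain Python loops, factorial arithmetic, Monte-Carlo
simulation) and deliberately shares no code with the library paths it
validates.
"""

import math

import numpy as np


def brute_force_incorporation(codon, pool, model, geom):
    """Direct transcription of the incorporation probabilities.

    Computes, per species: Pb as explicit Boltzmann weights, Pfirst as a
    rate ratio, the not-first branch as Pb_i * prod_k (1-Pb_k)^(lam_k/lam_i),
    the total-probability combination, and the final renormalisation.
    Returns a dict species id -> normalised PI.
    """
    # arrival rates
    n = geom.volume / geom.trna_length**3
    tau = geom.trna_length**2 / (6.0 * geom.diffusion_coeff)
    lam = {t.id: (t.abundance / n) / tau for t in pool}
    total_rate = sum(lam.values())

    # effective affinities, aligning codon position k with anticodon 3-k-1
    weights = (model.s1, model.s2, 1.0)
    dA = {}
    for t in pool:
        s = 0.0
        for k in range(3):
            s += model.affinity(codon[k], t.anticodon[2 - k]) * weights[k]
        dA[t.id] = s

    z = sum(math.exp(-v) for v in dA.values())
    pb = {tid: math.exp(-v) / z for tid, v in dA.items()}

    pi = {}
    for t in pool:
        p_first = lam[t.id] / total_rate
        not_first = pb[t.id]
        for other in pool:
            if other.id == t.id:
                continue
            not_first *= (1.0 - pb[other.id]) ** (lam[other.id] / lam[t.id])
        pi[t.id] = pb[t.id] * p_first + not_first * (1.0 - p_first)
    z_pi = sum(pi.values())
    return {tid: v / z_pi for tid, v in pi.items()}


def multinomial_logpmf_factorial(counts, probs):
    """Multinomial log-pmf via explicit factorials (counts must be small)."""
    n = sum(counts)
    log_coeff = math.log(math.factorial(n))
    for c in counts:
        log_coeff -= math.log(math.factorial(c))
    log_p = 0.0
    for c, p in zip(counts, probs):
        if c > 0:
            log_p += c * math.log(p)
    return log_coeff + log_p


def mc_race_probability(rates, focal_index, n_draws, seed):
    """P(focal arrives first) from simulated exponential waiting times."""
    rng = np.random.default_rng(seed)
    rates = np.asarray(rates, dtype=float)
    times = rng.exponential(1.0 / rates, size=(n_draws, len(rates)))
    wins = (times.argmin(axis=1) == focal_index).mean()
    se = math.sqrt(wins * (1 - wins) / n_draws)
    return wins, se


def mc_error_free_fraction(p_correct_per_site, n_reps, seed):
    """Fraction of simulated translations with zero errors, plus its SE."""
    rng = np.random.default_rng(seed)
    p = np.asarray(p_correct_per_site, dtype=float)
    draws = rng.uniform(size=(n_reps, len(p))) < p  # True = correct site
    error_free = draws.all(axis=1).mean()
    se = math.sqrt(max(error_free * (1 - error_free), 1e-12) / n_reps)
    return error_free, se
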