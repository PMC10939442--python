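"""Seeded generators that make every pipeline stage testable offline.

The generators emulate the study conditions the real analyses run under:
RNA-seq-like tRNA pools covering all amino acids, a Watson-Crick-favoring
affinity truth, multinomial misincorporation counts drawn from the
forward model, open-search PSM tables with injected substitutions and
decoys for every filter, random proteomes with heavy-tailed abundances,
and DFE-like variant-effect score tables (a point mass near zero plus a
deleterious tail).  All randomness flows through one seeded generator per
call; the same seed reproduces every output bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .arrival import ECOLI, CellGeometry
from .binding import AffinityModel, _AC_IDX, _C_IDX
from .etel_detection import PSMRecord, SubstitutionCall, load_ptm_list
from .fitness import FitnessScores, ProteomeEntry
from .genetic_code import (
    AMINO_ACIDS,
    CODON_ALPHABET,
    SENSE_CODONS,
    TRNASpecies,
    WC_PAIRS,
    cognate_anticodon,
    merge_il,
    substitution_mass_delta,
    translate,
)
from .incorporation import ErrorLandscape, build_landscape
from .inference import (
    CodonObservation,
    MCMCConfig,
    fit_mcmc,
    posterior_summary,
)


@dataclass
class SyntheticTruth:
    """Ground truth behind a synthetic study: model, pool and landscape."""

    seed: int
    model: AffinityModel
    pool: List[TRNASpecies]
    geom: CellGeometry
    landscape: ErrorLandscape
    dfe_params: Optional[Dict[str, float]] = None
    injected_substitutions: List[SubstitutionCall] = field(default_factory=list)


def _covering_anticodons(lysidine: bool) -> List[Tuple[str, str]]:
    """A decoding repertoire reading every sense codon by WC or wobble.

    Mirrors how real pools are organised: within each codon box, an
    anticodon starting with G reads the C-ending codon (WC) and the
    U-ending codon (G:U wobble); one starting with U reads the A-ending
    codon (WC) and the G-ending codon; single-codon boxes get their exact
    anticodon, and AUA gets the lysidine-modified LAU when enabled.
    """
    groups: Dict[Tuple[str, str], List[str]] = {}
    for codon in SENSE_CODONS:
        groups.setdefault((codon[:2], translate(codon)), []).append(codon[2])
    out = []
    for (prefix, aa), endings in sorted(groups.items()):
        if "C" in endings:
            out.append((cognate_anticodon(prefix + "C"), aa))
        elif "U" in endings:
            out.append((cognate_anticodon(prefix + "U"), aa))
        if "A" in endings:
            if prefix + "A" == "AUA" and lysidine:
                out.append(("LAU", aa))  # lysidine wobble slot reads AUA only
            else:
                out.append((cognate_anticodon(prefix + "A"), aa))
        elif "G" in endings:
            out.append((cognate_anticodon(prefix + "G"), aa))
    return out


def gen_trna_pool(
    seed: int,
    n_species: int = 42,
    abundance_range: Tuple[float, float] = (1e3, 1e5),
    lysidine: bool = True,
) -> List[TRNASpecies]:
    """Draw a tRNA pool covering all 20 amino acids.

    A wobble-aware covering repertoire (every sense codon readable by a
    synonymous anticodon through WC or G:U/lysidine pairing) is included
    first — 32 species; requesting fewer falls back to covering amino
    acids only.  Additional species up to ``n_species`` are WC anticodons
    of further codons, drawn without replacement.  Abundances are
    log-uniform over ``abundance_range`` (molecules/cell).
    """
    if n_species < len(AMINO_ACIDS):
        raise ValueError(
            f"need at least {len(AMINO_ACIDS)} species to cover all amino acids"
        )
    if n_species > len(SENSE_CODONS):
        raise ValueError(f"at most {len(SENSE_CODONS)} distinct anticodons exist")
    rng = np.random.default_rng(seed)
    covering = _covering_anticodons(lysidine)
    if n_species >= len(covering):
        chosen = list(covering)
    else:
        by_aa: Dict[str, Tuple[str, str]] = {}
        for anticodon, aa in covering:
            by_aa.setdefault(aa, (anticodon, aa))
        chosen = sorted(by_aa.values())
        rest = [x for x in covering if x not in chosen]
        idx = rng.choice(len(rest), size=n_species - len(chosen), replace=False)
        chosen.extend(rest[i] for i in sorted(idx))
    taken = {ac for ac, _ in chosen}
    extras = [
        (cognate_anticodon(c), translate(c))
        for c in SENSE_CODONS
        if cognate_anticodon(c) not in taken
    ]
    n_extra = n_species - len(chosen)
    if n_extra > 0:
        idx = rng.choice(len(extras), size=min(n_extra, len(extras)), replace=False)
        chosen.extend(extras[i] for i in sorted(idx))

    lo, hi = abundance_range
    pool = []
    for anticodon, aa in sorted(chosen):
        abundance = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        pool.append(
            TRNASpecies(
                id=f"tRNA-{aa}-{anticodon}",
                anticodon=anticodon,
                amino_acid=aa,
                abundance=abundance,
            )
        )
    return pool


#: wobble-capable (codon, anticodon) pairs get intermediate affinity
_WOBBLE_PAIRS = frozenset({("U", "G"), ("G", "U")})


def gen_true_model(seed: int, wc_strength: float = 4.0) -> AffinityModel:
    """A Watson-Crick-favoring affinity truth, gauge-anchored.

    WC pairs sit ``wc_strength`` below the mismatch entries (drawn in
    [0.5, 2.5]); wobble-capable G:U pairs sit halfway, so synonymous
    wobble decoding stays strongly preferred over near-cognate binding, as
    it must be for realistically small error rates.  The lysidine column
    interacts mildly favorably with every codon nucleotide.  The matrix is
    returned in the canonical gauge (column-U entry of each row at zero);
    WC entries are strictly below all plain-mismatch entries *within each
    row* by construction.
    """
    if wc_strength <= 0:
        raise ValueError("wc_strength must be positive")
    rng = np.random.default_rng(seed)
    a = np.empty((4, 5))
    for c in CODON_ALPHABET:
        for ac in "ACGUL":
            if (c, ac) in WC_PAIRS:
                val = -wc_strength + rng.uniform(-0.4, 0.4)
            elif (c, ac) in _WOBBLE_PAIRS:
                val = -wc_strength / 2.0 + rng.uniform(-0.3, 0.3)
            elif ac == "L":
                val = rng.uniform(-0.5, 1.0)
            else:
                val = rng.uniform(0.5, 2.5)
            a[_C_IDX[c], _AC_IDX[ac]] = val
    s1, s2 = rng.uniform(0.5, 3.0, size=2)
    return AffinityModel(a, float(s1), float(s2)).gauge_fixed()


def make_truth(
    seed: int,
    n_species: int = 42,
    geom: CellGeometry = ECOLI,
    wc_strength: float = 2.0,
    lysidine: bool = True,
) -> SyntheticTruth:
    """Bundle a pool, a true model and its forward landscape."""
    pool = gen_trna_pool(seed, n_species=n_species, lysidine=lysidine)
    model = gen_true_model(seed + 1, wc_strength=wc_strength)
    landscape = build_landscape(pool, model, geom)
    return SyntheticTruth(seed=seed, model=model, pool=pool, geom=geom, landscape=landscape)


def simulate_observations(
    truth: SyntheticTruth, depth_per_codon: int, seed: int
) -> List[CodonObservation]:
    """One multinomial draw of size ``depth_per_codon`` per sense codon."""
    if depth_per_codon < 1:
        raise ValueError("depth must be at least 1")
    rng = np.random.default_rng(seed)
    cats = truth.landscape.categories
    out = []
    for i, codon in enumerate(truth.landscape.codons):
        counts = rng.multinomial(depth_per_codon, truth.landscape.probs[i])
        own = merge_il(translate(codon))
        errors = {
            cats[j]: int(n)
            for j, n in enumerate(counts)
            if n > 0 and cats[j] != own
        }
        out.append(
            CodonObservation(
                codon=codon, total_count=depth_per_codon, error_counts=errors
            )
        )
    return out


def gen_proteome(
    seed: int,
    n_proteins: int = 30,
    length_range: Tuple[int, int] = (80, 300),
) -> List[ProteomeEntry]:
    """Random sense-codon proteins with heavy-tailed proteome fractions."""
    if n_proteins < 1:
        raise ValueError("need at least one protein")
    rng = np.random.default_rng(seed)
    raw = rng.lognormal(mean=0.0, sigma=1.5, size=n_proteins)
    phis = raw / raw.sum()
    entries = []
    for i in range(n_proteins):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        codons = tuple(
            SENSE_CODONS[j] for j in rng.integers(len(SENSE_CODONS), size=length)
        )
        entries.append(
            ProteomeEntry(protein_id=f"P{i:04d}", codons=codons, phi=float(phis[i]))
        )
    return entries


@dataclass
class PSMFixture:
    """A synthetic open-search PSM table plus its recoverable ground truth."""

    dataset_id: str
    psms: List[PSMRecord]
    truth_calls: List[SubstitutionCall]


def _jitter(rng: np.random.Generator, sd: float = 0.001, cap: float = 0.004) -> float:
    # truncated so injected classes never leak across the +/-5 mDa band
    return float(np.clip(rng.normal(scale=sd), -cap, cap))


def _window(rng, length: int, pos: int) -> Tuple[int, int]:
    """A peptide window (1-based start, end) of length 8-14 covering pos."""
    size = int(rng.integers(8, 15))
    size = min(size, length)
    lo = max(1, pos - size + 1)
    hi = min(pos, length - size + 1)
    start = int(rng.integers(lo, hi + 1)) if hi >= lo else 1
    return start, start + size - 1

def gen_psm_fixture(
    truth: SyntheticTruth,
    proteome: Sequence[ProteomeEntry],
    n_psms: int = 400,
    seed: int = 0,
    dataset_id: str = "synthetic-ds",
) -> PSMFixture:
    """Build a PSM table exercising every calling filter.

    Roughly 10% of PSMs carry true substitutions (each backed by an
    unmodified PSM covering the same position), 5% PTM decoys whose shift
    also matches a substitution, 3% multi-protein decoys, 3% unlocalized
    shifts, 2% isotope-label-like shifts, and the rest unmodified PSMs
    with sub-5-mDa mass jitter.  Injected substitutions avoid destinations
    whose delta collides (within 12 mDa) with a shipped PTM mass for the
    original residue, so every injected call is recoverable; the returned
    ``truth_calls`` aggregate them per site.
    """
    if not proteome:
        raise ValueError("proteome must be non-empty")
    rng = np.random.default_rng(seed)
    ptms = load_ptm_list()
    ptm_by_res: Dict[str, List[float]] = {}
    for res, shift, _ in ptms:
        ptm_by_res.setdefault(res, []).append(shift)

    n_sub = max(1, n_psms // 10)
    n_ptm = max(1, n_psms // 20)
    n_multi = max(1, int(0.03 * n_psms))
    n_unloc = max(1, int(0.03 * n_psms))
    n_label = max(1, int(0.02 * n_psms))

    seqs = {e.protein_id: e.sequence for e in proteome}
    ids = [e.protein_id for e in proteome]
    lengths = {e.protein_id: len(e.codons) for e in proteome}
    codon_map = {e.protein_id: e.codons for e in proteome}

    def random_site() -> Tuple[str, int]:
        pid = ids[rng.integers(len(ids))]
        return pid, int(rng.integers(1, lengths[pid] + 1))

    def clean_dest(orig: str) -> Optional[str]:
        options = []
        for dest in AMINO_ACIDS:
            if merge_il(dest) == merge_il(orig):
                continue
            delta = substitution_mass_delta(orig, dest)
            if abs(delta) < 0.012:
                continue  # would straddle the unmodified band
            if any(abs(delta - p) < 0.012 for p in ptm_by_res.get(orig, ())):
                continue  # indistinguishable from a known PTM
            options.append(dest)
        if not options:
            return None
        return options[rng.integers(len(options))]

    psms: List[PSMRecord] = []
    tally: Dict[Tuple[str, str, int, str], int] = {}
    meta: Dict[Tuple[str, str, int, str], Tuple[str, str]] = {}

    made = 0
    while made < n_sub:
        pid, pos = random_site()
        orig = seqs[pid][pos - 1]
        dest = clean_dest(orig)
        if dest is None:
            continue
        start, end = _window(rng, lengths[pid], pos)
        peptide = seqs[pid][start - 1 : end]
        delta = substitution_mass_delta(orig, dest)
        psms.append(
            PSMRecord(
                dataset_id=dataset_id,
                peptide=peptide,
                protein_id=pid,
                protein_start=start,
                mass_shift=delta + _jitter(rng),
                localized_position=pos - start + 1,
            )
        )
        # guarantee unmodified coverage of the same position
        psms.append(
            PSMRecord(
                dataset_id=dataset_id,
                peptide=peptide,
                protein_id=pid,
                protein_start=start,
                mass_shift=_jitter(rng),
            )
        )
        key = (dataset_id, pid, pos, merge_il(dest))
        tally[key] = tally.get(key, 0) + 1
        meta[key] = (codon_map[pid][pos - 1], orig)
        made += 1

    # PTM decoys: shifts that also match a substitution from that residue,
    # so they pass the mass-match step and must be caught by the PTM filter
    ptm_decoy_menu = [("N", 14.01565), ("N", 0.98402), ("D", 14.01565)]
    made = 0
    attempts = 0
    while made < n_ptm and attempts < 50 * n_ptm:
        attempts += 1
        res, shift = ptm_decoy_menu[rng.integers(len(ptm_decoy_menu))]
        pid, pos = random_site()
        if seqs[pid][pos - 1] != res:
            continue
        start, end = _window(rng, lengths[pid], pos)
        peptide = seqs[pid][start - 1 : end]
        psms.append(
            PSMRecord(dataset_id, peptide, pid, start, shift + _jitter(rng), pos - start + 1)
        )
        psms.append(PSMRecord(dataset_id, peptide, pid, start, _jitter(rng)))
        made += 1

    for _ in range(n_multi):
        pid, pos = random_site()
        other = ids[rng.integers(len(ids))]
        orig = seqs[pid][pos - 1]
        dest = clean_dest(orig)
        if dest is None:
            continue
        start, end = _window(rng, lengths[pid], pos)
        peptide = seqs[pid][start - 1 : end]
        psms.append(
            PSMRecord(
                dataset_id,
                peptide,
                f"{pid};{other}",
                start,
                substitution_mass_delta(orig, dest) + _jitter(rng),
                pos - start + 1,
            )
        )

    for _ in range(n_unloc):
        pid, pos = random_site()
        orig = seqs[pid][pos - 1]
        dest = clean_dest(orig)
        if dest is None:
            continue
        start, end = _window(rng, lengths[pid], pos)
        peptide = seqs[pid][start - 1 : end]
        psms.append(
            PSMRecord(
                dataset_id,
                peptide,
                pid,
                start,
                substitution_mass_delta(orig, dest) + _jitter(rng),
                localized_position=None,
                ambiguous_localization=True,
            )
        )
        psms.append(PSMRecord(dataset_id, peptide, pid, start, _jitter(rng)))

    for _ in range(n_label):
        pid, pos = random_site()
        start, end = _window(rng, lengths[pid], pos)
        peptide = seqs[pid][start - 1 : end]
        psms.append(
            PSMRecord(dataset_id, peptide, pid, start, 8.01420 + _jitter(rng), pos - start + 1)
        )

    while len(psms) < n_psms:
        pid, pos = random_site()
        start, end = _window(rng, lengths[pid], pos)
        peptide = seqs[pid][start - 1 : end]
        psms.append(PSMRecord(dataset_id, peptide, pid, start, _jitter(rng)))

    truth_calls = [
        SubstitutionCall(ds, pid, pos, meta[(ds, pid, pos, dest)][0],
                         meta[(ds, pid, pos, dest)][1], dest, n)
        for (ds, pid, pos, dest), n in sorted(tally.items())
    ]
    return PSMFixture(dataset_id=dataset_id, psms=psms, truth_calls=truth_calls)


def parameter_recovery(
    seed: int,
    depth_per_codon: int = 10_000,
    config: Optional[MCMCConfig] = None,
    lysidine: bool = False,
    ci_level: float = 0.95,
) -> Dict[str, object]:
    """Simulate counts from a known truth, refit, and score the recovery.

    Returns the truth, the chain, the Pearson correlation between true and
    posterior-mean gauge-fixed affinities, and the fraction of true values
    inside the central credible intervals.  The default configuration is
    lysidine-free: the lysidine column's pairings with pyrimidine-ending
    codons only reshuffle probability *within* the merged I/L category and
    are therefore structurally unidentifiable from misincorporation counts.
    """
    truth = make_truth(seed, lysidine=lysidine)
    obs = simulate_observations(truth, depth_per_codon, seed + 100)
    cfg = config or MCMCConfig(steps=2000, burnin=1000, thin=2)
    chain = fit_mcmc(obs, truth.pool, truth.geom, config=cfg, seed=seed)
    summary = posterior_summary(chain, level=ci_level)
    names = chain.parameter_names
    true_values = np.array(
        [
            truth.model.s1
            if n == "s1"
            else truth.model.s2
            if n == "s2"
            else truth.model.affinity(n[2], n[5])
            for n in names
        ]
    )
    is_affinity = np.array([n.startswith("a") for n in names])
    est = summary["mean"].to_numpy()
    r = float(np.corrcoef(true_values[is_affinity], est[is_affinity])[0, 1])
    inside = (summary["ci_low"].to_numpy() <= true_values) & (
        true_values <= summary["ci_high"].to_numpy()
    )
    return {
        "truth": truth,
        "chain": chain,
        "summary": summary,
        "parameter_names": names,
        "true_values": true_values,
        "is_affinity": is_affinity,
        "pearson_r": r,
        "ci_coverage": float(inside[is_affinity].mean()),
    }


def gen_fitness_scores(
    proteome: Sequence[ProteomeEntry],
    seed: int,
    w_neutral: float = 0.7,
    neutral_sd: float = 0.05,
    deleterious_scale: float = 2.0,
) -> FitnessScores:
    """DFE-like dE tables: mass near zero plus an exponential deleterious tail.

    For every site and every non-encoded amino acid, dE is N(0, neutral_sd)
    with probability ``w_neutral`` and -Exp(deleterious_scale) otherwise;
    the encoded residue scores exactly 0.
    """
    if not 0 <= w_neutral <= 1:
        raise ValueError("w_neutral must be a probability")
    rng = np.random.default_rng(seed)
    scores = FitnessScores()
    for entry in proteome:
        for pos, codon in enumerate(entry.codons, start=1):
            own = translate(codon)
            for aa in AMINO_ACIDS:
                if aa == own:
                    scores.set(entry.protein_id, pos, aa, 0.0)
                elif rng.uniform() < w_neutral:
                    scores.set(
                        entry.protein_id, pos, aa, float(rng.normal(scale=neutral_sd))
                    )
                else:
                    scores.set(
                        entry.protein_id,
                        pos,
                        aa,
                        float(-rng.exponential(deleterious_scale)),
                    )
    scores_params = {
        "w_neutral": w_neutral,
        "neutral_sd": neutral_sd,
        "deleterious_scale": deleterious_scale,
    }
    scores.params = scores_params  # type: ignore[attr-defined]
    return scores
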