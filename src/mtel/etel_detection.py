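"""Empirical substitution calling from open-search PSM tables (eTEL).

Open database searches report, per peptide-spectrum match (PSM), the mass
difference between the observed precursor and the theoretical peptide.
Shifts within +/-5 mDa of zero are unmodified; larger shifts are either
post-translational modifications, artefacts, or — when the shift equals
the residue-mass difference between the encoded amino acid and another —
candidate amino-acid misincorporations.

The calling pipeline applies, in order:

1. drop peptides matched to several proteins;
2. split PSMs into unmodified / modified at the +/-5 mDa band;
3. retain a modified PSM only if its protein position is covered by an
   unmodified PSM from the same dataset (and raw file, when known);
4. require an unambiguously localized modification site;
5. match the shift to a substitution mass delta from the encoded residue;
6. discard calls whose shift and localized residue also match a known PTM.

Every dropped PSM is attributed to exactly one filter.  Leucine and
isoleucine are merged.  Error detection rates divide substitution
observations by total (modified or unmodified) codon observations at the
PSM level.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .genetic_code import (
    AMINO_ACIDS,
    merge_il,
    substitution_mass_delta,
    translate,
)

#: half-width of the unmodified band and of all mass matching, in Da
MASS_TOL = 0.005

#: mass shifts indicative of isotopic labeling (SILAC-style), in Da
LABEL_SHIFTS = (4.02511, 6.02013, 8.01420, 10.00827)


@dataclass(frozen=True)
class PSMRecord:
    """One peptide-spectrum match from an open-search results table."""

    dataset_id: str
    peptide: str
    protein_id: str  # semicolon-separated when matched to several proteins
    protein_start: int  # 1-based position of the peptide in the protein
    mass_shift: float  # observed - theoretical, Da
    localized_position: Optional[int] = None  # 1-based within the peptide
    ambiguous_localization: bool = False
    raw_file: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.peptide or any(ch not in AMINO_ACIDS for ch in self.peptide):
            raise ValueError(f"invalid peptide sequence {self.peptide!r}")
        if self.protein_start < 1:
            raise ValueError("protein_start must be 1-based and positive")


@dataclass(frozen=True)
class SubstitutionCall:
    dataset_id: str
    protein_id: str
    position: int  # 1-based in the protein
    codon: str
    original_aa: str
    dest_aa: str  # I/L merged label where ambiguous
    psm_count: int = 1


@dataclass
class FilterStats:
    """Per-filter drop accounting; each dropped PSM is counted once."""

    n_input: int = 0
    multi_protein: int = 0
    unmodified: int = 0
    missing_protein: int = 0
    no_unmodified_coverage: int = 0
    unlocalized: int = 0
    no_substitution_match: int = 0
    ptm_collision: int = 0
    n_calls: int = 0

    def dropped(self) -> int:
        return (
            self.multi_protein
            + self.unmodified
            + self.missing_protein
            + self.no_unmodified_coverage
            + self.unlocalized
            + self.no_substitution_match
            + self.ptm_collision
        )


def classify_mass_shift(shift: float, tol: float = MASS_TOL) -> str:
    """'unmodified' if |shift| is within the tolerance band, else 'modified'."""
    if not math.isfinite(shift):
        raise ValueError("mass shift must be finite")
    return "unmodified" if abs(shift) <= tol else "modified"


def load_ptm_list(path=None) -> List[Tuple[str, float, str]]:
    """(residue, shift Da, name) triples; packaged Unimod-common defaults.

    The shipped list covers frequent artefact/PTM masses; reproducing a
    specific study exactly requires supplying its own exclusion list.
    """
    if path is None:
        text = resources.files("mtel").joinpath("data/ptm_list.tsv").read_text()
        lines = text.splitlines()
    else:
        with open(path) as fh:
            lines = fh.read().splitlines()
    out = []
    for line in lines[1:]:
        if not line.strip():
            continue
        residue, shift, name = line.split("\t")
        out.append((residue, float(shift), name))
    return out


def _substitution_targets(orig: str, shift: float, tol: float) -> List[str]:
    """Destination amino acids whose residue-mass delta matches the shift."""
    hits = [
        dest
        for dest in AMINO_ACIDS
        if merge_il(dest) != merge_il(orig)
        and abs(shift - substitution_mass_delta(orig, dest)) <= tol
    ]
    return sorted({merge_il(d) for d in hits})


def call_substitutions(
    psms: Sequence[PSMRecord],
    protein_db: Mapping[str, str],
    cds_map: Mapping[str, Sequence[str]],
    ptm_masses: Optional[Sequence[Tuple[str, float, str]]] = None,
    tol: float = MASS_TOL,
) -> Tuple[List[SubstitutionCall], FilterStats]:
    """Run the full filter pipeline and emit substitution calls.

    ``protein_db`` maps protein id -> amino-acid sequence and ``cds_map``
    maps protein id -> codon list (RNA alphabet), one codon per residue.
    PSMs referencing proteins absent from ``protein_db`` are skipped with
    a logged count; a protein/CDS length mismatch is a hard error.
    """
    if ptm_masses is None:
        ptm_masses = load_ptm_list()
    for pid, codons in cds_map.items():
        if pid in protein_db and len(codons) != len(protein_db[pid]):
            raise ValueError(f"protein {pid}: CDS and sequence lengths differ")

    stats = FilterStats(n_input=len(psms))

    # unmodified coverage per (dataset, raw file, protein) -> residue positions
    coverage: Dict[Tuple[str, Optional[str], str], set] = defaultdict(set)
    survivors: List[PSMRecord] = []
    for psm in psms:
        if ";" in psm.protein_id:
            stats.multi_protein += 1
            continue
        if psm.protein_id not in protein_db:
            stats.missing_protein += 1
            continue
        if classify_mass_shift(psm.mass_shift, tol) == "unmodified":
            stats.unmodified += 1
            span = range(psm.protein_start, psm.protein_start + len(psm.peptide))
            coverage[(psm.dataset_id, psm.raw_file, psm.protein_id)].update(span)
            continue
        survivors.append(psm)

    ptm_by_residue: Dict[str, List[float]] = defaultdict(list)
    for residue, shift, _name in ptm_masses:
        ptm_by_residue[residue].append(shift)

    tally: Counter = Counter()
    call_codon: Dict[Tuple[str, str, int, str], Tuple[str, str]] = {}
    for psm in survivors:
        if psm.localized_position is None or psm.ambiguous_localization:
            stats.unlocalized += 1
            continue
        pos = psm.protein_start + psm.localized_position - 1
        key = (psm.dataset_id, psm.raw_file, psm.protein_id)
        covered = pos in coverage[key] or (
            psm.raw_file is not None
            and pos in coverage[(psm.dataset_id, None, psm.protein_id)]
        )
        if not covered:
            stats.no_unmodified_coverage += 1
            continue
        orig = psm.peptide[psm.localized_position - 1]
        dests = _substitution_targets(orig, psm.mass_shift, tol)
        if not dests:
            stats.no_substitution_match += 1
            continue
        if any(
            abs(psm.mass_shift - ptm) <= tol for ptm in ptm_by_residue.get(orig, ())
        ):
            stats.ptm_collision += 1
            continue
        if len(dests) > 1:
            warnings.warn(
                f"shift {psm.mass_shift:+.5f} at {orig} matches several "
                f"destinations {dests}; keeping the closest",
                stacklevel=2,
            )
            dests.sort(
                key=lambda d: min(
                    abs(psm.mass_shift - substitution_mass_delta(orig, x))
                    for x in ("I", "L")
                    if merge_il(x) == d
                )
                if d == "I/L"
                else abs(psm.mass_shift - substitution_mass_delta(orig, d))
            )
        dest = dests[0]
        codons = cds_map.get(psm.protein_id)
        if codons is None:
            stats.missing_protein += 1
            continue
        codon = codons[pos - 1]
        if translate(codon) != orig:
            raise ValueError(
                f"protein {psm.protein_id} position {pos}: codon {codon} "
                f"does not encode observed residue {orig}"
            )
        tally[(psm.dataset_id, psm.protein_id, pos, dest)] += 1
        call_codon[(psm.dataset_id, psm.protein_id, pos, dest)] = (codon, orig)

    calls = [
        SubstitutionCall(ds, pid, pos, call_codon[(ds, pid, pos, dest)][0],
                         call_codon[(ds, pid, pos, dest)][1], dest, n)
        for (ds, pid, pos, dest), n in sorted(tally.items())
    ]
    stats.n_calls = len(calls)
    return calls, stats


def curate_datasets(
    calls_by_dataset: Mapping[str, Sequence[SubstitutionCall]],
    shifts_by_dataset: Mapping[str, Sequence[float]],
    min_substitutions: int = 10,
    label_shifts: Sequence[float] = LABEL_SHIFTS,
    max_label_fraction: float = 0.10,
    tol: float = MASS_TOL,
) -> List[str]:
    """Dataset ids passing the curation rules.

    A dataset is retained iff it has at least ``min_substitutions``
    detected substitutions (counting supporting PSMs) and at most
    ``max_label_fraction`` of its detected misincorporation mass shifts
    look like isotopic labeling.
    """
    retained = []
    for ds, calls in calls_by_dataset.items():
        n_subs = sum(c.psm_count for c in calls)
        if n_subs < min_substitutions:
            continue
        shifts = list(shifts_by_dataset.get(ds, ()))
        if shifts:
            label_like = sum(
                1
                for s in shifts
                if any(abs(abs(s) - ref) <= tol for ref in label_shifts)
            )
            if label_like > max_label_fraction * len(shifts):
                continue
        retained.append(ds)
    return retained


def psm_codon_coverage(
    psms: Sequence[PSMRecord],
    protein_db: Mapping[str, str],
    cds_map: Mapping[str, Sequence[str]],
) -> Tuple[Counter, Counter]:
    """PSM-level observation totals per codon and per protein.

    Every position of every single-protein PSM (modified or unmodified)
    whose protein is known counts one observation of that position's codon.
    """
    codon_totals: Counter = Counter()
    protein_totals: Counter = Counter()
    for psm in psms:
        if ";" in psm.protein_id or psm.protein_id not in cds_map:
            continue
        codons = cds_map[psm.protein_id]
        for pos in range(psm.protein_start, psm.protein_start + len(psm.peptide)):
            if pos <= len(codons):
                codon_totals[codons[pos - 1]] += 1
        protein_totals[psm.protein_id] += 1
    return codon_totals, protein_totals


def error_detection_rates(
    calls: Sequence[SubstitutionCall],
    coverage_counts: Mapping[str, int],
) -> Dict[str, Optional[float]]:
    """Per-codon error detection rate: substitution PSMs / total PSMs.

    Codons never observed get ``None`` (missing, not zero).
    """
    errors: Counter = Counter()
    for call in calls:
        errors[call.codon] += call.psm_count
    rates: Dict[str, Optional[float]] = {}
    for codon in set(coverage_counts) | set(errors):
        total = coverage_counts.get(codon, 0)
        rates[codon] = errors[codon] / total if total > 0 else None
    return rates


def protein_error_detection_rates(
    calls: Sequence[SubstitutionCall],
    protein_totals: Mapping[str, int],
) -> Dict[str, Optional[float]]:
    """Per-protein analogue: erroneous / total peptides of the protein."""
    errors: Counter = Counter()
    for call in calls:
        errors[call.protein_id] += call.psm_count
    out: Dict[str, Optional[float]] = {}
    for pid in set(protein_totals) | set(errors):
        total = protein_totals.get(pid, 0)
        out[pid] = errors[pid] / total if total > 0 else None
    return out


def substitution_count_matrix(
    calls: Sequence[SubstitutionCall],
):
    """Codon x destination-category PSM count matrix (landscape layout)."""
    import pandas as pd

    from .genetic_code import AA_CATEGORIES, SENSE_CODONS

    mat = pd.DataFrame(
        0, index=list(SENSE_CODONS), columns=list(AA_CATEGORIES), dtype=int
    )
    for call in calls:
        mat.loc[call.codon, call.dest_aa] += call.psm_count
    return mat


def rscu(
    cds_sequences: Iterable[Sequence[str]],
    expression_weights: Optional[Sequence[float]] = None,
    top_fraction: float = 0.05,
    stop_policy: str = "warn",
) -> Dict[str, float]:
    """Relative synonymous codon usage over a set of coding sequences.

    RSCU of a codon is its count divided by the mean count of its synonym
    family; single-codon families score 1 whenever observed.  When
    ``expression_weights`` are supplied, only the top ``top_fraction`` of
    sequences by weight contribute (codon usage of highly expressed genes).
    Internal stop codons are counted after an optional warning.
    """
    seqs = [list(s) for s in cds_sequences]
    if expression_weights is not None:
        if len(expression_weights) != len(seqs):
            raise ValueError("one expression weight per sequence required")
        order = sorted(
            range(len(seqs)), key=lambda i: expression_weights[i], reverse=True
        )
        keep = max(1, int(math.ceil(top_fraction * len(seqs))))
        seqs = [seqs[i] for i in order[:keep]]

    counts: Counter = Counter()
    for codons in seqs:
        for i, codon in enumerate(codons):
            try:
                translate(codon)
            except Exception:
                # stop codons have no synonym family; an internal one is
                # suspicious but does not affect sense-codon RSCU
                if i < len(codons) - 1 and stop_policy == "warn":
                    warnings.warn(f"internal stop codon {codon}", stacklevel=2)
                continue
            counts[codon] += 1

    families: Dict[str, List[str]] = defaultdict(list)
    from .genetic_code import GENETIC_CODE

    for codon, aa in GENETIC_CODE.items():
        families[aa].append(codon)

    out: Dict[str, float] = {}
    for aa, codons in families.items():
        family_total = sum(counts[c] for c in codons)
        if family_total == 0:
            continue
        expected = family_total / len(codons)
        for c in codons:
            out[c] = counts[c] / expected
    return out
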