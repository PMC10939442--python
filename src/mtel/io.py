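"""Readers and writers for the tab-separated formats the pipeline speaks.

All tabular formats are plain TSV with a header row; sequences use FASTA.
The PSM reader is tolerant of Philosopher-style ``psm.tsv`` column names
("Peptide", "Protein", "Protein Start", "Delta Mass", "MSFragger
Localization") as well as the minimal lowercase set documented here
(peptide, protein, protein_start, mass_shift, localized_position).
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
from Bio import SeqIO

from .etel_detection import PSMRecord
from .fitness import FitnessScores, ProteomeEntry
from .genetic_code import TRNASpecies
from .inference import CodonObservation


def read_trna_pool(path) -> List[TRNASpecies]:
    """tRNA pool TSV: columns id, anticodon, amino_acid, abundance (U alphabet)."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "anticodon": str})
    required = {"id", "anticodon", "amino_acid", "abundance"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"tRNA pool table is missing columns {sorted(missing)}")
    return [
        TRNASpecies(
            id=row.id,
            anticodon=row.anticodon,
            amino_acid=row.amino_acid,
            abundance=float(row.abundance),
        )
        for row in df.itertuples()
    ]


def write_trna_pool(pool: Sequence[TRNASpecies], path) -> None:
    pd.DataFrame(
        {
            "id": [t.id for t in pool],
            "anticodon": [t.anticodon for t in pool],
            "amino_acid": [t.amino_acid for t in pool],
            "abundance": [t.abundance for t in pool],
        }
    ).to_csv(path, sep="\t", index=False)


def read_observations(path) -> List[CodonObservation]:
    """Long-format observations TSV: codon, total_count, dest_aa, error_count.

    One row per (codon, destination); rows with an empty destination carry
    the codon's total only.
    """
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out: Dict[str, CodonObservation] = {}
    totals: Dict[str, int] = {}
    errors: Dict[str, Dict[str, int]] = {}
    for row in df.itertuples():
        totals[row.codon] = int(row.total_count)
        dest = str(getattr(row, "dest_aa", "") or "")
        if dest:
            errors.setdefault(row.codon, {})[dest] = int(row.error_count)
    for codon, total in totals.items():
        out[codon] = CodonObservation(codon, total, errors.get(codon, {}))
    return list(out.values())


def write_observations(observations: Sequence[CodonObservation], path) -> None:
    rows = []
    for obs in observations:
        if not obs.error_counts:
            rows.append((obs.codon, obs.total_count, "", 0))
        for dest, n in sorted(obs.error_counts.items()):
            rows.append((obs.codon, obs.total_count, dest, n))
    pd.DataFrame(
        rows, columns=["codon", "total_count", "dest_aa", "error_count"]
    ).to_csv(path, sep="\t", index=False)


def pool_observations(
    *observation_sets: Sequence[CodonObservation],
) -> List[CodonObservation]:
    """Sum counts across datasets codon-wise before fitting."""
    totals: Dict[str, int] = {}
    errors: Dict[str, Dict[str, int]] = {}
    for obs_set in observation_sets:
        for obs in obs_set:
            totals[obs.codon] = totals.get(obs.codon, 0) + obs.total_count
            for dest, n in obs.error_counts.items():
                errs = errors.setdefault(obs.codon, {})
                errs[dest] = errs.get(dest, 0) + n
    return [
        CodonObservation(codon, totals[codon], errors.get(codon, {}))
        for codon in sorted(totals)
    ]


_PSM_COLUMN_ALIASES = {
    "peptide": ["peptide", "Peptide"],
    "protein": ["protein", "Protein"],
    "protein_start": ["protein_start", "Protein Start"],
    "mass_shift": ["mass_shift", "delta_mass", "Delta Mass", "Original Delta Mass"],
    "localization": [
        "localized_position",
        "localization",
        "MSFragger Localization",
    ],
    "dataset": ["dataset_id", "dataset"],
    "raw_file": ["raw_file", "Spectrum File", "spectrum_file"],
}


def _find_column(df: pd.DataFrame, key: str) -> Optional[str]:
    for name in _PSM_COLUMN_ALIASES[key]:
        if name in df.columns:
            return name
    return None


def _parse_localization(value, peptide: str) -> Tuple[Optional[int], bool]:
    """Position within the peptide, plus an ambiguity flag.

    Accepts an integer position or an MSFragger-style localization string
    (the peptide with candidate sites in lowercase); several lowercase
    sites mean the localization is ambiguous.
    """
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None, False
    if isinstance(value, (int, float)):
        return int(value), False
    text = str(value).strip()
    if not text:
        return None, False
    if text.isdigit():
        return int(text), False
    lowers = [i for i, ch in enumerate(text) if ch.islower()]
    if len(lowers) == 1:
        return lowers[0] + 1, False
    if len(lowers) > 1:
        return lowers[0] + 1, True
    return None, False


def read_psm_table(path, dataset_id: Optional[str] = None) -> List[PSMRecord]:
    """Read a PSM TSV, mapping Philosopher-style column names if present."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    cols = {key: _find_column(df, key) for key in _PSM_COLUMN_ALIASES}
    for required in ("peptide", "protein", "protein_start", "mass_shift"):
        if cols[required] is None:
            raise ValueError(f"PSM table lacks a recognisable {required} column")
    records = []
    for row_d in df.to_dict(orient="records"):
        get = lambda key: row_d.get(cols[key]) if cols[key] else None  # noqa: E731
        peptide = str(get("peptide"))
        loc, ambiguous = _parse_localization(get("localization"), peptide)
        ds = dataset_id or (str(get("dataset")) if cols["dataset"] else "unknown")
        raw = get("raw_file")
        records.append(
            PSMRecord(
                dataset_id=ds,
                peptide=peptide,
                protein_id=str(get("protein")),
                protein_start=int(get("protein_start")),
                mass_shift=float(get("mass_shift")),
                localized_position=loc,
                ambiguous_localization=ambiguous,
                raw_file=str(raw) if raw not in (None, "") else None,
            )
        )
    return records


def read_fasta(path) -> Dict[str, str]:
    """FASTA -> {id: sequence} (protein or RNA/DNA as given)."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def cds_to_codons(sequence: str) -> List[str]:
    """Split a CDS into RNA codons, accepting DNA input; trailing stop dropped."""
    rna = sequence.upper().replace("T", "U")
    if len(rna) % 3 != 0:
        raise ValueError("CDS length is not divisible by 3")
    codons = [rna[i : i + 3] for i in range(0, len(rna), 3)]
    if codons and codons[-1] in ("UAA", "UAG", "UGA"):
        codons = codons[:-1]
    return codons


def read_fitness_scores(path) -> FitnessScores:
    """Score TSV: protein_id, site (1-based), amino_acid, deltaE."""
    df = pd.read_csv(path, sep="\t")
    scores = FitnessScores()
    for row in df.itertuples():
        scores.set(str(row.protein_id), int(row.site), str(row.amino_acid), float(row.deltaE))
    return scores


def write_fitness_scores(scores: FitnessScores, path) -> None:
    rows = [
        (pid, site, aa, val)
        for pid, sites in sorted(scores.scores.items())
        for site, table in sorted(sites.items())
        for aa, val in sorted(table.items())
    ]
    pd.DataFrame(rows, columns=["protein_id", "site", "amino_acid", "deltaE"]).to_csv(
        path, sep="\t", index=False
    )


def read_abundances(path) -> Dict[str, float]:
    """Abundance TSV: protein_id, phi."""
    df = pd.read_csv(path, sep="\t")
    return {str(r.protein_id): float(r.phi) for r in df.itertuples()}


def write_proteome(entries: Sequence[ProteomeEntry], fasta_path, abundance_path) -> None:
    """Write codon sequences as a CDS FASTA plus a phi table."""
    with open(fasta_path, "w") as fh:
        for e in entries:
            fh.write(f">{e.protein_id}\n{''.join(e.codons)}\n")
    pd.DataFrame(
        {"protein_id": [e.protein_id for e in entries], "phi": [e.phi for e in entries]}
    ).to_csv(abundance_path, sep="\t", index=False)


def read_proteome(fasta_path, abundance_path) -> List[ProteomeEntry]:
    seqs = read_fasta(fasta_path)
    phis = read_abundances(abundance_path)
    return [
        ProteomeEntry(pid, tuple(cds_to_codons(seq)), phis.get(pid, 0.0))
        for pid, seq in seqs.items()
    ]


def write_chain(chain, path) -> None:
    """Posterior chain as JSON-lines, one affinity model per line."""
    with open(path, "w") as fh:
        for model in chain.samples:
            fh.write(model.to_json() + "\n")
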