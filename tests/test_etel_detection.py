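import numpy as np
import pytest

from mtel.etel_detection import (
    PSMRecord,
    SubstitutionCall,
    call_substitutions,
    classify_mass_shift,
    curate_datasets,
    error_detection_rates,
    protein_error_detection_rates,
    psm_codon_coverage,
    rscu,
)
from mtel.genetic_code import substitution_mass_delta


@pytest.fixture
def tiny_proteome():
    # one protein: Met-Gly-Lys-Asn-Ser-Thr-Asp-Phe
    cds = ("AUG", "GGU", "AAA", "AAU", "UCU", "ACU", "GAU", "UUU")
    protein = "MGKNSTDF"
    return {"P1": protein}, {"P1": list(cds)}


def _psm(peptide, start, shift, loc=None, protein="P1", dataset="ds1", **kw):
    return PSMRecord(
        dataset_id=dataset,
        peptide=peptide,
        protein_id=protein,
        protein_start=start,
        mass_shift=shift,
        localized_position=loc,
        **kw,
    )


class TestClassifyMassShift:
    @pytest.mark.parametrize(
        "shift, expected",
        [
            (0.004, "unmodified"),
            (-0.0051, "modified"),
            (14.0157, "modified"),
            (0.005, "unmodified"),
            (-0.005, "unmodified"),
        ],
    )
    def test_band(self, shift, expected):
        assert classify_mass_shift(shift) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_mass_shift(float("nan"))


class TestCallSubstitutions:
    def test_clean_gly_to_ala_call(self, tiny_proteome):
        db, cds = tiny_proteome
        psms = [
            _psm("MGKN", 1, 0.0),  # unmodified coverage
            _psm("MGKN", 1, substitution_mass_delta("G", "A") + 0.001, loc=2),
        ]
        calls, stats = call_substitutions(psms, db, cds)
        assert len(calls) == 1
        call = calls[0]
        assert (call.original_aa, call.dest_aa) == ("G", "A")
        assert call.position == 2 and call.codon == "GGU"
        assert stats.n_calls == 1 and stats.unmodified == 1

    def test_ptm_collision_suppresses_call(self, tiny_proteome):
        # +14.01565 at Asn matches both N->Q and N-methylation: no call
        db, cds = tiny_proteome
        psms = [
            _psm("KNST", 3, 0.0),
            _psm("KNST", 3, 14.01565, loc=2),
        ]
        calls, stats = call_substitutions(psms, db, cds)
        assert calls == []
        assert stats.ptm_collision == 1

    def test_multi_protein_peptide_dropped(self, tiny_proteome):
        db, cds = tiny_proteome
        psms = [
            _psm("MGKN", 1, 0.0),
            _psm("MGKN", 1, 14.01565, loc=2, protein="P1;P2"),
        ]
        calls, stats = call_substitutions(psms, db, cds)
        assert calls == []
        assert stats.multi_protein == 1

    def test_requires_unmodified_coverage(self, tiny_proteome):
        db, cds = tiny_proteome
        psms = [_psm("MGKN", 1, substitution_mass_delta("G", "A"), loc=2)]
        calls, stats = call_substitutions(psms, db, cds)
        assert calls == []
        assert stats.no_unmodified_coverage == 1

    def test_requires_unambiguous_localization(self, tiny_proteome):
        db, cds = tiny_proteome
        psms = [
            _psm("MGKN", 1, 0.0),
            _psm("MGKN", 1, 14.01565, loc=2, ambiguous_localization=True),
            _psm("MGKN", 1, 14.01565, loc=None),
        ]
        calls, stats = call_substitutions(psms, db, cds)
        assert calls == []
        assert stats.unlocalized == 2

    def test_unmatched_shift_dropped(self, tiny_proteome):
        db, cds = tiny_proteome
        psms = [
            _psm("MGKN", 1, 0.0),
            _psm("MGKN", 1, 5.5555, loc=2),
        ]
        calls, stats = call_substitutions(psms, db, cds)
        assert calls == []
        assert stats.no_substitution_match == 1

    def test_missing_protein_skipped_and_counted(self, tiny_proteome):
        db, cds = tiny_proteome
        psms = [_psm("MGKN", 1, 0.0, protein="UNKNOWN")]
        calls, stats = call_substitutions(psms, db, cds)
        assert stats.missing_protein == 1

    def test_length_mismatch_is_hard_error(self):
        with pytest.raises(ValueError, match="lengths differ"):
            call_substitutions([], {"P1": "MG"}, {"P1": ["AUG"]})

    def test_drop_accounting_is_exhaustive(self, tiny_proteome):
        db, cds = tiny_proteome
        psms = [
            _psm("MGKN", 1, 0.0),
            _psm("MGKN", 1, substitution_mass_delta("G", "A"), loc=2),
            _psm("MGKN", 1, 14.01565, loc=2, protein="P1;P2"),
            _psm("KNST", 3, 14.01565, loc=2),
            _psm("MGKN", 1, 5.5555, loc=2),
            _psm("STDF", 5, substitution_mass_delta("T", "S"), loc=2),  # no coverage
            _psm("MGKN", 1, 14.01565, loc=None),
        ]
        calls, stats = call_substitutions(psms, db, cds)
        assert stats.n_input == len(psms)
        assert stats.dropped() + stats.n_calls == len(psms) - 0
        assert stats.dropped() == len(psms) - 1  # one clean call survives


class TestCuration:
    def _calls(self, n, dataset="ds"):
        return [
            SubstitutionCall(dataset, "P1", i + 1, "GGU", "G", "A", 1)
            for i in range(n)
        ]

    def test_too_few_substitutions_dropped(self):
        retained = curate_datasets({"ds": self._calls(9)}, {"ds": [14.0] * 9})
        assert retained == []

    def test_label_enrichment_dropped(self):
        shifts = [14.01565] * 89 + [8.0142] * 11
        retained = curate_datasets({"ds": self._calls(100)}, {"ds": shifts})
        assert retained == []

    def test_boundary_retained(self):
        retained = curate_datasets({"ds": self._calls(10)}, {"ds": [14.01565] * 10})
        assert retained == ["ds"]

    def test_exactly_ten_percent_labels_retained(self):
        shifts = [14.01565] * 90 + [8.0142] * 10
        retained = curate_datasets({"ds": self._calls(100)}, {"ds": shifts})
        assert retained == ["ds"]


class TestRates:
    def test_simple_ratio(self):
        calls = [SubstitutionCall("ds", "P1", 2, "GGU", "G", "A", 3)]
        rates = error_detection_rates(calls, {"GGU": 1000})
        assert rates["GGU"] == pytest.approx(0.003)

    def test_zero_errors(self):
        rates = error_detection_rates([], {"GGU": 50})
        assert rates["GGU"] == 0.0

    def test_unobserved_codon_is_missing_not_zero(self):
        calls = [SubstitutionCall("ds", "P1", 2, "GGU", "G", "A", 1)]
        rates = error_detection_rates(calls, {})
        assert rates["GGU"] is None

    def test_aggregation_associativity(self):
        calls_a = [SubstitutionCall("a", "P1", 2, "GGU", "G", "A", 2)]
        calls_b = [SubstitutionCall("b", "P1", 2, "GGU", "G", "S", 1)]
        combined = error_detection_rates(calls_a + calls_b, {"GGU": 300})
        split_sum = (2 + 1) / (100 + 200)
        assert combined["GGU"] == pytest.approx(split_sum)

    def test_coverage_counting(self, tiny_proteome):
        db, cds = tiny_proteome
        psms = [_psm("MGKN", 1, 0.0), _psm("GKNS", 2, 14.01565, loc=1)]
        codon_totals, protein_totals = psm_codon_coverage(psms, db, cds)
        assert codon_totals["GGU"] == 2  # covered by both peptides
        assert codon_totals["AUG"] == 1
        assert protein_totals["P1"] == 2

    def test_protein_rates(self):
        calls = [SubstitutionCall("ds", "P1", 2, "GGU", "G", "A", 1)]
        rates = protein_error_detection_rates(calls, {"P1": 10, "P2": 5})
        assert rates["P1"] == pytest.approx(0.1)
        assert rates["P2"] == 0.0


class TestRSCU:
    def test_two_codon_family_75_25(self):
        seqs = [["UUU"] * 75 + ["UUC"] * 25]
        values = rscu(seqs)
        assert values["UUU"] == pytest.approx(1.5)
        assert values["UUC"] == pytest.approx(0.5)

    def test_uniform_usage_all_one(self):
        from mtel.genetic_code import SENSE_CODONS

        values = rscu([list(SENSE_CODONS)])
        assert all(v == pytest.approx(1.0) for v in values.values())

    def test_single_codon_families(self):
        values = rscu([["AUG", "UGG", "AUG"]])
        assert values["AUG"] == 1.0
        assert values["UGG"] == 1.0

    def test_top_fraction_by_expression(self):
        seqs = [["UUU"] * 10, ["UUC"] * 10] + [["AUG"]] * 18
        weights = [100.0, 1.0] + [1.0] * 18
        values = rscu(seqs, expression_weights=weights, top_fraction=0.05)
        # only the top-expressed sequence (all UUU) contributes
        assert values["UUU"] == pytest.approx(2.0)
        assert values["UUC"] == pytest.approx(0.0)

    def test_internal_stop_warns(self):
        with pytest.warns(UserWarning, match="internal stop"):
            rscu([["UUU", "UAA", "UUC"]])


class TestPSMReader:
    def test_philosopher_columns(self, tmp_path):
        path = tmp_path / "psm.tsv"
        path.write_text(
            "Peptide\tProtein\tProtein Start\tDelta Mass\tMSFragger Localization\n"
            "MGKN\tP1\t1\t14.01565\tMgKN\n"
            "MGKN\tP1\t1\t0.00100\t\n"
        )
        from mtel.io import read_psm_table

        records = read_psm_table(path, dataset_id="ds1")
        assert records[0].localized_position == 2
        assert not records[0].ambiguous_localization
        assert records[1].localized_position is None
        assert records[0].mass_shift == pytest.approx(14.01565)

    def test_ambiguous_localization_flagged(self, tmp_path):
        path = tmp_path / "psm.tsv"
        path.write_text(
            "peptide\tprotein\tprotein_start\tmass_shift\tlocalization\n"
            "MGKN\tP1\t1\t14.01565\tmGkN\n"
        )
        from mtel.io import read_psm_table

        records = read_psm_table(path)
        assert records[0].ambiguous_localization
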