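import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mtel.fitness import (
    POPGEN_PRESETS,
    PopGenParams,
    ProteomeEntry,
    classify_effect,
    classify_sites,
    fixation_ratio,
    organismal_burden,
    protein_burden,
    protein_site_costs,
    site_cost,
    synonymous_cost_comparison,
)
from mtel.genetic_code import AMINO_ACIDS, translate
from mtel.incorporation import ErrorLandscape, build_landscape
from mtel.synthetic_data import gen_fitness_scores, gen_proteome, make_truth


@pytest.fixture(scope="module")
def truth():
    return make_truth(12)


@pytest.fixture(scope="module")
def unmerged_landscape(truth):
    return build_landscape(truth.pool, truth.model, truth.geom, merge=False)


class TestSiteCost:
    def test_zero_error_probability_zero_cost(self):
        landscape = ErrorLandscape(("AAA",), ("K", "N"), np.array([[1.0, 0.0]]))
        scores = {aa: -5.0 for aa in AMINO_ACIDS}
        assert site_cost("AAA", scores, landscape) == 0.0

    def test_single_term(self):
        landscape = ErrorLandscape(("AAA",), ("K", "A"), np.array([[0.99, 0.01]]))
        scores = {"A": -2.0}
        assert site_cost("AAA", scores, landscape) == pytest.approx(-0.02)

    def test_matches_direct_summation_over_20_amino_acids(self, unmerged_landscape):
        rng = np.random.default_rng(8)
        scores = {aa: float(rng.normal()) for aa in AMINO_ACIDS}
        codon = "GCU"
        scores[translate(codon)] = 0.0
        expected = sum(
            unmerged_landscape.p_category(codon, aa) * scores[aa]
            for aa in AMINO_ACIDS
            if aa != translate(codon)
        )
        assert site_cost(codon, scores, unmerged_landscape) == pytest.approx(
            expected, abs=1e-12
        )

    def test_missing_score_error_vs_renormalize(self, unmerged_landscape):
        scores = {"A": -1.0}  # every other destination unscored
        with pytest.raises(KeyError):
            site_cost("AAA", scores, unmerged_landscape, missing="error")
        value = site_cost("AAA", scores, unmerged_landscape, missing="renormalize")
        assert np.isfinite(value)

    def test_merged_landscape_uses_mean_il_score(self, truth):
        scores = {aa: 0.0 for aa in AMINO_ACIDS}
        scores["I"] = -2.0
        scores["L"] = -4.0
        cost = site_cost("AAA", scores, truth.landscape)
        p_il = truth.landscape.p_category("AAA", "I/L")
        assert cost == pytest.approx(p_il * -3.0)


class TestProteinBurden:
    def test_zero_abundance_zero_burden(self):
        entry = ProteomeEntry("P", ("AAA", "GCU"), 0.0)
        assert protein_burden(entry, [-1.0, -2.0]) == 0.0

    def test_linearity_in_phi(self):
        e1 = ProteomeEntry("P", ("AAA",), 0.1)
        e2 = ProteomeEntry("P", ("AAA",), 0.2)
        costs = [-0.5]
        assert protein_burden(e2, costs) == pytest.approx(2 * protein_burden(e1, costs))

    def test_organismal_burden_flat_sum(self, truth, unmerged_landscape):
        proteome = gen_proteome(5, n_proteins=4, length_range=(10, 20))
        scores = gen_fitness_scores(proteome, 6)
        total = organismal_burden(proteome, scores, unmerged_landscape)
        flat = sum(
            e.phi * c
            for e in proteome
            for c in protein_site_costs(e, scores, unmerged_landscape)
        )
        assert total == pytest.approx(flat, abs=1e-12)


class TestFixationRatio:
    def test_neutral_limit(self):
        assert fixation_ratio(0.0, POPGEN_PRESETS["ecoli"]) == 1.0

    def test_closed_form_at_s_half(self):
        # S = -0.5 directly: Theta = -1 / (1 - e)
        pg = PopGenParams(ne=1.0, q=0.5)
        theta = fixation_ratio(-1.0, pg)
        assert theta == pytest.approx(-1.0 / (1.0 - math.e), abs=1e-9)
        assert theta == pytest.approx(0.5820, abs=1e-4)

    def test_continuous_near_zero(self):
        pg = PopGenParams(ne=1.0, q=1.0)
        for dx in (1e-12, -1e-12, 1e-9, -1e-9):
            assert fixation_ratio(dx, pg) == pytest.approx(1.0 + dx, abs=1e-12)

    def test_extreme_negative_underflows_to_zero(self):
        pg = POPGEN_PRESETS["ecoli"]
        assert fixation_ratio(-1e6, pg) == 0.0

    def test_strictly_increasing(self):
        pg = PopGenParams(ne=100.0, q=0.01)
        xs = np.linspace(-3, 3, 101)
        thetas = [fixation_ratio(x, pg) for x in xs]
        assert all(b > a for a, b in zip(thetas, thetas[1:]))

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            fixation_ratio(float("inf"), POPGEN_PRESETS["ecoli"])


class TestClassifyEffect:
    @pytest.mark.parametrize(
        "theta, expected",
        [
            (0.96, "neutral"),
            (0.94, "deleterious"),
            (1.06, "advantageous"),
            (0.95, "neutral"),
            (1.05, "neutral"),
            (0.0, "deleterious"),
        ],
    )
    def test_band(self, theta, expected):
        assert classify_effect(theta) == expected

    @settings(derandomize=True)
    @given(st.floats(min_value=0.0, max_value=10.0, allow_nan=False))
    def test_partition_is_exhaustive_and_exclusive(self, theta):
        label = classify_effect(theta)
        assert label in {"neutral", "deleterious", "advantageous"}
        if label == "neutral":
            assert abs(theta - 1.0) <= 0.05
        elif label == "deleterious":
            assert theta < 0.95
        else:
            assert theta > 1.05

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_effect(-0.1)

    def test_classify_sites_weighted(self):
        pg = PopGenParams(ne=1.0, q=1.0)
        fractions = classify_sites([0.0, -100.0], pg, weights=[3.0, 1.0])
        assert fractions["neutral"] == pytest.approx(0.75)
        assert fractions["deleterious"] == pytest.approx(0.25)


class TestSynonymousComparison:
    def test_identical_distributions_high_p(self):
        rng = np.random.default_rng(0)
        costs = rng.normal(size=200)
        df = synonymous_cost_comparison({"UUU": costs, "UUC": costs.copy()})
        assert len(df) == 1
        assert df["pvalue"].iloc[0] > 0.9
        assert df["median_a"].iloc[0] == df["median_b"].iloc[0]

    def test_detects_one_sd_shift(self):
        rng = np.random.default_rng(1)
        a = rng.normal(loc=0.0, size=500)
        b = rng.normal(loc=1.0, size=500)
        df = synonymous_cost_comparison({"UUU": a, "UUC": b})
        assert df["pvalue"].iloc[0] < 0.01

    def test_single_codon_families_excluded(self):
        rng = np.random.default_rng(2)
        df = synonymous_cost_comparison(
            {"AUG": rng.normal(size=10), "UUU": rng.normal(size=10), "UUC": rng.normal(size=10)}
        )
        assert set(df["amino_acid"]) == {"F"}

    def test_rscu_annotation(self):
        rng = np.random.default_rng(3)
        df = synonymous_cost_comparison(
            {"UUU": rng.normal(size=20), "UUC": rng.normal(size=20)},
            rscu={"UUU": 1.5, "UUC": 0.5},
        )
        row = df.iloc[0]
        preferred = {row["codon_a"]: row["preferred_a"], row["codon_b"]: row["preferred_b"]}
        assert preferred == {"UUU": True, "UUC": False}

    def test_empty_distribution_rejected(self):
        with pytest.raises(ValueError):
            synonymous_cost_comparison({"UUU": [], "UUC": [1.0]})


class TestPresets:
    def test_popgen_constants(self):
        assert POPGEN_PRESETS["ecoli"].ne == 1e8
        assert POPGEN_PRESETS["yeast"].ne == 8.6e6
        assert POPGEN_PRESETS["ecoli"].q == pytest.approx(4.19e-7)

    def test_validation(self):
        with pytest.raises(ValueError):
            PopGenParams(ne=0.5)
        with pytest.raises(ValueError):
            PopGenParams(ne=10.0, q=-1.0)
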