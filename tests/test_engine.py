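"""Statistic tests: PAF, CAI, bands, adjustment, aggregation, distances."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from caindex import (
    AdjustmentSpec,
    ConcordanceVector,
    ParameterKind,
    SimilarityBand,
    WeightScheme,
    apply_variability_adjustment,
    cai,
    classify_cai,
    group_similarity,
    muscle_similarity,
    paf,
    pairwise_distance_matrix,
)
from caindex.engine import OverrideConflictError, SchemeMismatchError, round_half_up
from caindex.trait_matrix import CharacterMatrix

unit = st.floats(0.0, 1.0, allow_nan=False)


class TestPaf:
    @pytest.mark.parametrize(
        "rf, expected",
        [
            ((1, 1, 1, 1), 1.0),
            ((1, 1, 1, 0), 0.875),  # vascularization-only difference: 7/8
            ((1, 1, 0, 1), 0.75),  # insertion-only difference: 6/8
            ((0, 1, 1, 1), 0.625),  # innervation-only difference: 5/8
            ((0, 0, 0, 0), 0.0),
        ],
    )
    def test_weighted_average_of_rf(self, rf, expected, default_scheme):
        vec = ConcordanceVector.from_values(*rf)
        assert paf(vec, default_scheme) == pytest.approx(expected, abs=1e-12)

    def test_mismatched_parameter_sets_rejected(self):
        vec = ConcordanceVector.concordant()
        partial = WeightScheme(weights={ParameterKind.INNERVATION: 3.0})
        with pytest.raises(SchemeMismatchError):
            paf(vec, partial)

    @given(rf=st.tuples(unit, unit, unit, unit), scale=st.floats(0.1, 50.0))
    @settings(derandomize=True, max_examples=200)
    def test_invariant_to_common_weight_scaling(self, rf, scale):
        vec = ConcordanceVector.from_values(*rf)
        base = WeightScheme()
        scaled = WeightScheme(
            weights={k: w * scale for k, w in base.weights.items()}
        )
        assert paf(vec, scaled) == pytest.approx(paf(vec, base), abs=1e-12)


class TestCai:
    @pytest.mark.parametrize(
        "a, b, expected",
        [(1.0, 1.0, 0.0), (1.0, 0.875, 0.125), (1.0, 0.75, 0.25), (1.0, 0.0, 1.0)],
    )
    def test_absolute_paf_difference(self, a, b, expected):
        assert cai(a, b) == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_paf_rejected(self):
        with pytest.raises(ValueError):
            cai(1.2, 0.5)

    @given(a=unit, b=unit, c=unit)
    @settings(derandomize=True, max_examples=300)
    def test_pseudometric_properties(self, a, b, c):
        assert cai(a, b) == cai(b, a)
        assert cai(a, a) == 0.0
        assert cai(a, c) <= cai(a, b) + cai(b, c) + 1e-12

    def test_binary_vectors_give_exact_eighths(self, default_scheme):
        """Brute-force oracle: all 16 binary RF vectors span {0..8}/8 exactly."""
        weights = (3, 2, 2, 1)
        oracle = sorted(
            sum(w for w, bit in zip(weights, bits) if not bit) / 8
            for bits in itertools.product((0, 1), repeat=4)
        )
        engine = sorted(
            cai(1.0, paf(ConcordanceVector.from_values(*bits), default_scheme))
            for bits in itertools.product((0, 1), repeat=4)
        )
        assert engine == pytest.approx(oracle, abs=0)
        assert set(engine) == {k / 8 for k in range(9)}


class TestBands:
    @pytest.mark.parametrize(
        "value, band",
        [
            (0.0, SimilarityBand.HIGHLY_SIMILAR),
            (0.0625, SimilarityBand.SIMILAR),
            (0.125, SimilarityBand.SIMILAR),
            (0.20, SimilarityBand.SIMILAR),  # knot is upper-closed
            (0.250, SimilarityBand.SOMEWHAT_SIMILAR),
            (0.425, SimilarityBand.SOMEWHAT_SIMILAR),
            (0.650, SimilarityBand.SOMEWHAT_SIMILAR),
            (0.651, SimilarityBand.DISSIMILAR),
            (1.0, SimilarityBand.DISSIMILAR),
        ],
    )
    def test_band_boundaries(self, value, band):
        assert classify_cai(value) is band

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_cai(1.01)
        with pytest.raises(ValueError):
            classify_cai(-0.01)

    @given(a=unit, b=unit)
    @settings(derandomize=True, max_examples=200)
    def test_monotone_in_cai(self, a, b):
        lo, hi = sorted((a, b))
        assert classify_cai(lo) <= classify_cai(hi)


class TestVariabilityAdjustment:
    def test_stated_polymorphic_muscle_decreases(self):
        """10% off innervation/vascularization, 50% off origin/insertion."""
        adj = AdjustmentSpec(
            decreases={
                ParameterKind.INNERVATION: 0.1,
                ParameterKind.ORIGIN: 0.5,
                ParameterKind.INSERTION: 0.5,
                ParameterKind.VASCULARIZATION: 0.1,
            }
        )
        out = apply_variability_adjustment(ConcordanceVector.concordant(), adj)
        assert out.values() == pytest.approx((0.9, 0.5, 0.5, 0.9))

    @pytest.mark.parametrize("decrease, expected", [(0.0, 0.7), (1.0, 0.0)])
    def test_identity_and_annihilation(self, decrease, expected):
        vec = ConcordanceVector.from_values(0.7, 0.7, 0.7, 0.7)
        adj = AdjustmentSpec(decreases={k: decrease for k in ParameterKind})
        out = apply_variability_adjustment(vec, adj)
        assert out.values() == pytest.approx((expected,) * 4)

    def test_bad_decrease_rejected(self):
        with pytest.raises(ValueError):
            AdjustmentSpec(decreases={ParameterKind.ORIGIN: 1.5})


class TestMuscleAndGroupSimilarity:
    def test_fully_concordant_muscle(self, study_matrix):
        sim = muscle_similarity(study_matrix, "flexor carpi radialis", "Papio")
        assert sim.cai == 0.0
        assert sim.band is SimilarityBand.HIGHLY_SIMILAR
        assert not sim.from_override

    def test_absent_muscle_is_maximally_distant(self, study_matrix):
        sim = muscle_similarity(study_matrix, "flexor digitorum profundus", "Papio")
        assert sim.cai == 1.0
        assert sim.band is SimilarityBand.DISSIMILAR

    def test_override_cell_is_flagged(self, study_matrix):
        sim = muscle_similarity(study_matrix, "palmaris longus", "Homo")
        assert sim.cai == 0.425
        assert sim.from_override

    def test_unknown_labels_raise(self, study_matrix):
        with pytest.raises(KeyError):
            muscle_similarity(study_matrix, "gluteus maximus", "Homo")
        with pytest.raises(KeyError):
            muscle_similarity(study_matrix, "supinator", "Gorilla")

    def test_gcai_is_mean_of_members(self, study_matrix):
        g = group_similarity(study_matrix, "deep_flexor", "Papio")
        values = [v for _, v in g.member_cais]
        assert values == pytest.approx([0.0, 1.0, 0.25])
        assert g.gcai == pytest.approx(np.mean(values), abs=1e-12)
        assert min(values) <= g.gcai <= max(values)

    def test_gcai_invariant_to_member_order(self, study_matrix):
        g1 = group_similarity(study_matrix, "superficial_flexor", "Homo")
        shuffled = study_matrix.subset()
        shuffled.muscles = shuffled.muscles[::-1]
        g2 = group_similarity(shuffled, "superficial_flexor", "Homo")
        assert g2.gcai == pytest.approx(g1.gcai, abs=1e-12)
        assert sorted(g2.member_cais) == sorted(g1.member_cais)

    def test_empty_group_raises(self, study_matrix):
        with pytest.raises(ValueError, match="no muscles"):
            group_similarity(study_matrix, "intrinsic_hand", "Homo")


class TestPairwiseDistances:
    def _three_species(self):
        vectors = {
            "A": ConcordanceVector.concordant(),
            "B": ConcordanceVector.from_values(1, 1, 1, 0),  # PAF 0.875
            "C": ConcordanceVector.from_values(1, 1, 0, 1),  # PAF 0.75
        }
        return CharacterMatrix(
            species=["A", "B", "C"],
            reference="A",
            muscles=[("m", "g")],
            entries={(sp, "m"): v for sp, v in vectors.items()},
        )

    def test_all_pairs_from_paf_differences(self):
        d = pairwise_distance_matrix(self._three_species(), level="m")
        assert d.loc["A", "B"] == pytest.approx(0.125)
        assert d.loc["A", "C"] == pytest.approx(0.25)
        assert d.loc["B", "C"] == pytest.approx(0.125)
        assert np.allclose(d.to_numpy(), d.to_numpy().T)
        assert np.all(np.diag(d.to_numpy()) == 0)

    def test_identical_species_are_at_distance_zero(self, study_matrix):
        sub = study_matrix.subset(species=["Cebus", "Papio"])
        d = pairwise_distance_matrix(sub, level="superficial_flexor")
        assert d.loc["Cebus", "Papio"] == pytest.approx(0.0)

    def test_overrides_block_non_reference_pairs(self, study_matrix):
        with pytest.raises(OverrideConflictError):
            pairwise_distance_matrix(study_matrix, level="superficial_flexor")
        d = pairwise_distance_matrix(
            study_matrix, level="superficial_flexor", ignore_overrides=True
        )
        assert np.allclose(d.to_numpy(), d.to_numpy().T)

    def test_single_species_rejected(self, study_matrix):
        with pytest.raises(ValueError):
            pairwise_distance_matrix(study_matrix.subset(species=["Cebus"]))


class TestRounding:
    @pytest.mark.parametrize(
        "value, ndigits, expected",
        [
            (0.41666666, 3, 0.417),
            (0.02083333, 2, 0.02),
            (0.1254545, 3, 0.125),
            (0.0625, 3, 0.063),  # half rounds up, not to even
            (0.26, 2, 0.26),
        ],
    )
    def test_half_up_report_convention(self, value, ndigits, expected):
        assert round_half_up(value, ndigits) == expected
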