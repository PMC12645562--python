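"""Natural-abundance correction model and tracer statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lactrace.isotope import (
    DataError,
    IsotopologueVector,
    PairingError,
    ParameterError,
    build_correction_matrix,
    correct_mid,
    cycling_ratio,
    molecular_enrichment,
    normalized_enrichment,
    process_mid_table,
)


def vec(values, n=None, fraction=True, name="met"):
    values = np.asarray(values, dtype=float)
    return IsotopologueVector(name, n or values.size - 1, values, is_fraction=fraction)


class TestCorrectionMatrix:
    def test_identity_when_no_abundance_no_impurity(self):
        m = build_correction_matrix(2, p13=0.0, tracer_purity=1.0)
        np.testing.assert_allclose(m.matrix, np.eye(3))

    def test_unlabelled_column_is_binomial(self):
        m = build_correction_matrix(2, p13=0.011, tracer_purity=1.0)
        expected = [0.989 ** 2, 2 * 0.011 * 0.989, 0.011 ** 2]
        np.testing.assert_allclose(m.matrix[:, 0], expected, rtol=1e-12)

    def test_fully_labelled_column_has_no_room_for_natural_label(self):
        m = build_correction_matrix(3, p13=0.011, tracer_purity=1.0)
        np.testing.assert_allclose(m.matrix[:, 3], [0, 0, 0, 1], atol=1e-15)

    def test_lower_triangular_and_column_stochastic_at_full_purity(self):
        m = build_correction_matrix(5, p13=0.02, tracer_purity=1.0).matrix
        assert np.allclose(m, np.tril(m))
        np.testing.assert_allclose(m.sum(axis=0), 1.0)
        assert np.all(m >= 0)

    def test_impurity_moves_mass_below_the_label_count(self):
        m = build_correction_matrix(3, p13=0.0, tracer_purity=0.99).matrix
        # a fully labelled molecule can now appear at lower mass shifts
        assert m[2, 3] > 0
        np.testing.assert_allclose(m.sum(axis=0), 1.0)

    @pytest.mark.parametrize("bad", [0, -1, 2.5])
    def test_invalid_carbon_count_rejected(self, bad):
        with pytest.raises(ParameterError):
            build_correction_matrix(bad)

    def test_invalid_abundance_rejected(self):
        with pytest.raises(ParameterError):
            build_correction_matrix(3, p13=0.6)
        with pytest.raises(ParameterError):
            build_correction_matrix(3, tracer_purity=0.0)


class TestCorrectMid:
    def test_identity_model_returns_input(self):
        m = build_correction_matrix(2, p13=0.0, tracer_purity=1.0)
        out = correct_mid(vec([0.2, 0.3, 0.5], fraction=False), m)
        np.testing.assert_allclose(out.values, [0.2, 0.3, 0.5], atol=1e-12)

    def test_unlabelled_compound_corrects_to_pure_m0(self):
        m = build_correction_matrix(2, p13=0.011, tracer_purity=1.0)
        raw = vec([0.989 ** 2, 2 * 0.011 * 0.989, 0.011 ** 2], fraction=False)
        np.testing.assert_allclose(correct_mid(raw, m).values, [1, 0, 0], atol=1e-9)

    def test_recovers_half_labelled_lactate(self):
        m = build_correction_matrix(3, p13=0.011, tracer_purity=1.0)
        x = np.array([0.5, 0.0, 0.0, 0.5])
        raw = vec(m.forward(x), fraction=False)
        np.testing.assert_allclose(correct_mid(raw, m).values, x, atol=1e-8)

    def test_intensity_scale_is_irrelevant(self):
        m = build_correction_matrix(3)
        x = np.array([0.3, 0.2, 0.1, 0.4])
        a = correct_mid(vec(1e7 * m.forward(x), fraction=False), m)
        b = correct_mid(vec(m.forward(x), fraction=False), m)
        np.testing.assert_allclose(a.values, b.values, atol=1e-10)

    def test_all_zero_vector_rejected(self):
        m = build_correction_matrix(2)
        with pytest.raises(DataError):
            correct_mid(vec([0, 0, 0], fraction=False), m)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            correct_mid(vec([1, 0, 0], fraction=False), build_correction_matrix(3))

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        n=st.integers(2, 6),
        p13=st.floats(0.0, 0.05),
        purity=st.floats(0.95, 1.0),
        data=st.data(),
    )
    def test_round_trip_property(self, n, p13, purity, data):
        """forward then correct recovers any valid fraction vector."""
        raws = data.draw(
            st.lists(st.floats(0.0, 1.0), min_size=n + 1, max_size=n + 1).filter(
                lambda v: sum(v) > 1e-3
            )
        )
        x = np.asarray(raws) / np.sum(raws)
        m = build_correction_matrix(n, p13=p13, tracer_purity=purity)
        out = correct_mid(vec(m.forward(x), n=n, fraction=False), m)
        np.testing.assert_allclose(out.values, x, atol=1e-7)
        assert out.values.min() >= 0
        assert abs(out.values.sum() - 1) < 1e-9


class TestEnrichmentStatistics:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([0, 0, 0, 1], 1.0),
            ([1, 0, 0, 0], 0.0),
            ([0.2, 0.3, 0.1, 0.4], (0.3 + 0.2 + 1.2) / 3),
        ],
    )
    def test_molecular_enrichment(self, values, expected):
        assert molecular_enrichment(vec(values)) == pytest.approx(expected, abs=1e-9)

    def test_enrichment_requires_fractions(self):
        with pytest.raises(DataError):
            molecular_enrichment(vec([10, 0, 0, 0], fraction=False))

    def test_enrichment_is_linear_in_fractions(self, rng):
        a = rng.dirichlet(np.ones(4))
        b = rng.dirichlet(np.ones(4))
        lam = 0.3
        mixed = molecular_enrichment(vec(lam * a + (1 - lam) * b))
        parts = lam * molecular_enrichment(vec(a)) + (1 - lam) * molecular_enrichment(vec(b))
        assert mixed == pytest.approx(parts, abs=1e-12)

    def test_enrichment_invariant_under_correction_round_trip(self, rng):
        m = build_correction_matrix(4, p13=0.0111)
        x = rng.dirichlet(np.ones(5))
        direct = molecular_enrichment(vec(x))
        recovered = molecular_enrichment(correct_mid(vec(m.forward(x), fraction=False), m))
        assert recovered == pytest.approx(direct, abs=1e-9)

    @pytest.mark.parametrize(
        "e_met, e_lac, expected",
        [(0.05, 0.05, 1.0), (0.0, 0.14, 0.0), (0.02, 0.14, 0.02 / 0.14)],
    )
    def test_normalized_enrichment(self, e_met, e_lac, expected):
        assert normalized_enrichment(e_met, e_lac) == pytest.approx(expected, abs=1e-9)

    def test_zero_tracer_enrichment_is_undefined_not_zero(self):
        with pytest.raises(DataError):
            normalized_enrichment(0.05, 0.0)

    @pytest.mark.parametrize(
        "values, expected",
        [
            ([0.6, 0, 0, 0.4], 0.0),
            ([0.4, 0.1, 0.1, 0.4], 0.5),
            ([0.55, 0.15, 0.05, 0.25], 0.8),
        ],
    )
    def test_cycling_ratio(self, values, expected):
        assert cycling_ratio(vec(values)) == pytest.approx(expected, abs=1e-9)

    def test_cycling_ratio_zero_m3_flagged(self):
        with pytest.raises(DataError):
            cycling_ratio(vec([0.5, 0.3, 0.2, 0.0]))

    def test_cycling_ratio_needs_three_carbons(self):
        with pytest.raises(ParameterError):
            cycling_ratio(vec([0.5, 0.3, 0.1, 0.05, 0.05]))

    def test_cycling_ratio_increases_in_partial_labels(self):
        low = cycling_ratio(vec([0.6, 0.05, 0.05, 0.3]))
        high = cycling_ratio(vec([0.5, 0.1, 0.1, 0.3]))
        assert high > low


class TestTableProcessing:
    def test_pairing_error_when_lactate_row_missing(self, clean_cohort):
        mids, _ = clean_cohort
        dropped = mids[mids.metabolite != "lactate"]
        with pytest.raises(PairingError, match="lack a lactate row"):
            process_mid_table(dropped, p13=0.0, tracer_purity=1.0)

    def test_normalization_is_per_compartment(self, clean_cohort):
        mids, truth = clean_cohort
        enr = process_mid_table(mids, p13=0.0, tracer_purity=1.0)
        one = enr[(enr.sample_id == "4C_a1") & (enr.tissue == "iBAT")]
        lac_e = one[one.metabolite == "lactate"].molecular_enrichment.iloc[0]
        pyr = one[one.metabolite == "pyruvate"].iloc[0]
        assert pyr.normalized_ratio == pytest.approx(pyr.molecular_enrichment / lac_e, abs=1e-12)
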