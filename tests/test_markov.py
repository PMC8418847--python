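"""Markov engine: matrix construction, risk-ratio adjustment, cohort traces."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crccea.markov import (
    DEATH,
    PD,
    PF,
    RiskRatioPair,
    TransitionMatrix,
    ValidationError,
    add_background_mortality,
    apply_risk_ratios,
    build_matrix,
    default_horizon,
    microsimulate,
    run_cohort,
)

from .conftest import random_valid_matrix


def raw_rows(pf_pf, pf_pd, pf_d, pd_pd, pd_d):
    return {
        "progression_free_to_progression_free": pf_pf,
        "progression_free_to_progressive": pf_pd,
        "progression_free_to_death": pf_d,
        "progressive_to_progressive": pd_pd,
        "progressive_to_death": pd_d,
    }


class TestBuildMatrix:
    def test_proportional_normalization_of_published_row(self):
        # the published chemo row sums to 0.999; proportional rescaling
        # divides each entry by the row sum
        m = build_matrix(raw_rows(0.877, 0.116, 0.006, 0.963, 0.037))
        np.testing.assert_allclose(
            m.p[PF], np.array([0.877, 0.116, 0.006]) / 0.999, atol=1e-12
        )
        np.testing.assert_allclose(m.p[PF], [0.87788, 0.11612, 0.00601], atol=5e-6)
        assert m.p[PF].sum() == pytest.approx(1.0, abs=1e-15)

    def test_residual_to_death_policy(self):
        m = build_matrix(
            raw_rows(0.877, 0.116, 0.006, 0.963, 0.037), policy="residual_to_death"
        )
        assert m[PF, PF] == 0.877
        assert m[PF, PD] == 0.116
        assert m[PF, DEATH] == pytest.approx(0.007)

    def test_death_row_is_absorbing(self):
        m = build_matrix(raw_rows(0.9, 0.1, 0.0, 0.9, 0.1))
        np.testing.assert_array_equal(m.p[DEATH], [0.0, 0.0, 1.0])

    def test_row_sum_above_tolerance_rejected(self):
        with pytest.raises(ValidationError, match="progression_free"):
            build_matrix(raw_rows(0.5, 0.6, 0.2, 0.9, 0.1))

    def test_negative_probability_rejected_naming_row(self):
        with pytest.raises(ValidationError, match="progressive"):
            build_matrix(raw_rows(0.9, 0.1, 0.0, 1.01, -0.01))

    def test_backward_transition_structurally_zero(self):
        m = build_matrix(raw_rows(0.9, 0.05, 0.05, 0.95, 0.05))
        assert m[PD, PF] == 0.0


class TestRiskRatios:
    def test_hazard_transform_closed_form(self):
        # p' = 1 - (1-p)^rr for the progression transition
        base = build_matrix(raw_rows(0.878, 0.116, 0.006, 0.963, 0.037))
        adj = apply_risk_ratios(base, RiskRatioPair(rr_pfs=0.72, rr_os=1.0))
        assert adj[PF, PD] == pytest.approx(1 - (1 - base[PF, PD]) ** 0.72, abs=1e-12)
        assert adj[PF, PD] == pytest.approx(0.0849, abs=5e-4)

    def test_identity_at_unit_ratios(self):
        base = build_matrix(raw_rows(0.877, 0.116, 0.006, 0.963, 0.037))
        adj = apply_risk_ratios(base, RiskRatioPair(1.0, 1.0))
        np.testing.assert_allclose(adj.p, base.p, atol=1e-15)

    def test_zero_probability_stays_zero(self):
        base = build_matrix(raw_rows(0.9, 0.1, 0.0, 0.9, 0.1))
        adj = apply_risk_ratios(base, RiskRatioPair(0.5, 0.5))
        assert adj[PF, DEATH] == 0.0

    def test_os_ratio_applies_to_both_death_transitions(self):
        base = build_matrix(raw_rows(0.877, 0.116, 0.006, 0.963, 0.037))
        adj = apply_risk_ratios(base, RiskRatioPair(rr_pfs=1.0, rr_os=0.84))
        for row in (PF, PD):
            assert adj[row, DEATH] == pytest.approx(
                1 - (1 - base[row, DEATH]) ** 0.84, abs=1e-12
            )
            assert adj.p[row].sum() == pytest.approx(1.0, abs=1e-12)

    def test_direct_mode_multiplies_and_guards_support(self):
        base = build_matrix(raw_rows(0.877, 0.116, 0.006, 0.963, 0.037))
        adj = apply_risk_ratios(base, RiskRatioPair(0.5, 1.0), mode="direct")
        assert adj[PF, PD] == pytest.approx(base[PF, PD] * 0.5)
        big = build_matrix(raw_rows(0.05, 0.9, 0.05, 0.5, 0.5))
        with pytest.raises(ValidationError):
            apply_risk_ratios(big, RiskRatioPair(1.5, 1.0), mode="direct")

    @given(rr=st.floats(0.05, 0.999))
    @settings(max_examples=30, deadline=None)
    def test_rr_below_one_strictly_decreases_probabilities(self, rr):
        base = build_matrix(raw_rows(0.877, 0.116, 0.006, 0.963, 0.037))
        adj = apply_risk_ratios(base, RiskRatioPair(rr, rr))
        for i, j in ((PF, PD), (PF, DEATH), (PD, DEATH)):
            assert 0.0 < adj[i, j] < base[i, j]


class TestRunCohort:
    def test_identity_matrix_constant_trace(self):
        m = TransitionMatrix(np.eye(3))
        trace = run_cohort(m, 10, start=(0.4, 0.6, 0.0))
        np.testing.assert_allclose(trace.occupancy, np.tile([0.4, 0.6, 0.0], (11, 1)))

    def test_geometric_decay_closed_form(self):
        # two-state toy: PF -> death with probability 0.5 each cycle
        m = build_matrix(raw_rows(0.5, 0.0, 0.5, 0.0, 1.0))
        trace = run_cohort(m, 12)
        np.testing.assert_allclose(
            trace.occupancy[:, PF], 0.5 ** np.arange(13), atol=1e-15
        )

    def test_long_horizon_exhausts_cohort(self, chemo_secondary_matrix):
        trace = run_cohort(chemo_secondary_matrix, 300)
        assert trace.occupancy[-1, DEATH] > 0.99

    def test_trace_shape_and_start(self, chemo_secondary_matrix):
        trace = run_cohort(chemo_secondary_matrix, 25)
        assert trace.occupancy.shape == (26, 3)
        np.testing.assert_array_equal(trace.occupancy[0], [1.0, 0.0, 0.0])

    def test_invalid_start_rejected(self, chemo_secondary_matrix):
        with pytest.raises(ValidationError):
            run_cohort(chemo_secondary_matrix, 5, start=(0.5, 0.2, 0.2))

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None)
    def test_conservation_property(self, seed):
        """Every trace row sums to 1 within 1e-12 for any valid matrix."""
        rng = np.random.default_rng(seed)
        m = random_valid_matrix(rng)
        trace = run_cohort(m, 50)
        np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-12)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_death_occupancy_monotone(self, seed):
        rng = np.random.default_rng(seed)
        m = random_valid_matrix(rng)
        trace = run_cohort(m, 50)
        assert np.all(np.diff(trace.occupancy[:, DEATH]) >= -1e-15)


class TestDefaultHorizon:
    def test_age_bound(self, chemo_secondary_matrix):
        # 50 years of 2-month cycles is an upper bound of 300 cycles
        h = default_horizon(chemo_secondary_matrix, 50, 100, residual_alive_tol=1e-300)
        assert h == 300

    def test_one_year_bound(self, chemo_secondary_matrix):
        assert default_horizon(chemo_secondary_matrix, 99, 100, 1e-300) == 6

    def test_tolerance_stops_early(self, chemo_secondary_matrix):
        h = default_horizon(chemo_secondary_matrix, 50, 100, residual_alive_tol=0.5)
        assert 1 <= h < 50

    def test_degenerate_tolerance_clamped_to_one_cycle(self, chemo_secondary_matrix):
        assert default_horizon(chemo_secondary_matrix, 50, 100, 1.0) == 1

    def test_invalid_ages(self, chemo_secondary_matrix):
        with pytest.raises(ValidationError):
            default_horizon(chemo_secondary_matrix, 100, 50)


class TestBackgroundMortality:
    def test_zero_hazard_is_identity(self, chemo_secondary_matrix):
        m = add_background_mortality(chemo_secondary_matrix, 0.0)
        assert m is chemo_secondary_matrix

    def test_hazard_combines_as_competing_risk(self, chemo_secondary_matrix):
        h = 0.01
        m = add_background_mortality(chemo_secondary_matrix, h)
        base = chemo_secondary_matrix
        for row in (PF, PD):
            assert m[row, DEATH] == pytest.approx(
                1 - (1 - base[row, DEATH]) * (1 - h), abs=1e-12
            )
            assert m.p[row].sum() == pytest.approx(1.0, abs=1e-12)


class TestMicrosimulationOracle:
    def test_cohort_trace_matches_microsimulation(self, chemo_secondary_matrix):
        """The deterministic trace is the expectation of per-patient paths.

        Agreement within 3 Monte-Carlo standard errors at every checked
        cycle, with 100,000 simulated patients.
        """
        n = 100_000
        horizon = 60
        trace = run_cohort(chemo_secondary_matrix, horizon)
        emp = microsimulate(chemo_secondary_matrix, n, horizon, seed=20240917)
        for k in (1, 2, 5, 10, 20, 40, 60):
            p = trace.occupancy[k]
            se = np.sqrt(p * (1 - p) / n)
            np.testing.assert_array_less(
                np.abs(emp[k] - p), 3 * np.maximum(se, 1e-12) + 1e-12
            )
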