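"""Record discretization, transition estimation, KM survival, summaries."""

import numpy as np
import pandas as pd
import pytest

from crccea.markov import ValidationError
from crccea.rwd import (
    config_fragment,
    count_transitions,
    discretize,
    estimate_transitions,
    estimates_to_matrix,
    km_median,
    summarize_costs_utilities,
    survival_months,
)
from crccea.synthetic import worked_fixture


def make_records(rows):
    """rows: (patient_id, arm, obs_month, state[, death])"""
    out = []
    for r in rows:
        pid, arm, month, state = r[:4]
        death = r[4] if len(r) > 4 else (1 if state == "death" else 0)
        out.append(
            {
                "patient_id": pid,
                "arm": arm,
                "obs_month": month,
                "state": state,
                "direct_medical_idr": 1e6,
                "direct_nonmedical_idr": 1e5,
                "indirect_idr": 1e4,
                "eq5d_index": 0.8 if state == "progression_free" else 0.6,
                "death": death,
                "censored": 0,
            }
        )
    df = pd.DataFrame(out)
    df.loc[df["state"] == "death", ["direct_medical_idr", "direct_nonmedical_idr",
                                    "indirect_idr", "eq5d_index"]] = np.nan
    return df


class TestDiscretize:
    def test_locf_at_cycle_boundaries(self):
        # observations at months 0 (PF), 3 (PF), 5 (PD) -> PF, PF, PD
        rec = make_records(
            [
                ("a", "chemo", 0, "progression_free"),
                ("a", "chemo", 3, "progression_free"),
                ("a", "chemo", 5, "progressive"),
            ]
        )
        seq = discretize(rec)
        assert seq["state"].tolist() == [
            "progression_free",
            "progression_free",
            "progressive",
        ]
        assert seq["cycle"].tolist() == [0, 1, 2]

    def test_single_observation_yields_no_transitions(self):
        rec = make_records([("a", "chemo", 0, "progression_free")])
        seq = discretize(rec)
        assert len(seq) == 1
        assert count_transitions(seq).empty

    def test_death_recorded_at_containing_cycle_boundary(self):
        rec = make_records(
            [
                ("a", "chemo", 0, "progression_free"),
                ("a", "chemo", 1, "death"),
            ]
        )
        seq = discretize(rec)
        assert seq[seq["state"] == "death"]["cycle"].tolist() == [1]
        # the patient is progression-free at cycle 0, so the death is a
        # countable PF -> death transition
        counts = count_transitions(seq)
        assert counts.iloc[0][["from_state", "to_state"]].tolist() == [
            "progression_free",
            "death",
        ]

    def test_conflicting_observations_rejected_with_patient_id(self):
        rec = make_records(
            [
                ("bad", "chemo", 0, "progression_free"),
                ("bad", "chemo", 0, "progressive"),
            ]
        )
        with pytest.raises(ValidationError, match="bad"):
            discretize(rec)

    def test_observation_after_death_rejected(self):
        rec = make_records(
            [
                ("a", "chemo", 0, "progression_free"),
                ("a", "chemo", 2, "death"),
                ("a", "chemo", 4, "progressive", 0),
            ]
        )
        with pytest.raises(ValidationError, match="after death"):
            discretize(rec)

    def test_boundary_sampled_data_loses_no_transitions(self):
        """Records generated exactly at cycle boundaries are conserved."""
        states = ["progression_free"] * 3 + ["progressive"] * 2
        rec = make_records(
            [("a", "chemo", 2 * k, s) for k, s in enumerate(states)]
            + [("a", "chemo", 10, "death")]
        )
        seq = discretize(rec)
        assert len(seq) == 6
        assert count_transitions(seq)["count"].sum() == 5


class TestEstimateTransitions:
    def test_worked_fixture_hand_counts(self):
        """Golden check: hand-counted fixture estimates match exactly."""
        records, expected = worked_fixture()
        est = estimate_transitions(discretize(records))["chemo"]
        for key, exp in expected.items():
            got = est[key]
            assert got.point == pytest.approx(exp["point"], abs=1e-12), key
            assert got.alpha == exp["alpha"], key
            assert got.beta == exp["beta"], key

    def test_worked_fixture_is_bit_identical_across_calls(self):
        a, _ = worked_fixture()
        b, _ = worked_fixture()
        pd.testing.assert_frame_equal(a, b)

    def test_counting_rule_example(self):
        # 35 progression events in 96 at-risk PF cycles -> 0.3646, Beta(36, 62)
        rows = []
        for i in range(35):
            rows += [(f"p{i}", "chemo", 0, "progression_free"),
                     (f"p{i}", "chemo", 2, "progressive")]
        for i in range(35, 96):
            rows += [(f"p{i}", "chemo", 0, "progression_free"),
                     (f"p{i}", "chemo", 2, "progression_free")]
        est = estimate_transitions(discretize(make_records(rows)))["chemo"]
        e = est[("progression_free", "progressive")]
        assert e.point == pytest.approx(35 / 96)
        assert (e.alpha, e.beta) == (36, 62)

    def test_no_events_gives_zero_point_with_prior_mass(self):
        rows = []
        for i in range(50):
            rows += [(f"p{i}", "chemo", 0, "progressive"),
                     (f"p{i}", "chemo", 2, "progressive")]
        est = estimate_transitions(discretize(make_records(rows)))["chemo"]
        e = est[("progressive", "death")]
        assert e.point == 0.0 and e.alpha == 1 and e.beta == 51
        assert est[("progression_free", "progressive")] is None

    def test_all_events_boundary(self):
        rows = [("p0", "chemo", 0, "progressive"), ("p0", "chemo", 2, "death")]
        est = estimate_transitions(discretize(make_records(rows)))["chemo"]
        assert est[("progressive", "death")].point == 1.0

    def test_raw_count_prior(self):
        records, _ = worked_fixture()
        est = estimate_transitions(discretize(records), prior=(0.0, 0.0))["chemo"]
        e = est[("progression_free", "progressive")]
        assert (e.alpha, e.beta) == (4, 16)

    def test_credible_interval_contains_point(self):
        records, _ = worked_fixture()
        est = estimate_transitions(discretize(records))["chemo"]
        lo, hi = est[("progression_free", "progressive")].credible_interval()
        assert lo < 0.2 < hi

    def test_estimates_assemble_into_valid_matrix(self):
        records, _ = worked_fixture()
        est = estimate_transitions(discretize(records))["chemo"]
        m = estimates_to_matrix(est)
        np.testing.assert_allclose(m.p.sum(axis=1), 1.0, atol=1e-12)
        assert m[0, 1] == pytest.approx(0.2)


class TestKaplanMeier:
    def test_uncensored_median_is_midpoint_of_step_curve(self):
        # S(t) reaches 0.6 at t=6 and 0.4 at t=8 for five uncensored times;
        # the product-limit median (first time S <= 0.5) is 6
        assert km_median([2, 4, 6, 8, 10], [1, 1, 1, 1, 1]) == pytest.approx(6)

    def test_single_event(self):
        assert km_median([5.0], [1]) == pytest.approx(5.0)

    def test_all_censored_not_reached(self):
        assert km_median([3, 6, 9], [0, 0, 0]) is None

    def test_survival_extraction_from_records(self):
        rec = make_records(
            [
                ("a", "chemo", 0, "progression_free"),
                ("a", "chemo", 4, "death"),
                ("b", "chemo", 0, "progression_free"),
                ("b", "chemo", 6, "progressive"),
            ]
        )
        surv = survival_months(rec)
        a = surv[surv["patient_id"] == "a"].iloc[0]
        b = surv[surv["patient_id"] == "b"].iloc[0]
        assert (a.duration_months, a.event) == (4.0, 1)
        assert (b.duration_months, b.event) == (6.0, 0)

    def test_geometric_truth_median_recovered_within_one_cycle(self):
        # per-cycle death probability p gives geometric lifetimes with
        # closed-form median ceil(log(0.5)/log(1-p)) cycles
        p = 0.2
        rng = np.random.default_rng(99)
        cycles = rng.geometric(p, size=4000)
        med = km_median(cycles * 2.0, np.ones_like(cycles))
        closed = np.ceil(np.log(0.5) / np.log(1 - p)) * 2.0
        assert abs(med - closed) <= 2.0


class TestSummaries:
    def test_sample_mean_and_sem(self):
        rows = [
            ("a", "chemo", 0, "progression_free"),
            ("b", "chemo", 0, "progression_free"),
            ("c", "chemo", 0, "progression_free"),
        ]
        rec = make_records(rows)
        rec["direct_medical_idr"] = [10e6, 20e6, 30e6]
        s = summarize_costs_utilities(rec, "chemo", "progression_free")
        assert s["direct_medical"]["mean"] == pytest.approx(20e6)
        assert s["direct_medical"]["se"] == pytest.approx(10e6 / np.sqrt(3))

    def test_identical_values_zero_se(self):
        rec = make_records(
            [(f"p{i}", "chemo", 0, "progressive") for i in range(5)]
        )
        s = summarize_costs_utilities(rec, "chemo", "progressive")
        assert s["direct_medical"]["se"] == 0.0

    def test_two_utility_values(self):
        rec = make_records(
            [("a", "chemo", 0, "progression_free"), ("b", "chemo", 0, "progression_free")]
        )
        rec["eq5d_index"] = [0.8, 0.9]
        s = summarize_costs_utilities(rec, "chemo", "progression_free")
        assert s["utility"]["mean"] == pytest.approx(0.85)
        assert s["utility"]["se"] == pytest.approx(0.05)

    def test_single_patient_se_unavailable(self):
        rec = make_records([("only", "chemo", 0, "progression_free")])
        s = summarize_costs_utilities(rec, "chemo", "progression_free")
        assert s["direct_medical"]["mean"] == pytest.approx(1e6)
        assert s["direct_medical"]["se"] is None

    def test_config_fragment_validates_against_schema(self, config):
        records, _ = worked_fixture()
        # fragment needs both arms: duplicate the fixture as the bev arm
        twin = records.copy()
        twin["arm"] = "chemo_bev"
        twin["patient_id"] = twin["patient_id"] + "b"
        frag = config_fragment(pd.concat([records, twin], ignore_index=True))
        data = config.model_dump(mode="json")

        def merge(dst, src):
            for k, v in src.items():
                if isinstance(v, dict) and isinstance(dst.get(k), dict):
                    merge(dst[k], v)
                else:
                    dst[k] = v

        for key in ("transition_probabilities", "costs_idr", "utilities"):
            merge(data[key], frag[key])
        from crccea.config import ModelConfig

        cfg = ModelConfig.model_validate(data)
        tp = cfg.transition_probabilities.chemo_real_world
        assert tp.progression_free_to_progressive.value == pytest.approx(0.2)
        assert tp.progression_free_to_progressive.alpha == 5
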