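from fractions import Fraction
from itertools import product

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grnlogic.ambiguity import (
    InconsistentObservationError,
    ObservationSet,
    PerturbationPath,
    consistent_count,
    consistent_indices,
    mean_common_count,
    min_common_counts,
    observations_from_step,
    ratio_tables,
    unambiguity_probability,
)
from grnlogic.boolean_space import decode_index, enumerate_search_space


class TestObservationSet:
    def test_merge_disjoint(self):
        merged = ObservationSet(2, {0: 1}).merge(ObservationSet(2, {3: 0}))
        assert merged.observed == {0: 1, 3: 0}

    def test_merge_conflict_raises(self):
        with pytest.raises(InconsistentObservationError, match="state 1"):
            ObservationSet(2, {1: 0}).merge(ObservationSet(2, {1: 1}))

    def test_rejects_bad_state_or_value(self):
        with pytest.raises(ValueError):
            ObservationSet(2, {4: 0})
        with pytest.raises(ValueError):
            ObservationSet(2, {0: 2})

    def test_generating_function_is_consistent(self, space3):
        f = decode_index(22, 3)
        step = observations_from_step(f, 3, "DO")
        assert step.observations.is_consistent_with(f)


class TestObservationsFromStep:
    def test_f22_first_step_from_3(self):
        step = observations_from_step(decode_index(22, 3), 3, "DO", first_step=True)
        assert step.observations.observed == {3: 1, 7: 0, 1: 0, 2: 0}
        assert set(step.destinations) == {7, 1, 2}
        assert step.visible_out_degree == 3
        assert step.fully_visible

    def test_f22_second_step_from_2(self):
        step = observations_from_step(decode_index(22, 3), 2, "DO", first_step=False)
        assert step.observations.observed == {2: 0, 6: 1, 0: 0, 3: 1}
        assert step.visible_out_degree is None

    def test_state_zero_under_d_has_no_transitions(self):
        step = observations_from_step(decode_index(22, 3), 0, "D")
        assert step.destinations == ()
        assert step.observations.observed == {0: 0}

    def test_first_step_visibility_gating_tx(self):
        # F_11^2 state 2 is blind under the transcriptome alone
        step = observations_from_step(
            decode_index(11, 2), 2, "DO", first_step=True, integration="tx"
        )
        assert step.visible_out_degree == 0
        assert not step.fully_visible


class TestConsistentCount:
    def test_f22_single_step_sixteen(self, space3):
        obs = observations_from_step(decode_index(22, 3), 3, "DO").observations
        idx = consistent_indices(obs, space3)
        assert len(idx) == 16
        assert idx == (16, 18, 20, 22, 24, 26, 28, 30,
                       144, 146, 148, 150, 152, 154, 156, 158)

    def test_f22_two_steps_four(self, space3):
        f = decode_index(22, 3)
        obs = observations_from_step(f, 3, "DO").observations
        obs = obs.merge(observations_from_step(f, 2, "DO", first_step=False).observations)
        assert consistent_indices(obs, space3) == (18, 22, 26, 30)

    def test_empty_observations_whole_space(self, space3):
        assert consistent_count(ObservationSet(3, {}), space3) == 218

    def test_full_observation_unique(self, space3):
        f = decode_index(22, 3)
        obs = ObservationSet(3, {s: f.outputs[s] for s in range(8)})
        assert consistent_count(obs, space3) == 1

    def test_completion_route_agrees_exhaustively_k2(self, space2):
        # dual route: inclusion-exclusion completion counting vs filtering,
        # over every partial assignment on 2 inputs
        for values in product([None, 0, 1], repeat=4):
            obs = ObservationSet(
                2, {s: v for s, v in enumerate(values) if v is not None}
            )
            assert consistent_count(obs, space2, method="completion") == (
                consistent_count(obs, space2, method="filter")
            )

    @given(st.data())
    @settings(max_examples=150, deadline=None)
    def test_completion_route_agrees_sampled_k3(self, space3, data):
        values = data.draw(
            st.lists(st.sampled_from([None, 0, 1]), min_size=8, max_size=8)
        )
        obs = ObservationSet(3, {s: v for s, v in enumerate(values) if v is not None})
        assert consistent_count(obs, space3, method="completion") == (
            consistent_count(obs, space3, method="filter")
        )

    @given(st.data())
    @settings(max_examples=25, deadline=None)
    def test_completion_route_agrees_sampled_k4(self, space4, data):
        values = data.draw(
            st.lists(st.sampled_from([None, 0, 1]), min_size=16, max_size=16)
        )
        obs = ObservationSet(4, {s: v for s, v in enumerate(values) if v is not None})
        assert consistent_count(obs, space4, method="completion") == (
            consistent_count(obs, space4, method="filter")
        )


class TestPerturbationPath:
    def test_valid_do_path(self):
        path = PerturbationPath(3, "DO", (3, 2, 6))
        assert path.n_p == 3

    def test_d_path_must_descend(self):
        with pytest.raises(ValueError, match="reachable"):
            PerturbationPath(3, "D", (3, 7))

    def test_d_path_length_capped_at_k(self):
        with pytest.raises(ValueError, match="exhaust"):
            PerturbationPath(2, "D", (3, 2, 0, 0))

    def test_unreachable_step_rejected(self):
        with pytest.raises(ValueError, match="reachable"):
            PerturbationPath(2, "DO", (0, 3))


class TestUnambiguityProbability:
    def test_do_cis_k2_single_step_80_percent(self):
        res = unambiguity_probability(2, "DO", "cis-ppi", 1)
        assert res.exact_P_ua == Fraction(4, 5)

    def test_do_cis_k2_two_steps_certain(self):
        assert unambiguity_probability(2, "DO", "cis-ppi", 2).exact_P_ua == 1

    def test_do_cis_k3_four_steps_certain(self):
        assert unambiguity_probability(3, "DO", "cis-ppi", 4).exact_P_ua == 1

    @pytest.mark.parametrize("k,ratio", [(2, 4), (3, 8), (4, 16)])
    def test_do_over_d_tx_is_2k(self, k, ratio):
        do = unambiguity_probability(k, "DO", "tx", 1).exact_P_ua
        d = unambiguity_probability(k, "D", "tx", 1).exact_P_ua
        assert do / d == ratio

    @pytest.mark.parametrize("k", [2, 3])
    @pytest.mark.parametrize("regime", ["D", "DO"])
    @pytest.mark.parametrize("integration", ["tx", "ppi", "cis-ppi"])
    def test_monotone_in_steps(self, k, regime, integration):
        limit = k if regime == "D" else 4
        values = [
            unambiguity_probability(k, regime, integration, n).exact_P_ua
            for n in range(1, limit + 1)
        ]
        assert all(lo <= hi for lo, hi in zip(values, values[1:]))

    @pytest.mark.parametrize("k", [2, 3])
    @pytest.mark.parametrize("regime", ["D", "DO"])
    def test_monotone_in_integration(self, k, regime):
        tx = unambiguity_probability(k, regime, "tx", 1).exact_P_ua
        ppi = unambiguity_probability(k, regime, "ppi", 1).exact_P_ua
        cis = unambiguity_probability(k, regime, "cis-ppi", 1).exact_P_ua
        assert tx <= ppi <= cis

    def test_d_regime_rejects_np_beyond_k(self):
        with pytest.raises(ValueError, match="n_p=3"):
            unambiguity_probability(2, "D", "tx", 3)

    def test_np_must_be_positive(self):
        with pytest.raises(ValueError):
            unambiguity_probability(2, "DO", "tx", 0)

    def test_saturated_paths_resolve_everything(self):
        # DO+cis at (k=2, n_p=2): minimal paths see all four states
        mins = min_common_counts(2, "DO", 2)
        assert (mins == 1).all()

    def test_d_from_top_exhausts_at_state_zero(self):
        # a k-step knock-down path observes a chain down to state 0
        mins = min_common_counts(3, "D", 3)
        space = enumerate_search_space(3)
        # chain 7 -> x -> y -> 0 exists for every function; the minimal count
        # can never be smaller than the fully observed chain allows
        assert mins[:, 7].min() >= 1

    def test_result_record(self):
        rec = unambiguity_probability(2, "DO", "tx", 1).to_record()
        assert rec["P_ua"] == pytest.approx(0.2)
        assert rec["n_p"] == 1


class TestMinCommonCounts:
    def test_single_step_matches_direct_filter(self, space3):
        mins = min_common_counts(3, "DO", 1, space3)
        for j, b in [(0, space3.indices[0]), (100, space3.indices[100])]:
            f = decode_index(b, 3)
            for s in range(8):
                obs = observations_from_step(f, s, "DO").observations
                assert mins[j, s] == consistent_count(obs, space3)

    def test_f22_entry(self, space3):
        j = space3.indices.index(22)
        assert min_common_counts(3, "DO", 1, space3)[j, 3] == 16

    def test_two_step_minimum_at_most_any_path(self, space3):
        # the reported minimum beats the specific worked path 3 -> 2
        f = decode_index(22, 3)
        obs = observations_from_step(f, 3, "DO").observations
        obs = obs.merge(observations_from_step(f, 2, "DO", first_step=False).observations)
        j = space3.indices.index(22)
        assert min_common_counts(3, "DO", 2, space3)[j, 3] <= consistent_count(
            obs, space3
        )


class TestMeanCommonCount:
    def test_at_least_one(self):
        for regime in ("D", "DO"):
            assert mean_common_count(2, regime, "cis-ppi") >= 1

    def test_do_tx_includes_f22_contribution(self, space3):
        # the (F_22^3, s=3) cell contributes its count of 16 to the average
        mins = min_common_counts(3, "DO", 1, space3)
        assert mins[space3.indices.index(22), 3] == 16
        assert mean_common_count(3, "DO", "tx") >= 1

    def test_d_averages_top_state_only(self, space2):
        mins = min_common_counts(2, "D", 1, space2)
        assert mean_common_count(2, "D", "cis-ppi") == pytest.approx(
            float(mins[:, 3].mean())
        )

    def test_unrestricted_mean_covers_all_states(self):
        r = mean_common_count(2, "DO", "tx", restrict_visible=False)
        assert r >= mean_common_count(2, "DO", "cis-ppi")


@pytest.fixture(scope="module")
def tables():
    return ratio_tables((2, 3), n_p_max=4)


class TestRatioTables:

    def test_do_over_d_first_row_tx(self, tables):
        row = tables["do_over_d"]["n_p=1"]
        assert row["k=2"]["tx"] == pytest.approx(4)
        assert row["k=3"]["tx"] == pytest.approx(8)

    def test_k3_np2_cis_ratio(self, tables):
        assert tables["do_over_d"]["n_p=2"]["k=3"]["cis-ppi"] == pytest.approx(
            4.33, abs=0.01
        )

    def test_integration_gain_d_k3_cis(self, tables):
        # clamped average over n_p = 1..4; prints as 18 at paper precision
        assert tables["integration_gain"]["D"]["k=3"]["cis-ppi"] == pytest.approx(17.75)

    def test_clamp_flags(self, tables):
        assert tables["do_over_d"]["n_p=3"]["k=2"]["d_clamped"] is True
        assert tables["do_over_d"]["n_p=2"]["k=2"]["d_clamped"] is False

    def test_omit_mode_drops_exhausted(self):
        tabs = ratio_tables((2,), n_p_max=3, exhausted="omit")
        assert tabs["do_over_d"]["n_p=3"]["k=2"]["tx"] is None
        # feasible-only average reproduces the k=2 row of the printed table
        assert tabs["integration_gain"]["D"]["k=2"]["cis-ppi"] == pytest.approx(7.0)
        assert tabs["integration_gain"]["D"]["k=2"]["ppi"] == pytest.approx(2.5)
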