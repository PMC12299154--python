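"""Monthly kernel: event semantics, stochasticity, Monte-Carlo agreement."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dairyherd as dh
from dairyherd import CowState
from dairyherd.states import INITIAL_STATE
from dairyherd.transitions import (
    EVENT_NAMES,
    ProbabilityCapWarning,
    event_probabilities,
    transition_distribution,
)


class TestKernelExamples:
    def test_fresh_heifer_month(self, defaults, validation_policy):
        """A first-month heifer either exits (replaced in place) or moves on;
        conception is impossible before the second month."""
        rates, effects, _ = defaults
        dist = dict(
            transition_distribution(
                CowState(0, 1, 0, 1), rates, effects, validation_policy, "base"
            )
        )
        assert dist == {
            CowState(0, 1, 0, 1): pytest.approx(0.010, abs=1e-12),
            CowState(0, 1, 0, 2): pytest.approx(0.990, abs=1e-12),
        }

    def test_first_service_conception_mass(self, defaults, validation_policy):
        """Survivors of month 2 conceive at the primiparous service rate."""
        rates, effects, _ = defaults
        dist = dict(
            transition_distribution(
                CowState(0, 1, 0, 2), rates, effects, validation_policy, "base"
            )
        )
        assert dist[CowState(0, 1, 1, 3)] == pytest.approx(0.99 * 0.2368, abs=1e-12)
        assert dist[CowState(0, 1, 0, 3)] == pytest.approx(0.99 * (1 - 0.2368), abs=1e-12)

    def test_detectable_abortion_splits_into_types(self, defaults, validation_policy):
        """A gestation-month-3 abortion is RA with probability 84.8% (cow
        keeps lactating) and NLA otherwise (fresh lactation, next parity)."""
        rates, effects, _ = defaults
        dist = dict(
            transition_distribution(
                CowState(0, 2, 3, 7), rates, effects, validation_policy, "extended"
            )
        )
        survive = 1 - (0.009 + 0.011)
        abort = survive * 0.025
        assert dist[CowState(1, 2, 0, 8)] == pytest.approx(abort * (1 - 1.9 / 12.5))
        assert dist[CowState(2, 3, 0, 1)] == pytest.approx(abort * (1.9 / 12.5))
        assert dist[CowState(0, 2, 4, 8)] == pytest.approx(survive - abort)

    def test_base_model_keeps_abortions_untyped(self, defaults, validation_policy):
        rates, effects, _ = defaults
        dist = dict(
            transition_distribution(
                CowState(0, 2, 3, 7), rates, effects, validation_policy, "base"
            )
        )
        survive = 1 - 0.020
        assert dist[CowState(0, 2, 0, 8)] == pytest.approx(survive * 0.025)

    def test_voluntary_cull_at_threshold(self, defaults, validation_policy):
        """An open cow reaching the threshold month is wholly replaced."""
        rates, effects, _ = defaults
        dist = dict(
            transition_distribution(
                CowState(0, 3, 0, 10), rates, effects, validation_policy, "base"
            )
        )
        assert dist == {INITIAL_STATE: pytest.approx(1.0, abs=1e-12)}

    def test_calving_and_parity_cap(self, defaults, validation_policy):
        rates, effects, _ = defaults
        dist = dict(
            transition_distribution(
                CowState(0, 3, 9, 12), rates, effects, validation_policy, "base"
            )
        )
        assert dist[CowState(0, 4, 0, 1)] == pytest.approx(1 - 0.012)
        dist_cap = dict(
            transition_distribution(
                CowState(0, 15, 9, 12), rates, effects, validation_policy, "base"
            )
        )
        assert dist_cap == {INITIAL_STATE: pytest.approx(1.0, abs=1e-12)}

    def test_culling_multiplier_for_aborted_cows(self, defaults, validation_policy):
        """Extended model: aborted cows face 1.9x the involuntary culling."""
        rates, effects, _ = defaults
        ev = event_probabilities(
            CowState(1, 2, 0, 5), rates, effects, validation_policy, "extended"
        )
        assert ev.involuntary_cull == pytest.approx(1.9 * 0.014)
        assert ev.death == pytest.approx(0.010)

    def test_infeasible_origin_rejected(self, defaults, validation_policy):
        rates, effects, _ = defaults
        with pytest.raises(ValueError, match="infeasible"):
            transition_distribution(
                CowState(0, 1, 1, 1), rates, effects, validation_policy, "base"
            )

    def test_multiplier_overflow_is_capped_with_warning(self, defaults, validation_policy):
        rates, _, _ = defaults
        harsh = dh.AbortionEffects(cull_risk_multiplier=80.0)
        with pytest.warns(ProbabilityCapWarning):
            dist = transition_distribution(
                CowState(1, 2, 0, 5), rates, harsh, validation_policy, "extended"
            )
        assert sum(p for _, p in dist) == pytest.approx(1.0, abs=1e-12)


class TestMatrixInvariants:
    @pytest.mark.parametrize("model_kind", ["base", "extended"])
    @pytest.mark.parametrize("policy", [(2, 2), (6, 10), (11, 10), (15, 15)])
    def test_rows_stochastic_and_events_complete(self, defaults, model_kind, policy):
        rates, effects, _ = defaults
        space = dh.enumerate_states(model_kind)
        tm = dh.build_transition_matrix(space, rates, effects, dh.Policy(*policy))
        row_sums = np.asarray(tm.matrix.sum(axis=1)).ravel()
        np.testing.assert_allclose(row_sums, 1.0, atol=1e-12)
        np.testing.assert_allclose(tm.events.sum(axis=1), 1.0, atol=1e-12)
        assert (tm.events.to_numpy() >= 0).all()

    def test_matrix_rows_equal_kernel(self, defaults, validation_policy, ext_space):
        rates, effects, _ = defaults
        tm = dh.build_transition_matrix(ext_space, rates, effects, validation_policy)
        rng = np.random.default_rng(0)
        for i in rng.choice(len(ext_space), size=200, replace=False):
            state = ext_space.states[i]
            expected = transition_distribution(
                state, rates, effects, validation_policy, "extended"
            )
            assert sorted(tm.row(state)) == [
                (s, pytest.approx(p, abs=0)) for s, p in expected
            ]

    def test_no_abortions_isolate_extended_blocks(self, defaults, validation_policy, ext_space):
        """With a zero abortion hazard no cow can ever leave level AB=0."""
        rates, effects, _ = defaults
        no_abort = replace(rates, abort_hazard=np.zeros_like(rates.abort_hazard))
        tm = dh.build_transition_matrix(ext_space, no_abort, effects, validation_policy)
        ab = np.array([s.ab for s in ext_space.states])
        from_ab0 = tm.matrix[ab == 0][:, ab >= 1]
        assert from_ab0.nnz == 0

    def test_triplet_export_round_trip(self, defaults, validation_policy, base_space):
        rates, effects, _ = defaults
        tm = dh.build_transition_matrix(base_space, rates, effects, validation_policy)
        trip = tm.to_triplets()
        assert trip["prob"].sum() == pytest.approx(len(base_space), abs=1e-9)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(min_value=0, max_value=2**31 - 1))
    def test_random_tables_yield_stochastic_kernels(self, seed):
        """Row-stochasticity holds for arbitrary valid rate tables."""
        rates = dh.random_rate_tables(seed)
        space = dh.enumerate_states("base")
        tm = dh.build_transition_matrix(space, rates, None, dh.Policy(8, 7))
        row_sums = np.asarray(tm.matrix.sum(axis=1)).ravel()
        np.testing.assert_allclose(row_sums, 1.0, atol=1e-12)


def test_one_step_monte_carlo_frequencies(defaults, validation_policy):
    """Empirical one-step frequencies from 1e5 draws of one pregnant state
    match the kernel within three binomial standard errors."""
    rates, effects, _ = defaults
    dist = transition_distribution(
        CowState(0, 2, 3, 7), rates, effects, validation_policy, "extended"
    )
    dests, probs = zip(*dist)
    probs = np.asarray(probs)
    n = 100_000
    rng = np.random.default_rng(12345)
    counts = np.bincount(rng.choice(len(dests), size=n, p=probs), minlength=len(dests))
    freq = counts / n
    se = np.sqrt(probs * (1 - probs) / n)
    assert (np.abs(freq - probs) <= 3 * se + 1e-12).all()


def test_event_names_cover_decomposition(defaults, validation_policy):
    rates, effects, _ = defaults
    ev = event_probabilities(
        CowState(0, 2, 0, 5), rates, effects, validation_policy, "base"
    )
    assert set(ev.as_dict()) == set(EVENT_NAMES)
    assert ev.total() == pytest.approx(1.0, abs=1e-12)
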