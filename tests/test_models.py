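import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gonogo import MODELS, MODEL_IDS, ParameterVector, TaskConfig, make_session
from gonogo.models import (
    action_weights,
    choice_probability,
    effective_learning_rate,
    init_state,
    sequence_log_likelihood,
    to_constrained,
    to_unconstrained,
    update_state,
)
from gonogo.simulate import simulate_subject
from gonogo.task import AVOID, GO, NOGO, WIN, Cue, TrialRecord

from conftest import random_params

M1, M7 = MODELS["M1"], MODELS["M7"]


def make_pv(**constrained):
    """M7 ParameterVector from constrained values, zeros elsewhere."""
    defaults = dict(rho=1.0, eps=0.5, go_bias=0.0, pi=0.0, kappa=1e-12,
                    phi_int=0.0, phi_diff=1e-12)
    defaults.update(constrained)
    return ParameterVector.from_constrained(M7, **defaults)


class TestTransforms:
    @pytest.mark.parametrize("name,values", [
        ("rho", [0.1, 1.0, 5.0, 50.0]),
        ("eps", [0.01, 0.3, 0.5, 0.9]),
        ("kappa", [0.05, 0.5, 2.0]),
        ("phi_diff", [0.05, 0.5, 2.0]),
        ("go_bias", [-2.0, 0.0, 1.5]),
        ("pi", [-1.0, 0.0, 2.0]),
        ("phi_int", [-0.5, 0.0, 0.7]),
    ])
    def test_round_trip(self, name, values):
        for y in values:
            assert to_constrained(name, to_unconstrained(name, y)) == pytest.approx(y, abs=1e-10)

    def test_inactive_parameters_are_zero(self):
        pv = ParameterVector(M1, np.array([0.3, -0.2]))
        assert pv.go_bias == pv.pi == pv.kappa == pv.phi_int == pv.phi_diff == 0.0

    def test_json_round_trip(self, rng):
        pv = random_params(MODELS["M5"], rng)
        back = ParameterVector.from_json(pv.to_json())
        np.testing.assert_allclose(back.x, pv.x)
        assert back.spec.model_id == "M5"


class TestNesting:
    def test_model_family_structure(self):
        assert MODELS["M1"].active_parameters == ("rho", "eps")
        assert MODELS["M4"].active_parameters == ("rho", "eps", "go_bias", "kappa")
        assert MODELS["M7"].n_params == 7
        for mid in MODEL_IDS:
            assert set(MODELS["M1"].active_parameters) <= set(MODELS[mid].active_parameters)


class TestActionWeights:
    def test_first_trial_fully_muted(self):
        cue = Cue(0, WIN, GO)
        pv = make_pv(rho=2.0, pi=1.0)
        state = init_state([cue], pv)
        assert action_weights(state, cue, pv) == (0.0, 0.0)

    def test_unmuted_win_cue_hand_computation(self):
        # Q(Go)=1, Q(NoGo)=0, b=0.2, pi=0.4, no history:
        # w_Go = 1 + 0.2 + 0.4 * 0.5 = 1.4, w_NoGo = 0
        cue = Cue(0, WIN, GO)
        pv = make_pv(go_bias=0.2, pi=0.4)
        state = init_state([cue], pv)
        state.muted[0] = False
        state.q[(0, GO)] = 1.0
        state.q[(0, NOGO)] = 0.0
        w_go, w_nogo = action_weights(state, cue, pv)
        assert w_go == pytest.approx(1.4)
        assert w_nogo == pytest.approx(0.0)

    def test_persistence_avoid_branch(self):
        # Avoid cue, last action Go: Go weight gets phi_int - phi_diff = +0.2
        cue = Cue(0, AVOID, NOGO)
        pv = make_pv(phi_int=0.3, phi_diff=0.1)
        state = init_state([cue], pv)
        state.last_action[0] = GO
        w_go, w_nogo = action_weights(state, cue, pv)
        assert w_go == pytest.approx(0.3 - 0.1)
        assert w_nogo == pytest.approx(0.0)

    def test_unknown_cue_raises(self):
        pv = make_pv()
        state = init_state([Cue(0, WIN, GO)], pv)
        with pytest.raises(KeyError):
            action_weights(state, Cue(5, WIN, GO), pv)

    def test_pi_muted_until_valenced_outcome(self):
        cue = Cue(0, WIN, GO)
        lo, hi = make_pv(pi=0.1), make_pv(pi=5.0)
        for pv in (lo, hi):
            state = init_state([cue], pv)
            assert action_weights(state, cue, pv) == (0.0, 0.0)


class TestChoiceProbability:
    def test_symmetry_and_closed_form(self):
        assert choice_probability((0.0, 0.0)) == pytest.approx(0.5)
        assert choice_probability((math.log(2.0), 0.0)) == pytest.approx(2.0 / 3.0)

    @given(w=st.floats(-30, 30), c=st.floats(-500, 500))
    @settings(max_examples=50, deadline=None)
    def test_shift_invariance(self, w, c):
        assert choice_probability((w + c, c)) == pytest.approx(
            choice_probability((w, 0.0)), abs=1e-12
        )

    def test_nonfinite_weights_rejected(self):
        with pytest.raises(ValueError):
            choice_probability((float("nan"), 0.0))


class TestEffectiveLearningRate:
    def test_zero_bias_reduction(self):
        pv = make_pv(eps=0.37, kappa=0.0)
        for action, outcome in itertools.product((GO, NOGO), (-1, 0, 1)):
            assert effective_learning_rate(pv, action, outcome) == pytest.approx(0.37)

    def test_neutral_outcome_uses_base_rate(self):
        pv = make_pv(eps=0.3, kappa=0.8)
        assert effective_learning_rate(pv, GO, 0) == pytest.approx(0.3)
        assert effective_learning_rate(pv, NOGO, 0) == pytest.approx(0.3)

    def test_logit_space_bias_frozen_example(self):
        # X_eps = -1, kappa = 0.5 applied in logit space:
        # eps0 = logistic(-1) = 0.26894, eps_punNoGo = logistic(-1.5) = 0.18243,
        # eps_rewGo = 2 * 0.26894 - 0.18243 = 0.35546
        pv = ParameterVector.from_constrained(
            MODELS["M4"], rho=1.0, eps=float(1 / (1 + np.exp(1.0))),
            go_bias=0.0, kappa=0.5,
        )
        assert effective_learning_rate(pv, NOGO, -1) == pytest.approx(0.18242552380635635, abs=1e-9)
        assert effective_learning_rate(pv, GO, 1) == pytest.approx(0.35545731893363385, abs=1e-9)

    @pytest.mark.parametrize("x_eps", [-2.0, -0.5, 0.0, 0.5, 2.0])
    @pytest.mark.parametrize("kappa", [0.1, 0.5, 1.5])
    def test_symmetric_impact_of_kappa(self, x_eps, kappa):
        pv = ParameterVector(
            MODELS["M4"],
            np.array([0.0, x_eps, 0.0, to_unconstrained("kappa", kappa)]),
        )
        eps0 = 1.0 / (1.0 + np.exp(-x_eps))
        e_rg = effective_learning_rate(pv, GO, 1)
        e_pn = effective_learning_rate(pv, NOGO, -1)
        assert abs((e_rg - eps0) - (eps0 - e_pn)) < 1e-10
        assert 0.0 <= e_pn <= e_rg <= 1.0

    def test_branch_continuity_at_half(self):
        # both branch readings coincide when eps0 = 0.5
        pv = ParameterVector(MODELS["M4"], np.array([0.0, 0.0, 0.0, 0.3]))
        kappa = pv.kappa
        e_rg = effective_learning_rate(pv, GO, 1)
        e_pn = effective_learning_rate(pv, NOGO, -1)
        assert e_rg == pytest.approx(1.0 / (1.0 + np.exp(-kappa)), abs=1e-12)
        assert e_pn == pytest.approx(1.0 / (1.0 + np.exp(kappa)), abs=1e-12)


class TestUpdateState:
    def test_delta_rule_arithmetic(self):
        cue = Cue(0, WIN, GO)
        pv = make_pv(rho=2.0, eps=0.5)
        state = init_state([cue], pv)
        state.q[(0, GO)] = 0.0
        update_state(state, cue, GO, 1, pv)
        assert state.q[(0, GO)] == pytest.approx(1.0)  # 0 + 0.5*(2*1 - 0)
        assert state.muted[0] is False
        assert state.last_action[0] == GO

    def test_fixed_point_when_rho_r_equals_q(self):
        cue = Cue(0, WIN, GO)
        pv = make_pv(rho=3.0, eps=0.7)
        state = init_state([cue], pv)
        state.q[(0, GO)] = 3.0
        update_state(state, cue, GO, 1, pv)
        assert state.q[(0, GO)] == pytest.approx(3.0)

    def test_neutral_outcome_does_not_unmute(self):
        cue = Cue(0, WIN, GO)
        pv = make_pv()
        state = init_state([cue], pv)
        update_state(state, cue, GO, 0, pv)
        assert state.muted[0] is True

    def test_geometric_recursion_closed_form(self):
        # constant reward: Q_t = rho*r + (Q_0 - rho*r)(1 - eps)^t
        cue = Cue(0, WIN, GO)
        pv = make_pv(rho=2.5, eps=0.3)
        state = init_state([cue], pv)
        q0 = state.q[(0, GO)]
        for t in range(1, 9):
            update_state(state, cue, GO, 1, pv)
            expected = 2.5 + (q0 - 2.5) * (1.0 - 0.3) ** t
            assert state.q[(0, GO)] == pytest.approx(expected, abs=1e-12)

    def test_other_entries_untouched(self):
        cues = [Cue(0, WIN, GO), Cue(1, AVOID, NOGO)]
        pv = make_pv(rho=2.0, eps=0.5)
        state = init_state(cues, pv)
        before = dict(state.q)
        update_state(state, cues[0], GO, 1, pv)
        for key, val in before.items():
            if key != (0, GO):
                assert state.q[key] == val


def _deterministic_toy(n_trials, responses):
    """Single Win-Go cue, validity-1 feedback (reward iff Go)."""
    cue = Cue(0, WIN, GO)
    trials = []
    for t, resp in enumerate(responses, start=1):
        trials.append(
            TrialRecord(
                session_id="toy", block_index=1, trial_index_in_block=t,
                cue=cue, response=resp, outcome=1 if resp == GO else 0,
            )
        )
    return trials


class TestSequenceLikelihood:
    @pytest.mark.parametrize("mid", ["M1", "M4", "M7"])
    @pytest.mark.parametrize("T", [2, 4, 6])
    def test_sequence_probabilities_normalize(self, mid, T, rng):
        spec = MODELS[mid]
        pv = random_params(spec, rng)
        total = 0.0
        for pattern in itertools.product([GO, NOGO], repeat=T):
            trials = _deterministic_toy(T, pattern)
            total += math.exp(sequence_log_likelihood(trials, pv))
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_fast_matches_reference(self, rng, m7_dataset):
        for mid in MODEL_IDS:
            pv = random_params(MODELS[mid], rng)
            fast = sequence_log_likelihood(m7_dataset, pv, engine="fast")
            ref = sequence_log_likelihood(m7_dataset, pv, engine="reference")
            assert fast == pytest.approx(ref, abs=1e-10)

    def test_nested_models_reduce_bitcompatibly(self, rng, m7_dataset):
        """Fixing the richer model's extra parameters at 0 reproduces the
        nested model's likelihood exactly."""
        pairs = [("M1", "M2"), ("M2", "M3"), ("M2", "M4"), ("M3", "M5"),
                 ("M5", "M6"), ("M6", "M7"), ("M1", "M7")]
        for small_id, big_id in pairs:
            small, big = MODELS[small_id], MODELS[big_id]
            pv_small = random_params(small, rng)
            x_big = np.full(big.n_params, -np.inf)
            for j, name in enumerate(big.active_parameters):
                if name in small.active_parameters:
                    x_big[j] = pv_small.x[small.index_of(name)]
                else:
                    # identity-transformed biases off at 0; softplus at -inf
                    x_big[j] = 0.0 if name in ("go_bias", "pi", "phi_int") else -np.inf
            ll_small = sequence_log_likelihood(m7_dataset, pv_small)
            ll_big = sequence_log_likelihood(m7_dataset, ParameterVector(big, x_big))
            assert ll_big == ll_small

    def test_incomplete_trials_rejected(self):
        trials = make_session(TaskConfig(), rng=0)
        with pytest.raises(ValueError):
            sequence_log_likelihood(trials, random_params(M1, np.random.default_rng(0)))

    def test_all_go_saturates_to_certainty(self):
        trials = _deterministic_toy(10, [GO] * 10)
        pv = make_pv(go_bias=40.0)
        assert sequence_log_likelihood(trials, pv) == pytest.approx(0.0, abs=1e-12)

    def test_go_probability_monotonic_in_pi(self, rng):
        """More response bias means more Go on unmuted Win cues, less on
        unmuted Avoid cues."""
        session = make_session(TaskConfig(n_blocks=1, trials_per_block=80), rng=rng)
        data = simulate_subject(session, make_pv(rho=2.0, eps=0.3, go_bias=0.2), rng=rng)
        from gonogo.models import predicted_go_probabilities

        seen_valenced = set()
        unmuted = []
        for i, t in enumerate(data.trials):
            unmuted.append(t.cue.id in seen_valenced)
            if t.outcome != 0:
                seen_valenced.add(t.cue.id)
        pis = [0.0, 0.5, 1.5]
        probs = [
            predicted_go_probabilities(data.trials, make_pv(rho=2.0, eps=0.3, go_bias=0.2, pi=p))
            for p in pis
        ]
        for i, t in enumerate(data.trials):
            if not unmuted[i]:
                continue
            a, b, c = probs[0][i], probs[1][i], probs[2][i]
            if t.cue.valence == WIN:
                assert a < b < c
            else:
                assert a > b > c
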