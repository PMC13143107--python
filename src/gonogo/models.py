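"""The nested M1-M7 Q-learning model family with Pavlovian bias terms.

All models learn per-cue action values Q(a, s) from prediction errors,

    Q_t(a_t, s_t) = Q_{t-1}(a_t, s_t) + eps * (rho * r_t - Q_{t-1}(a_t, s_t)),

and map action weights w(a, s) to choice probabilities through a softmax.
The base model M1 has a feedback sensitivity ``rho`` (playing the role of an
inverse temperature) and a learning rate ``eps``. The extensions add:

* ``go_bias`` (b, M2+): constant bonus on the Go weight;
* ``pi`` (M3, M5+): response bias, pi * V(s) added to the Go weight with cue
  valence V = +0.5 (Win) / -0.5 (Avoid);
* ``kappa`` (M4, M5+): learning bias, boosting the rate for rewarded Go and
  dampening it for punished NoGo, applied symmetrically in logit space;
* ``phi_int`` (M6+): persistence, added to the weight of whichever action was
  taken on the previous encounter of the same cue;
* ``phi_diff`` (M7): persistence bias, added to the repeated action's weight
  for Win cues and subtracted for Avoid cues.

Q-values start at the midpoint of each cue's outcome range, V(s) * rho, and
are "muted" (excluded from action selection, together with the pi * V term)
until the first valenced (non-zero) outcome reveals the cue's valence;
learning proceeds during muting.

Parameters are estimated in an unconstrained space X: rho = exp(X_rho),
eps = logistic(X_eps), kappa and phi_diff via the softplus
y = log(1 + exp(x)), and b, pi, phi_int untransformed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit, logit

from . import _fastlik
from .task import GO, NOGO, WIN, Cue, TrialRecord, TrialArrays, trials_to_arrays

PARAM_NAMES = ("rho", "eps", "go_bias", "pi", "kappa", "phi_int", "phi_diff")

_MODEL_PARAMS: dict[str, tuple[str, ...]] = {
    "M1": ("rho", "eps"),
    "M2": ("rho", "eps", "go_bias"),
    "M3": ("rho", "eps", "go_bias", "pi"),
    "M4": ("rho", "eps", "go_bias", "kappa"),
    "M5": ("rho", "eps", "go_bias", "pi", "kappa"),
    "M6": ("rho", "eps", "go_bias", "pi", "kappa", "phi_int"),
    "M7": ("rho", "eps", "go_bias", "pi", "kappa", "phi_int", "phi_diff"),
}

_TRANSFORMS = {
    "rho": "exp",
    "eps": "logistic",
    "go_bias": "identity",
    "pi": "identity",
    "kappa": "softplus",
    "phi_int": "identity",
    "phi_diff": "softplus",
}


def softplus(x: float | np.ndarray) -> float | np.ndarray:
    return np.logaddexp(0.0, x)


def softplus_inv(y: float | np.ndarray) -> float | np.ndarray:
    y = np.asarray(y, dtype=float)
    with np.errstate(divide="ignore"):  # y = 0 maps to -inf by design
        out = y + np.log(-np.expm1(-y))
    return float(out) if out.ndim == 0 else out


def to_constrained(name: str, x: float) -> float:
    t = _TRANSFORMS[name]
    if t == "exp":
        return float(np.exp(x))
    if t == "logistic":
        return float(expit(x))
    if t == "softplus":
        return float(softplus(x))
    return float(x)


def to_unconstrained(name: str, y: float) -> float:
    t = _TRANSFORMS[name]
    if t == "exp":
        return float(np.log(y))
    if t == "logistic":
        return float(logit(y))
    if t == "softplus":
        return float(softplus_inv(y))
    return float(y)


@dataclass(frozen=True)
class ModelSpec:
    """Which of the seven nested models is active.

    Inactive parameters are fixed at 0 (on the constrained scale); ``rho``
    and ``eps`` are always free.
    """

    model_id: str

    def __post_init__(self) -> None:
        if self.model_id not in _MODEL_PARAMS:
            raise ValueError(f"unknown model id {self.model_id!r}")

    @property
    def active_parameters(self) -> tuple[str, ...]:
        return _MODEL_PARAMS[self.model_id]

    @property
    def n_params(self) -> int:
        return len(self.active_parameters)

    def index_of(self, name: str) -> int:
        return self.active_parameters.index(name)


MODELS: dict[str, ModelSpec] = {mid: ModelSpec(mid) for mid in _MODEL_PARAMS}
MODEL_IDS: tuple[str, ...] = tuple(_MODEL_PARAMS)


@dataclass(frozen=True)
class ParameterVector:
    """Unconstrained parameters X for a model, with constrained views."""

    spec: ModelSpec
    x: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.x, dtype=float)
        if arr.shape != (self.spec.n_params,):
            raise ValueError(
                f"{self.spec.model_id} expects {self.spec.n_params} unconstrained "
                f"values, got shape {arr.shape}"
            )
        object.__setattr__(self, "x", arr)

    @classmethod
    def from_constrained(cls, spec: ModelSpec, **values: float) -> "ParameterVector":
        """Build from constrained values (rho=..., eps=..., ...)."""
        extra = set(values) - set(spec.active_parameters)
        if extra:
            raise ValueError(f"parameters {sorted(extra)} not active in {spec.model_id}")
        x = np.array(
            [to_unconstrained(n, values[n]) for n in spec.active_parameters], dtype=float
        )
        return cls(spec, x)

    def _get(self, name: str, unconstrained: bool = False) -> float:
        if name not in self.spec.active_parameters:
            # inactive parameters are fixed at 0 on the constrained scale
            return 0.0
        xi = float(self.x[self.spec.index_of(name)])
        return xi if unconstrained else to_constrained(name, xi)

    @property
    def rho(self) -> float:
        return self._get("rho")

    @property
    def eps(self) -> float:
        return self._get("eps")

    @property
    def x_eps(self) -> float:
        return self._get("eps", unconstrained=True)

    @property
    def go_bias(self) -> float:
        return self._get("go_bias")

    @property
    def pi(self) -> float:
        return self._get("pi")

    @property
    def kappa(self) -> float:
        return self._get("kappa")

    @property
    def phi_int(self) -> float:
        return self._get("phi_int")

    @property
    def phi_diff(self) -> float:
        return self._get("phi_diff")

    def constrained(self) -> dict[str, float]:
        return {
            n: to_constrained(n, float(self.x[i]))
            for i, n in enumerate(self.spec.active_parameters)
        }

    def to_json(self) -> str:
        return json.dumps(
            {
                "model_id": self.spec.model_id,
                "unconstrained": dict(zip(self.spec.active_parameters, self.x.tolist())),
                "constrained": self.constrained(),
                "transforms": {n: _TRANSFORMS[n] for n in self.spec.active_parameters},
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ParameterVector":
        data = json.loads(text)
        spec = MODELS[data["model_id"]]
        x = np.array([data["unconstrained"][n] for n in spec.active_parameters])
        return cls(spec, x)


# ---------------------------------------------------------------------------
# reference (step-by-step) implementation


@dataclass
class AgentState:
    """Per-cue Q-values, muting flags, and last-response memory."""

    q: dict[tuple[int, str], float]
    muted: dict[int, bool]
    last_action: dict[int, str | None]
    cues: dict[int, Cue] = field(default_factory=dict)


def init_state(cues: Sequence[Cue], params: ParameterVector) -> AgentState:
    """Fresh state: Q(a, s) = V(s) * rho for both actions; everything muted."""
    q: dict[tuple[int, str], float] = {}
    muted: dict[int, bool] = {}
    last: dict[int, str | None] = {}
    reg: dict[int, Cue] = {}
    for cue in cues:
        q0 = cue.valence_value * params.rho
        q[(cue.id, GO)] = q0
        q[(cue.id, NOGO)] = q0
        muted[cue.id] = True
        last[cue.id] = None
        reg[cue.id] = cue
    return AgentState(q=q, muted=muted, last_action=last, cues=reg)


def action_weights(
    state: AgentState, cue: Cue, params: ParameterVector
) -> tuple[float, float]:
    """(w_Go, w_NoGo) for the next choice on ``cue``.

    While a cue is muted its Q-values and the pi * V response-bias term are
    multiplied with zero; the Go bias and persistence terms apply throughout.
    """
    if cue.id not in state.muted:
        raise KeyError(f"cue {cue.id} unknown to this agent state")
    v = cue.valence_value
    w_go = params.go_bias
    w_nogo = 0.0
    if not state.muted[cue.id]:
        w_go += state.q[(cue.id, GO)] + params.pi * v
        w_nogo += state.q[(cue.id, NOGO)]
    last = state.last_action[cue.id]
    if last is not None:
        persist = params.phi_int + (params.phi_diff if cue.valence == WIN else -params.phi_diff)
        if last == GO:
            w_go += persist
        else:
            w_nogo += persist
    return w_go, w_nogo


def choice_probability(weights: tuple[float, float]) -> float:
    """Softmax probability of the Go action, stable under weight shifts."""
    w_go, w_nogo = weights
    if not (math.isfinite(w_go) and math.isfinite(w_nogo)):
        raise ValueError(f"non-finite action weights {weights}")
    m = max(w_go, w_nogo)
    eg = math.exp(w_go - m)
    return eg / (eg + math.exp(w_nogo - m))


def effective_learning_rate(params: ParameterVector, action: str, outcome: int) -> float:
    """Learning rate for one update, with the symmetric kappa bias.

    Rewarded Go updates use a boosted rate and punished NoGo updates a
    dampened one; all other cells use the base rate eps0. The bias is applied
    in logit space on the side of eps0 closer to the range limit and mirrored
    on the other side, so the two shifts are equal in magnitude.
    """
    eps0, e_rg, e_pn = _fastlik.effective_rates(params.x_eps, params.kappa)
    if outcome == 1 and action == GO:
        return float(e_rg)
    if outcome == -1 and action == NOGO:
        return float(e_pn)
    return float(eps0)


def update_state(
    state: AgentState,
    cue: Cue,
    action: str,
    outcome: int,
    params: ParameterVector,
) -> AgentState:
    """Delta-rule update of Q(action, cue); unmutes on valenced outcomes.

    Mutates and returns ``state``. Updates run even while the cue is muted.
    """
    eps = effective_learning_rate(params, action, outcome)
    key = (cue.id, action)
    state.q[key] += eps * (params.rho * outcome - state.q[key])
    state.last_action[cue.id] = action
    if outcome != 0:
        state.muted[cue.id] = False
    return state


def _unique_cues(trials: Sequence[TrialRecord]) -> list[Cue]:
    seen: dict[int, Cue] = {}
    for t in trials:
        seen.setdefault(t.cue.id, t.cue)
    return list(seen.values())


def _kernel_args(params: ParameterVector) -> tuple[float, ...]:
    return (
        params.rho,
        params.x_eps,
        params.go_bias,
        params.pi,
        params.kappa,
        params.phi_int,
        params.phi_diff,
    )


def sequence_log_likelihood(
    trials: Sequence[TrialRecord] | TrialArrays,
    x: np.ndarray | ParameterVector,
    spec: ModelSpec | None = None,
    engine: str = "fast",
) -> float:
    """Log-likelihood of the observed response sequence under one model.

    ``trials`` must be complete and ordered as experienced. ``x`` is either a
    :class:`ParameterVector` or an unconstrained array for ``spec``.
    ``engine='reference'`` runs the step-by-step Python implementation.
    """
    params = x if isinstance(x, ParameterVector) else ParameterVector(spec, np.asarray(x))
    if engine == "fast" or isinstance(trials, TrialArrays):
        arrs = trials if isinstance(trials, TrialArrays) else trials_to_arrays(trials)
        pgo = np.empty(len(arrs.cue_idx))
        return float(
            _fastlik.loglik_pgo(
                arrs.cue_idx, arrs.cue_val, arrs.response, arrs.outcome,
                *_kernel_args(params), pgo,
            )
        )
    if engine != "reference":
        raise ValueError(f"unknown engine {engine!r}")
    state = init_state(_unique_cues(trials), params)
    ll = 0.0
    for t in trials:
        if not t.complete:
            raise ValueError("trials must have responses and outcomes set")
        p_go = choice_probability(action_weights(state, t.cue, params))
        ll += math.log(p_go if t.response == GO else 1.0 - p_go)
        update_state(state, t.cue, t.response, t.outcome, params)
    return ll


def predicted_go_probabilities(
    trials: Sequence[TrialRecord] | TrialArrays,
    params: ParameterVector,
) -> np.ndarray:
    """Pre-choice p(Go) per trial, conditioning on the observed history."""
    arrs = trials if isinstance(trials, TrialArrays) else trials_to_arrays(trials)
    pgo = np.empty(len(arrs.cue_idx))
    _fastlik.loglik_pgo(
        arrs.cue_idx, arrs.cue_val, arrs.response, arrs.outcome,
        *_kernel_args(params), pgo,
    )
    return pgo
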