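"""Model fitting and random-effects Bayesian model selection.

Three layers, mirroring the usual empirical-Bayes pipeline for trial-level
choice models:

1. :func:`map_fit` — per-subject MAP estimation in the unconstrained
   parameter space under a Gaussian prior, with multiple restarts, plus a
   Laplace approximation of the log model evidence
   ``log p(D) ~= log p(D|X*) + log p(X*) + d/2 log 2pi - 1/2 log|H|``
   with H the Hessian of the negative log posterior at the mode X*.
2. :func:`hierarchical_fit` — empirical-Bayes group fitting: alternate
   per-subject Laplace fits under the current group prior with
   moment-matching updates of the group mean and variance (which include the
   subjects' posterior variances), so each subject's estimate is shrunk
   toward, and informed by, the rest of the group.
3. :func:`joint_model_fit` — fits several candidate models at once,
   weighting each subject's contribution to a model's group update by the
   posterior probability ("responsibility") that this model generated that
   subject's data, and summarises the result with random-effects model
   selection: model frequencies, exceedance probabilities (EP), the Bayes
   omnibus risk (BOR), and the protected exceedance probability
   PXP = (1 - BOR) * EP + BOR / K.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import digamma, gammaln, logsumexp

from .models import MODELS, ModelSpec, ParameterVector, sequence_log_likelihood
from .task import TrialRecord, trials_to_arrays

_DEFAULT_PRIOR_MEAN = {
    "rho": 2.0, "eps": 0.0, "go_bias": 0.0, "pi": 0.0,
    "kappa": 0.0, "phi_int": 0.0, "phi_diff": 0.0,
}
# spreads follow the weakly-informative hyperpriors X_rho ~ N(2, 3),
# X_eps ~ N(0, 2), X_{b,pi,kappa} ~ N(0, 3); the persistence parameters,
# whose hyperpriors are not standardly printed, get N(0, 3) by analogy
_DEFAULT_PRIOR_SPREAD = {
    "rho": 3.0, "eps": 2.0, "go_bias": 3.0, "pi": 3.0,
    "kappa": 3.0, "phi_int": 3.0, "phi_diff": 3.0,
}


@dataclass(frozen=True)
class PriorSpec:
    """Independent Gaussian priors per parameter in unconstrained space.

    ``spread`` is interpreted as a variance by default; set
    ``spread_is_sd=True`` to read it as a standard deviation.
    """

    mean: Mapping[str, float]
    spread: Mapping[str, float]
    spread_is_sd: bool = False

    @classmethod
    def default(cls) -> "PriorSpec":
        return cls(mean=dict(_DEFAULT_PRIOR_MEAN), spread=dict(_DEFAULT_PRIOR_SPREAD))

    def variance(self, name: str) -> float:
        s = float(self.spread[name])
        return s * s if self.spread_is_sd else s

    def mean_vector(self, spec: ModelSpec) -> np.ndarray:
        return np.array([self.mean[n] for n in spec.active_parameters], dtype=float)

    def var_vector(self, spec: ModelSpec) -> np.ndarray:
        return np.array([self.variance(n) for n in spec.active_parameters], dtype=float)

    def logpdf(self, x: np.ndarray, spec: ModelSpec) -> float:
        mu = self.mean_vector(spec)
        var = self.var_vector(spec)
        return float(
            -0.5 * np.sum((x - mu) ** 2 / var)
            - 0.5 * np.sum(np.log(2.0 * np.pi * var))
        )

    def sample(self, spec: ModelSpec, rng: np.random.Generator) -> np.ndarray:
        mu = self.mean_vector(spec)
        sd = np.sqrt(self.var_vector(spec))
        return rng.normal(mu, sd)


@dataclass
class SubjectFit:
    """MAP estimate, curvature, and Laplace log model evidence."""

    spec: ModelSpec
    x: np.ndarray  # unconstrained MAP
    hessian: np.ndarray  # of the negative log posterior at x
    log_evidence: float
    converged: bool
    n_restarts_used: int
    log_posterior: float = float("nan")

    @property
    def posterior_cov(self) -> np.ndarray:
        return np.linalg.inv(self.hessian)

    @property
    def params(self) -> ParameterVector:
        return ParameterVector(self.spec, self.x)

    def to_dict(self) -> dict:
        return {
            "model_id": self.spec.model_id,
            "x": self.x.tolist(),
            "log_evidence": self.log_evidence,
            "converged": self.converged,
            "n_restarts_used": self.n_restarts_used,
        }


@dataclass
class GroupFit:
    """Converged group prior, per-subject fits, and the objective trace."""

    spec: ModelSpec
    prior: PriorSpec  # group-level means and variances (spread = variance)
    subject_fits: list[SubjectFit]
    trace: list[float] = field(default_factory=list)
    converged: bool = True
    n_iter: int = 0

    @property
    def group_mean(self) -> np.ndarray:
        return self.prior.mean_vector(self.spec)

    @property
    def group_variance(self) -> np.ndarray:
        return self.prior.var_vector(self.spec)

    @property
    def log_evidence(self) -> float:
        return float(sum(f.log_evidence for f in self.subject_fits))


@dataclass
class BMSResult:
    """Random-effects model-selection summary."""

    model_ids: tuple[str, ...]
    responsibilities: np.ndarray  # subjects x models, rows sum to 1
    alpha: np.ndarray  # Dirichlet posterior counts
    model_frequency: np.ndarray
    exceedance_probability: np.ndarray
    protected_exceedance_probability: np.ndarray
    bayes_omnibus_risk: float

    def to_dict(self) -> dict:
        return {
            "model_ids": list(self.model_ids),
            "model_frequency": self.model_frequency.tolist(),
            "exceedance_probability": self.exceedance_probability.tolist(),
            "protected_exceedance_probability":
                self.protected_exceedance_probability.tolist(),
            "bayes_omnibus_risk": self.bayes_omnibus_risk,
        }


# ---------------------------------------------------------------------------
# Laplace fitting


def _fd_hessian(f: Callable[[np.ndarray], float], x: np.ndarray, rel_step: float = 5e-3) -> np.ndarray:
    """Central finite-difference Hessian (exact for quadratics up to roundoff)."""
    d = len(x)
    h = rel_step * (1.0 + np.abs(x))
    H = np.empty((d, d))
    f0 = f(x)
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / (h[i] * h[i])
        for j in range(i + 1, d):
            ej = np.zeros(d)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def _regularize_spd(H: np.ndarray) -> tuple[np.ndarray, bool]:
    """Smallest power-of-ten diagonal jitter (from 1e-8) making H SPD."""
    def is_spd(a: np.ndarray) -> bool:
        try:
            np.linalg.cholesky(a)
            return True
        except np.linalg.LinAlgError:
            return False

    H = 0.5 * (H + H.T)
    if is_spd(H):
        return H, False
    jitter = 1e-8
    eye = np.eye(len(H))
    for _ in range(20):
        if is_spd(H + jitter * eye):
            return H + jitter * eye, True
        jitter *= 10.0
    raise np.linalg.LinAlgError("could not regularize Hessian to positive definite")


def laplace_fit(
    loglik: Callable[[np.ndarray], float],
    spec: ModelSpec,
    prior: PriorSpec,
    n_restarts: int = 10,
    rng: np.random.Generator | int | None = None,
    extra_inits: Sequence[np.ndarray] = (),
    tol: float = 1e-6,
) -> SubjectFit:
    """MAP + Laplace evidence for an arbitrary log-likelihood callable.

    Restart 1 starts at the prior mean, further restarts at draws from the
    prior; ``extra_inits`` (e.g. warm starts) are tried first. A fit is
    flagged ``converged=False`` if the optimizer never reported success or
    the Hessian needed jitter to become positive definite.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    mu = prior.mean_vector(spec)

    def neg_log_post(x: np.ndarray) -> float:
        ll = loglik(x)
        if not np.isfinite(ll):
            return 1e10
        return -(ll + prior.logpdf(x, spec))

    inits = [np.asarray(x0, dtype=float) for x0 in extra_inits]
    inits.append(mu.copy())
    inits.extend(prior.sample(spec, rng) for _ in range(n_restarts - 1))

    best = None
    any_success = False
    for i, x0 in enumerate(inits):
        res = minimize(
            neg_log_post, x0, method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
        )
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None

    H, jittered = _regularize_spd(_fd_hessian(neg_log_post, best.x))
    sign, logdet = np.linalg.slogdet(H)
    d = spec.n_params
    log_post = -float(best.fun)
    evidence = log_post + 0.5 * d * np.log(2.0 * np.pi) - 0.5 * logdet
    return SubjectFit(
        spec=spec,
        x=np.asarray(best.x, dtype=float),
        hessian=H,
        log_evidence=float(evidence),
        converged=bool(any_success and not jittered),
        n_restarts_used=len(inits),
        log_posterior=log_post,
    )


def _make_loglik(trials: Sequence[TrialRecord], spec: ModelSpec) -> Callable[[np.ndarray], float]:
    arrs = trials_to_arrays(trials) if trials else None

    def loglik(x: np.ndarray) -> float:
        if arrs is None:
            return 0.0
        return sequence_log_likelihood(arrs, x, spec)

    return loglik


def map_fit(
    trials: Sequence[TrialRecord],
    spec: ModelSpec,
    prior: PriorSpec | None = None,
    n_restarts: int = 10,
    rng: np.random.Generator | int | None = None,
    extra_inits: Sequence[np.ndarray] = (),
) -> SubjectFit:
    """Per-subject MAP fit with Laplace evidence on one trial sequence."""
    prior = prior or PriorSpec.default()
    return laplace_fit(
        _make_loglik(trials, spec), spec, prior,
        n_restarts=n_restarts, rng=rng, extra_inits=extra_inits,
    )


# ---------------------------------------------------------------------------
# hierarchical (empirical-Bayes) group fitting

_VARIANCE_FLOOR = 1e-6


def _weighted_group_update(
    fits: Sequence[SubjectFit], weights: np.ndarray, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Moment-matching group mean/variance from subject posteriors.

    The group variance pools the spread of the subject MAPs around the group
    mean with the subjects' own posterior variances, floored away from zero.
    """
    X = np.stack([f.x for f in fits])
    V = np.stack([np.diag(f.posterior_cov) for f in fits])
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    mu = w @ X
    var = w @ ((X - mu) ** 2 + V)
    return mu, np.maximum(var, _VARIANCE_FLOOR)


def _prior_from(spec: ModelSpec, mu: np.ndarray, var: np.ndarray) -> PriorSpec:
    names = spec.active_parameters
    return PriorSpec(
        mean=dict(zip(names, mu.tolist())),
        spread=dict(zip(names, var.tolist())),
        spread_is_sd=False,
    )


def hierarchical_fit(
    datasets: Sequence[Sequence[TrialRecord]],
    spec: ModelSpec,
    init: PriorSpec | None = None,
    tol: float = 1e-4,
    max_iter: int = 100,
    n_restarts: int = 5,
    rng: np.random.Generator | int | None = None,
    weights: np.ndarray | None = None,
    warm_starts: Sequence[np.ndarray] | None = None,
) -> GroupFit:
    """Empirical-Bayes fit: subjects constrain each other via the group prior.

    Alternates per-subject Laplace fits under the current group prior with
    moment-matching updates of the group mean and variance until the group
    mean moves less than ``tol`` (max ``max_iter`` iterations). After the
    first sweep subject fits are warm-started from their previous optimum.
    """
    if len(datasets) < 2:
        raise ValueError("hierarchical fitting needs at least 2 subjects")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    prior = init or PriorSpec.default()
    logliks = [_make_loglik(d, spec) for d in datasets]
    n = len(datasets)
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)

    fits: list[SubjectFit] = []
    trace: list[float] = []
    prev_mu = prior.mean_vector(spec)
    converged = False
    starts: list[list[np.ndarray]] = [
        [] if warm_starts is None else [np.asarray(warm_starts[i])] for i in range(n)
    ]
    it = 0
    for it in range(1, max_iter + 1):
        restarts = n_restarts if it == 1 and warm_starts is None else 1
        fits = [
            laplace_fit(
                logliks[i], spec, prior,
                n_restarts=restarts, rng=rng, extra_inits=starts[i],
            )
            for i in range(n)
        ]
        starts = [[f.x] for f in fits]
        trace.append(float(sum(f.log_evidence for f in fits)))
        mu, var = _weighted_group_update(fits, w, spec)
        prior = _prior_from(spec, mu, var)
        if np.max(np.abs(mu - prev_mu)) < tol:
            converged = True
            break
        prev_mu = mu
    if not converged:
        warnings.warn(
            f"hierarchical fit for {spec.model_id} did not converge in {max_iter} iterations",
            RuntimeWarning,
        )
    return GroupFit(
        spec=spec, prior=prior, subject_fits=fits,
        trace=trace, converged=converged, n_iter=it,
    )


# ---------------------------------------------------------------------------
# random-effects Bayesian model selection


def _dirichlet_vb(lme: np.ndarray, alpha0: float = 1.0, max_iter: int = 200, tol: float = 1e-8):
    """Variational posterior Dirichlet(alpha) and responsibilities g."""
    n, k = lme.shape
    alpha = np.full(k, alpha0, dtype=float)
    g = np.full((n, k), 1.0 / k)
    for _ in range(max_iter):
        logu = lme + digamma(alpha) - digamma(alpha.sum())
        g_new = np.exp(logu - logsumexp(logu, axis=1, keepdims=True))
        alpha_new = alpha0 + g_new.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha, g = alpha_new, g_new
            break
        alpha, g = alpha_new, g_new
    return alpha, g


def _dirichlet_kl(alpha: np.ndarray, alpha0: np.ndarray) -> float:
    asum, a0sum = alpha.sum(), alpha0.sum()
    return float(
        gammaln(asum) - gammaln(alpha).sum()
        - gammaln(a0sum) + gammaln(alpha0).sum()
        + np.sum((alpha - alpha0) * (digamma(alpha) - digamma(asum)))
    )


def _free_energy(lme: np.ndarray, alpha: np.ndarray, g: np.ndarray, alpha0: float) -> float:
    logu = lme + digamma(alpha) - digamma(alpha.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = np.where(g > 0, g * np.log(g), 0.0)
    f = float(np.sum(g * logu) - np.sum(ent))
    return f - _dirichlet_kl(alpha, np.full(len(alpha), alpha0))


def exceedance_from_alpha(
    alpha: np.ndarray, n_draws: int = 1_000_000, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Monte-Carlo exceedance probabilities of a Dirichlet posterior."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    k = len(alpha)
    counts = np.zeros(k)
    chunk = 200_000
    remaining = int(n_draws)
    while remaining > 0:
        m = min(chunk, remaining)
        draws = rng.dirichlet(alpha, size=m)
        counts += np.bincount(np.argmax(draws, axis=1), minlength=k)
        remaining -= m
    return counts / float(n_draws)


def protected_exceedance(
    log_evidence: np.ndarray,
    model_ids: Sequence[str] | None = None,
    n_draws: int = 1_000_000,
    rng: np.random.Generator | int | None = None,
    alpha0: float = 1.0,
) -> BMSResult:
    """Random-effects model selection over a subjects x models evidence matrix.

    Fits a Dirichlet model of population model frequencies, computes
    exceedance probabilities by Monte-Carlo, and protects them against the
    null hypothesis of equal frequencies via the Bayes omnibus risk:
    PXP = (1 - BOR) * EP + BOR / K.
    """
    lme = np.asarray(log_evidence, dtype=float)
    if lme.ndim != 2:
        raise ValueError("log_evidence must be a subjects x models matrix")
    if not np.all(np.isfinite(lme)):
        raise ValueError("log evidences must be finite")
    n, k = lme.shape
    ids = tuple(model_ids) if model_ids is not None else tuple(f"M{i+1}" for i in range(k))
    if k == 1:
        return BMSResult(
            model_ids=ids,
            responsibilities=np.ones((n, 1)),
            alpha=np.array([alpha0 + n]),
            model_frequency=np.array([1.0]),
            exceedance_probability=np.array([1.0]),
            protected_exceedance_probability=np.array([1.0]),
            bayes_omnibus_risk=0.0,
        )
    alpha, g = _dirichlet_vb(lme, alpha0=alpha0)
    freq = alpha / alpha.sum()
    ep = exceedance_from_alpha(alpha, n_draws=n_draws, rng=rng)
    f1 = _free_energy(lme, alpha, g, alpha0)
    # null of equal frequencies: every model equally likely for each subject
    f0 = float(np.sum(logsumexp(lme, axis=1) - np.log(k)))
    bor = float(1.0 / (1.0 + np.exp(f1 - f0)))
    pxp = (1.0 - bor) * ep + bor / k
    return BMSResult(
        model_ids=ids,
        responsibilities=g,
        alpha=alpha,
        model_frequency=freq,
        exceedance_probability=ep,
        protected_exceedance_probability=pxp,
        bayes_omnibus_risk=bor,
    )


def joint_model_fit(
    datasets: Sequence[Sequence[TrialRecord]],
    specs: Sequence[ModelSpec],
    init: PriorSpec | None = None,
    tol: float = 1e-4,
    max_iter: int = 20,
    inner_max_iter: int = 15,
    n_restarts: int = 5,
    rng: np.random.Generator | int | None = None,
    n_draws: int = 1_000_000,
) -> tuple[BMSResult, dict[str, GroupFit]]:
    """Joint hierarchical fitting of several models with model responsibilities.

    Iterates (a) responsibility updates — the posterior probability that each
    subject's data come from each model, given the current per-model group
    priors — and (b) responsibility-weighted group updates per model, until
    the responsibilities stabilise. Finishes with random-effects model
    selection on the final evidence matrix.
    """
    if len(specs) < 1:
        raise ValueError("need at least one model")
    if len(datasets) < 2:
        raise ValueError("need at least two subjects")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    ids = tuple(s.model_id for s in specs)
    n, k = len(datasets), len(specs)

    # initial pass: independent hierarchical fits per model; inner
    # non-convergence is tolerable here since the outer loop keeps refining
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        group: dict[str, GroupFit] = {
            s.model_id: hierarchical_fit(
                datasets, s, init=init, max_iter=inner_max_iter,
                n_restarts=n_restarts, rng=rng,
            )
            for s in specs
        }
    lme = _evidence_matrix(group, ids, n)
    if k == 1:
        return protected_exceedance(lme, ids, n_draws=n_draws, rng=rng), group

    g_prev = np.full((n, k), 1.0 / k)
    for _ in range(max_iter):
        alpha, g = _dirichlet_vb(lme)
        for j, s in enumerate(specs):
            gf = group[s.model_id]
            w = g[:, j] + 1e-12
            mu, var = _weighted_group_update(gf.subject_fits, w, s)
            prior = _prior_from(s, mu, var)
            fits = [
                laplace_fit(
                    _make_loglik(datasets[i], s), s, prior,
                    n_restarts=1, rng=rng, extra_inits=[gf.subject_fits[i].x],
                )
                for i in range(n)
            ]
            group[s.model_id] = GroupFit(
                spec=s, prior=prior, subject_fits=fits,
                trace=gf.trace + [float(sum(f.log_evidence for f in fits))],
                converged=gf.converged, n_iter=gf.n_iter + 1,
            )
        lme = _evidence_matrix(group, ids, n)
        if np.max(np.abs(g - g_prev)) < tol:
            g_prev = g
            break
        g_prev = g

    bms = protected_exceedance(lme, ids, n_draws=n_draws, rng=rng)
    return bms, group


def _evidence_matrix(group: Mapping[str, GroupFit], ids: Sequence[str], n: int) -> np.ndarray:
    lme = np.empty((n, len(ids)))
    for j, mid in enumerate(ids):
        col = np.array([f.log_evidence for f in group[mid].subject_fits])
        if not np.all(np.isfinite(col)):
            warnings.warn(
                f"model {mid} produced non-finite evidence; flooring", RuntimeWarning
            )
            finite = col[np.isfinite(col)]
            floor = (finite.min() if finite.size else 0.0) - 1000.0
            col = np.where(np.isfinite(col), col, floor)
        lme[:, j] = col
    return lme
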