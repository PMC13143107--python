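"""Numba kernel for the trial-sequence likelihood.

One compiled pass over a session: evolves per-cue Q-values, muting flags and
last-action memory, and accumulates the log-likelihood of the observed
responses. Also writes the pre-choice p(Go) per trial, which doubles as the
one-step-ahead posterior predictive probability.

The kernel takes the seven model quantities in a fixed layout; inactive
parameters of nested models are passed as 0, which reduces the computation
exactly to the simpler model.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def effective_rates(x_eps, kappa):
    """(eps0, eps_rewarded_go, eps_punished_nogo) with the symmetric kappa bias.

    The learning bias is applied in the unconstrained (logit) space on the
    side of the base rate closer to the range limit; the other side mirrors
    the resulting difference so the bias is symmetric around eps0.
    """
    eps0 = 1.0 / (1.0 + np.exp(-x_eps))
    if kappa == 0.0:
        return eps0, eps0, eps0
    if eps0 <= 0.5:
        e_pn = 1.0 / (1.0 + np.exp(-(x_eps - kappa)))
        e_rg = eps0 + (eps0 - e_pn)
    else:
        e_rg = 1.0 / (1.0 + np.exp(-(x_eps + kappa)))
        e_pn = eps0 - (e_rg - eps0)
    e_rg = min(max(e_rg, 0.0), 1.0)
    e_pn = min(max(e_pn, 0.0), 1.0)
    return eps0, e_rg, e_pn


@njit(cache=True)
def loglik_pgo(
    cue_idx,
    cue_val,
    response,
    outcome,
    rho,
    x_eps,
    go_bias,
    pi_bias,
    kappa,
    phi_int,
    phi_diff,
    pgo_out,
):
    """Sequence log-likelihood; fills pgo_out with pre-choice p(Go) per trial."""
    n_cues = cue_val.shape[0]
    q_go = np.empty(n_cues)
    q_nogo = np.empty(n_cues)
    muted = np.empty(n_cues, dtype=np.bool_)
    last = np.empty(n_cues, dtype=np.int8)
    for c in range(n_cues):
        q0 = cue_val[c] * rho
        q_go[c] = q0
        q_nogo[c] = q0
        muted[c] = True
        last[c] = -1

    eps0, e_rg, e_pn = effective_rates(x_eps, kappa)

    ll = 0.0
    for t in range(cue_idx.shape[0]):
        c = cue_idx[t]
        v = cue_val[c]
        w_go = go_bias
        w_nogo = 0.0
        if not muted[c]:
            w_go += q_go[c] + pi_bias * v
            w_nogo += q_nogo[c]
        if last[c] == 1:
            w_go += phi_int + (phi_diff if v > 0.0 else -phi_diff)
        elif last[c] == 0:
            w_nogo += phi_int + (phi_diff if v > 0.0 else -phi_diff)
        m = w_go if w_go > w_nogo else w_nogo
        eg = np.exp(w_go - m)
        en = np.exp(w_nogo - m)
        p_go = eg / (eg + en)
        pgo_out[t] = p_go

        a = response[t]
        r = outcome[t]
        ll += np.log(p_go if a == 1 else 1.0 - p_go)

        if r == 1.0 and a == 1:
            eps = e_rg
        elif r == -1.0 and a == 0:
            eps = e_pn
        else:
            eps = eps0
        if a == 1:
            q_go[c] += eps * (rho * r - q_go[c])
        else:
            q_nogo[c] += eps * (rho * r - q_nogo[c])
        last[c] = a
        if r != 0.0:
            muted[c] = False
    return ll
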