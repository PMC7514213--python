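"""Information-theoretic measures of the fitness value of sensing.

Quantities computed here, all by exhaustive path enumeration at small
horizons (Monte-Carlo estimation lives in :mod:`sensegain.fluctuation`):

* ``G``: fitness gain of individual over common sensing; the KL divergence
  between the forward signal-history measure PS[Zt||Yt] Q[Yt] and the
  selection-biased retrospective measure PBi[Zt|Yt] Q[Yt].  Equals
  <Psi_i> - <Psi_c> when the common signal follows the same law PS.
* ``sigma[Yt]`` and ``gamma_t``: pathwise and total fidelity of the
  sensing -> switching -> allocation cascade, via the correct-allocation
  probability PKFS[Yt|Yt].
* Bayesian causal decomposition of the joint (environment, signal) law into a
  signal-predictive kernel and an environment posterior, the pointwise and
  average directed information I(Z -> Y), and the implementation loss Dloss.

Directed information here runs from signal to environment (the environment is
*inferred* from the signal path), the reverse of the more common
environment-to-signal direction.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import logsumexp

from .errors import UnsupportedModelError
from .histories import DEFAULT_GUARD, enumerate_histories, enumerate_index_paths
from .models import ModelBundle
from .paths import (
    _dp_common,
    _dp_individual,
    _log,
    _lse,
    env_indices,
    env_logprob_batch,
    fitness_common_batch,
    fitness_individual_batch,
    kmax_fitness_batch,
    sensing_logprob_batch,
    signal_indices,
)

# ---------------------------------------------------------------------------
# fitness gain G
# ---------------------------------------------------------------------------

def _joint_forward(model: ModelBundle, t: int, guard: int):
    """Enumerate (Yt, Zt) pairs with log forward weights ln Q + ln PS."""
    Ys = enumerate_index_paths(model.spaces.ny, t, guard=guard)
    Zs = enumerate_index_paths(model.spaces.nz, t, guard=guard)
    mY, mZ = Ys.shape[0], Zs.shape[0]
    if mY * mZ > guard:
        from .errors import EnumerationLimitError

        raise EnumerationLimitError(
            f"{mY} x {mZ} joint histories exceed the guard of {guard}"
        )
    Yrep = np.repeat(Ys, mZ, axis=0)
    Zrep = np.tile(Zs, (mY, 1))
    logQ = env_logprob_batch(model.env, Yrep)
    logPS = sensing_logprob_batch(model.sensing, Zrep, Yrep)
    return Ys, Zs, Yrep, Zrep, logQ, logPS


def fitness_gain_G(model: ModelBundle, t: int, guard: int = DEFAULT_GUARD) -> float:
    """Average fitness gain of individual over common sensing at horizon t.

    G = <Psi_i>_Q - <Psi_c>_{Q PS}, the KL divergence between the forward and
    retrospective signal-history measures; non-negative.
    """
    _, _, Yrep, Zrep, logQ, logPS = _joint_forward(model, t, guard)
    logw = logQ + logPS
    mask = logw > -np.inf
    psi_i = fitness_individual_batch(model, Yrep[mask])
    psi_c = fitness_common_batch(model, Yrep[mask], Zrep[mask])
    return float(np.sum(np.exp(logw[mask]) * (psi_i - psi_c)))


# ---------------------------------------------------------------------------
# fidelity: PKFS, sigma, gamma
# ---------------------------------------------------------------------------

def pkfs_log_batch(model: ModelBundle, Yalloc: np.ndarray, Yactual: np.ndarray) -> np.ndarray:
    """ln PKFS[Y'|Y] = ln sum_{Xt,Zt} PK[Y'||Xt] PF[Xt||Zt] PS[Zt||Y].

    Computed by the joint (x, z) transfer-matrix recursion with per-step
    weight TK(y'_alloc | x') and sensing driven by the actual history.

    Nothing is allocated at time 0 (the allocation path product starts at the
    first transition), so the time-0 slot of the allocation history is pinned
    to the realized initial state: histories differing there get probability
    zero.  This makes PKFS a normalized distribution over allocation
    histories and leaves the diagonal PKFS[Yt|Yt] untouched.
    """
    decomp = model.require_decomposition()
    logTK = _log(decomp.allocation)  # (x, y)
    Yalloc = np.asarray(Yalloc, dtype=np.intp)
    Yactual = np.asarray(Yactual, dtype=np.intp)
    if Yalloc.shape != Yactual.shape:
        raise ValueError("allocation and actual histories must share horizon and batch shape")
    out = _dp_individual(model, Yalloc, Yactual, logTK)
    return np.where(Yalloc[:, 0] == Yactual[:, 0], out, -np.inf)


def pkfs(model: ModelBundle, Yt_alloc, Yt_actual) -> float:
    """Probability that resources follow allocation history Yt_alloc under Yt_actual."""
    Ya = env_indices(model, Yt_alloc)
    Yb = env_indices(model, Yt_actual)
    return float(np.exp(pkfs_log_batch(model, Ya, Yb)[0]))


def sigma_of_history(model: ModelBundle, Yt) -> float:
    """Pathwise fidelity gain sigma[Yt] = ln(PKFS[Yt|Yt] / Q[Yt]).

    Satisfies Psi_i[Yt] = Kmax[Yt] + ln PKFS[Yt|Yt] = Psi_0[Yt] + sigma[Yt]
    with Psi_0 = Kmax + ln Q.
    """
    Y = env_indices(model, Yt)
    logQ = env_logprob_batch(model.env, Y)[0]
    if np.isneginf(logQ):
        raise ValueError("sigma is undefined on a zero-probability environment history")
    return float(pkfs_log_batch(model, Y, Y)[0] - logQ)


def gamma_total(model: ModelBundle, t: int) -> float:
    """Total fidelity gamma_t = ln sum_{Yt} PKFS[Yt|Yt], exactly, for any t.

    The diagonal sum is linear in the path weights, so it collapses to a joint
    (x, z) transfer matrix in which the matched environment state of each step
    is summed out on the spot; cost is O(t) with no history enumeration.
    """
    decomp = model.require_decomposition()
    logTK = _log(decomp.allocation)  # (x', y')
    logTS = _log(model.sensing.kernel)  # (z, y', z')
    logTF = _log(model.switching.kernel)  # (x, z', x')
    logpS0 = _log(model.sensing.initial)  # (y0, z0)
    logpF0 = _log(model.switching.initial)  # (z0, x0)

    # V[x, z] = sum over y0 of pS(z|y0) pF(x|z); later steps fold the matched
    # environment state in as it appears (in TK and TS only).
    V = _lse(logpS0[:, None, :] + logpF0.T[None, :, :], axis=0)  # (x, z)

    # inner[z, x', z'] = lse_{y'}( logTK[x', y'] + logTS[z, y', z'] )
    tsT = logTS.transpose(0, 2, 1)  # (z, z', y')
    inner = _lse(tsT[:, None, :, :] + logTK[None, :, None, :], axis=3)  # (z, x', z')
    # M[x, z, x', z'] = inner[z, x', z'] + logTF[x, z', x']
    M = inner[None, :, :, :] + logTF.transpose(0, 2, 1)[:, None, :, :]

    for _ in range(t):
        V = _lse((V[:, :, None, None] + M).reshape(-1, *M.shape[2:]), axis=0)
    return float(_lse(V.reshape(-1), axis=0))


@dataclass
class FidelityReport:
    """Per-history fidelity gains and the total-fidelity decomposition."""

    histories: list
    sigma_by_history: dict
    gamma_total: float
    p_gamma: np.ndarray
    kl_env_pgamma: float
    horizon: int


def gamma_and_pgamma(model: ModelBundle, t: int, guard: int = DEFAULT_GUARD) -> FidelityReport:
    """Enumerate sigma[Yt], gamma_t, the tilted measure P_gamma, and D[Q||P_gamma].

    P_gamma[Yt] = e^{-gamma_t} PKFS[Yt|Yt] is a normalized path measure and
    <sigma>_Q = gamma_t - D[Q || P_gamma].
    """
    model.require_decomposition()
    Ys = enumerate_index_paths(model.spaces.ny, t, guard=guard)
    log_diag = pkfs_log_batch(model, Ys, Ys)
    logQ = env_logprob_batch(model.env, Ys)
    gamma = float(logsumexp(log_diag))
    log_pgamma = log_diag - gamma
    hists = enumerate_histories(model.spaces.environments, t, guard=guard)
    support = logQ > -np.inf
    sigma = np.where(support, log_diag - logQ, np.nan)
    kl = float(np.sum(np.exp(logQ[support]) * (logQ[support] - log_pgamma[support])))
    return FidelityReport(
        histories=hists,
        sigma_by_history={h.labels: float(s) for h, s in zip(hists, sigma)},
        gamma_total=gamma,
        p_gamma=np.exp(log_pgamma),
        kl_env_pgamma=kl,
        horizon=t,
    )


# ---------------------------------------------------------------------------
# Bayesian causal decomposition and directed information
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BayesKernels:
    """Bayes-inverted kernels of the joint (environment, signal) forward law.

    ``signal_predictive[y, z']``: probability of next signal z' given current
    environment y, with the next environment summed out.
    ``env_posterior[y, z', y']``: Bayesian posterior of the next environment
    y' given the sensed signal z' and the current environment y.
    ``signal_marginal[z0]`` and ``env_posterior0[z0, y0]`` play the same roles
    at time zero, built from the initial laws pS and pE.

    Rows of the posterior tables are normalized wherever the corresponding
    predictive probability is positive; elsewhere they are identically zero.
    """

    signal_predictive: np.ndarray
    env_posterior: np.ndarray
    signal_marginal: np.ndarray
    env_posterior0: np.ndarray


def bayes_kernels(model: ModelBundle) -> BayesKernels:
    """Invert the causal order y -> z of the forward law by Bayes' theorem.

    Requires a Markov environment and memoryless sensing.  Satisfies the
    reconstruction identity  TS(z'|y') TEF(y'|y) =
    signal_predictive(z'|y) * env_posterior(y'|z', y)  for every triple.
    """
    if not model.sensing.memoryless:
        raise UnsupportedModelError(
            "the Bayesian causal decomposition requires memoryless sensing"
        )
    TS = model.sensing.memoryless_kernel  # (y', z')
    TEF = model.env.transition  # (y, y')
    pred = TEF @ TS  # (y, z'): sum_y' TS(z'|y') TEF(y'|y)
    joint = TEF[:, :, None] * TS[None, :, :]  # (y, y', z')
    with np.errstate(divide="ignore", invalid="ignore"):
        post = joint.transpose(0, 2, 1) / pred[:, :, None]  # (y, z', y')
    post = np.where(pred[:, :, None] > 0, post, 0.0)

    pE = model.env.initial
    pS0 = model.sensing.initial  # (y0, z0)
    pz0 = pE @ pS0  # (z0,)
    joint0 = pE[:, None] * pS0  # (y0, z0)
    with np.errstate(divide="ignore", invalid="ignore"):
        post0 = joint0.T / pz0[:, None]  # (z0, y0)
    post0 = np.where(pz0[:, None] > 0, post0, 0.0)
    return BayesKernels(
        signal_predictive=pred,
        env_posterior=post,
        signal_marginal=pz0,
        env_posterior0=post0,
    )


def psb_env_logprob_batch(bk: BayesKernels, Y: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """ln PSB[Yt || Zt]: product of environment posteriors along the paths."""
    Y = np.asarray(Y, dtype=np.intp)
    Z = np.asarray(Z, dtype=np.intp)
    out = _log(bk.env_posterior0)[Z[:, 0], Y[:, 0]]
    if Y.shape[1] > 1:
        steps = _log(bk.env_posterior)[Y[:, :-1], Z[:, 1:], Y[:, 1:]]
        out = out + steps.sum(axis=1)
    return out


def psb_signal_logprob_batch(bk: BayesKernels, Z: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """ln PSB[Zt || Yt-1]: signal-predictive product (conditions on the *previous* y)."""
    Y = np.asarray(Y, dtype=np.intp)
    Z = np.asarray(Z, dtype=np.intp)
    out = _log(bk.signal_marginal)[Z[:, 0]]
    if Y.shape[1] > 1:
        steps = _log(bk.signal_predictive)[Y[:, :-1], Z[:, 1:]]
        out = out + steps.sum(axis=1)
    return out


def pointwise_directed_info(model: ModelBundle, Zt, Yt, bk: Optional[BayesKernels] = None) -> float:
    """i[Zt -> Yt] = ln PSB[Yt || Zt] - ln Q[Yt]."""
    if bk is None:
        bk = bayes_kernels(model)
    Y = env_indices(model, Yt)
    Z = signal_indices(model, Zt)
    logQ = env_logprob_batch(model.env, Y)[0]
    if np.isneginf(logQ):
        raise ValueError("pointwise directed information undefined on zero-probability Yt")
    return float(psb_env_logprob_batch(bk, Y, Z)[0] - logQ)


def directed_information(model: ModelBundle, t: int, guard: int = DEFAULT_GUARD) -> float:
    """I(Zt -> Yt): average pointwise directed information under the forward law."""
    bk = bayes_kernels(model)
    _, _, Yrep, Zrep, logQ, logPS = _joint_forward(model, t, guard)
    logw = logQ + logPS
    mask = logw > -np.inf
    i_pt = psb_env_logprob_batch(bk, Yrep[mask], Zrep[mask]) - logQ[mask]
    return float(np.sum(np.exp(logw[mask]) * i_pt))


def pkf_log_batch(model: ModelBundle, Y: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """ln PK,F[Yt|Zt] = ln sum_Xt PK[Yt||Xt] PF[Xt||Zt] (allocation-through-switching)."""
    decomp = model.require_decomposition()
    return _dp_common(model, np.asarray(Y, dtype=np.intp), np.asarray(Z, dtype=np.intp),
                      _log(decomp.allocation))


def dloss(model: ModelBundle, t: int, guard: int = DEFAULT_GUARD) -> float:
    """Implementation loss of sequential Bayesian inference.

    Dloss = D[ PS[Yt,Zt] || PK,F[Yt|Zt] PSB[Zt||Yt-1] ]; zero exactly when
    switching and allocation jointly realize the Bayesian posterior.  Returns
    +inf if the forward law puts mass where the reference measure has none.
    """
    bk = bayes_kernels(model)
    _, _, Yrep, Zrep, logQ, logPS = _joint_forward(model, t, guard)
    logw = logQ + logPS
    mask = logw > -np.inf
    log_ref = pkf_log_batch(model, Yrep[mask], Zrep[mask]) + psb_signal_logprob_batch(
        bk, Zrep[mask], Yrep[mask]
    )
    if np.any(np.isneginf(log_ref)):
        return float("inf")
    return float(np.sum(np.exp(logw[mask]) * (logw[mask] - log_ref)))


# ---------------------------------------------------------------------------
# average fitness summaries
# ---------------------------------------------------------------------------

def average_fitness(model: ModelBundle, t: int, guard: int = DEFAULT_GUARD) -> dict:
    """Exhaustive averages <Psi_i>, <Psi_c>, and (with a decomposition) <Psi_0>.

    <Psi_i> averages over Q[Yt]; <Psi_c> over the joint Q[Yt] PS[Zt||Yt];
    Psi_0[Yt] = Kmax[Yt] + ln Q[Yt] is the no-sensing fitness bound.
    """
    Ys = enumerate_index_paths(model.spaces.ny, t, guard=guard)
    logQ = env_logprob_batch(model.env, Ys)
    wY = np.exp(logQ)
    maskY = wY > 0
    psi_i = fitness_individual_batch(model, Ys[maskY])
    out = {"psi_i": float(np.sum(wY[maskY] * psi_i))}

    _, _, Yrep, Zrep, logQj, logPS = _joint_forward(model, t, guard)
    logw = logQj + logPS
    maskJ = logw > -np.inf
    psi_c = fitness_common_batch(model, Yrep[maskJ], Zrep[maskJ])
    out["psi_c"] = float(np.sum(np.exp(logw[maskJ]) * psi_c))

    if model.decomposition is not None:
        kmaxY = kmax_fitness_batch(model.decomposition, Ys)
        out["psi_0"] = float(np.sum(wY[maskY] * (kmaxY[maskY] + logQ[maskY])))
    return out


def measures_table(model: ModelBundle, t_max: int, guard: int = DEFAULT_GUARD) -> list:
    """Rows (t, psi_i_avg, psi_c_avg, psi0_avg, G, I_directed, Dloss, gamma, kl_q_pgamma)."""
    rows = []
    for t in range(1, t_max + 1):
        avg = average_fitness(model, t, guard=guard)
        G = avg["psi_i"] - avg["psi_c"]
        memoryless = model.sensing.memoryless
        I = directed_information(model, t, guard=guard) if memoryless else float("nan")
        has_decomp = model.decomposition is not None and memoryless
        dl = dloss(model, t, guard=guard) if has_decomp else float("nan")
        has_decomp = model.decomposition is not None
        if has_decomp:
            rep = gamma_and_pgamma(model, t, guard=guard)
            gamma, kl = rep.gamma_total, rep.kl_env_pgamma
        else:
            gamma, kl = float("nan"), float("nan")
        rows.append(
            (
                t,
                avg["psi_i"],
                avg["psi_c"],
                avg.get("psi_0", float("nan")),
                G,
                I,
                dl,
                gamma,
                kl,
            )
        )
    return rows
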