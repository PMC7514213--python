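"""Exact path-space computations.

Path probabilities use Kramer's causal conditioning: each step factor
conditions only on past-and-present states of the conditioning history.  The
per-step causal order is y_{tau+1} -> z_{tau+1} -> x_{tau+1} -> replication by
e^{k(x_{tau+1}, y_{tau+1})}; no replication occurs at tau = 0.

Population fitnesses are computed by transfer-matrix dynamic programming on
log-abundance tables (individual sensing: joint (x, z) table; common sensing:
x table), which equals the exhaustive path sums

    Psi_i[Yt] = ln < e^{K[Xt,Yt]} >_{PF PS}   (sum over Xt, Zt)
    Psi_c[Yt,Zt] = ln < e^{K[Xt,Yt]} >_{PF}   (sum over Xt)

All weights are carried in the log domain with -inf for zero probability.
"""
from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from .histories import (
    DEFAULT_GUARD,
    History,
    PathEnsemble,
    as_indices,
    enumerate_histories,
    enumerate_index_paths,
)
from .models import (
    AllocationDecomposition,
    EnvironmentModel,
    ModelBundle,
    ReplicationModel,
    SensingModel,
    SwitchingModel,
)

NEG_INF = -np.inf


def _log(table: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(table)


def _lse(a: np.ndarray, axis: int) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        out = logsumexp(a, axis=axis)
    return np.where(np.isnan(out), NEG_INF, out)


def _as_paths(arr, n_states: int) -> np.ndarray:
    """Validate a (B, t+1) batch of index paths."""
    arr = np.asarray(arr, dtype=np.intp)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.size and (arr.min() < 0 or arr.max() >= n_states):
        raise ValueError("state index out of range")
    return arr


# ---------------------------------------------------------------------------
# log path probabilities
# ---------------------------------------------------------------------------

def env_logprob_batch(env: EnvironmentModel, Y: np.ndarray) -> np.ndarray:
    """ln Q[Yt] for a (B, t+1) batch of environment index paths."""
    Y = _as_paths(Y, env.transition.shape[0])
    logT, logp0 = _log(env.transition), _log(env.initial)
    out = logp0[Y[:, 0]]
    if Y.shape[1] > 1:
        out = out + _log_steps_sum(logT[Y[:, :-1], Y[:, 1:]])
    return out


def _log_steps_sum(step_logs: np.ndarray) -> np.ndarray:
    # sum of per-step logs; -inf propagates cleanly
    with np.errstate(invalid="ignore"):
        return step_logs.sum(axis=1)


def sensing_logprob_batch(sensing: SensingModel, Z: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """ln PS[Zt || Yt]: product of TS(z_{tau+1}|z_tau, y_{tau+1}) pS(z0|y0)."""
    nz = sensing.kernel.shape[0]
    Z = _as_paths(Z, nz)
    Y = _as_paths(Y, sensing.kernel.shape[1])
    if Z.shape != Y.shape:
        raise ValueError("signal and environment paths must share horizon and batch shape")
    logK, logp0 = _log(sensing.kernel), _log(sensing.initial)
    out = logp0[Y[:, 0], Z[:, 0]]
    if Z.shape[1] > 1:
        out = out + _log_steps_sum(logK[Z[:, :-1], Y[:, 1:], Z[:, 1:]])
    return out


def switching_logprob_batch(switching: SwitchingModel, X: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """ln PF[Xt || Zt]: product of TF(x_{tau+1}|x_tau, z_{tau+1}) pF(x0|z0)."""
    nx = switching.kernel.shape[0]
    X = _as_paths(X, nx)
    Z = _as_paths(Z, switching.kernel.shape[1])
    if X.shape != Z.shape:
        raise ValueError("phenotype and signal paths must share horizon and batch shape")
    logK, logp0 = _log(switching.kernel), _log(switching.initial)
    out = logp0[Z[:, 0], X[:, 0]]
    if X.shape[1] > 1:
        out = out + _log_steps_sum(logK[X[:, :-1], Z[:, 1:], X[:, 1:]])
    return out


def historical_fitness_batch(
    replication: ReplicationModel, X: np.ndarray, Y: np.ndarray
) -> np.ndarray:
    """K[Xt,Yt] = sum_{tau=0..t-1} k(x_{tau+1}, y_{tau+1}); the step-0 pair is free."""
    X = _as_paths(X, replication.lograte.shape[0])
    Y = _as_paths(Y, replication.lograte.shape[1])
    if X.shape != Y.shape:
        raise ValueError("phenotype and environment paths must share horizon and batch shape")
    if X.shape[1] == 1:
        return np.zeros(X.shape[0])
    return _log_steps_sum(replication.lograte[X[:, 1:], Y[:, 1:]])


def allocation_logprob_batch(
    decomp: AllocationDecomposition, Yalloc: np.ndarray, X: np.ndarray
) -> np.ndarray:
    """ln PK[Yt || Xt] = sum_{tau=0..t-1} ln TK(y_{tau+1}|x_{tau+1})."""
    X = _as_paths(X, decomp.allocation.shape[0])
    Yalloc = _as_paths(Yalloc, decomp.allocation.shape[1])
    if X.shape != Yalloc.shape:
        raise ValueError("paths must share horizon and batch shape")
    if X.shape[1] == 1:
        return np.zeros(X.shape[0])
    return _log_steps_sum(_log(decomp.allocation)[X[:, 1:], Yalloc[:, 1:]])


def kmax_fitness_batch(decomp: AllocationDecomposition, Y: np.ndarray) -> np.ndarray:
    """Kmax[Yt] = sum_{tau=1..t} kmax(y_tau)."""
    Y = _as_paths(Y, decomp.kmax.shape[0])
    return decomp.kmax[Y[:, 1:]].sum(axis=1) if Y.shape[1] > 1 else np.zeros(Y.shape[0])


# single-history conveniences -------------------------------------------------

def env_logprob(env: EnvironmentModel, Yt, environments: Optional[Sequence[str]] = None) -> float:
    return float(env_logprob_batch(env, _idx(Yt, environments))[0])


def sensing_logprob(sensing: SensingModel, Zt, Yt, spaces=None) -> float:
    Z = _idx(Zt, spaces.signals if spaces else None)
    Y = _idx(Yt, spaces.environments if spaces else None)
    return float(sensing_logprob_batch(sensing, Z, Y)[0])


def switching_logprob(switching: SwitchingModel, Xt, Zt, spaces=None) -> float:
    X = _idx(Xt, spaces.phenotypes if spaces else None)
    Z = _idx(Zt, spaces.signals if spaces else None)
    return float(switching_logprob_batch(switching, X, Z)[0])


def historical_fitness(replication: ReplicationModel, Xt, Yt, spaces=None) -> float:
    X = _idx(Xt, spaces.phenotypes if spaces else None)
    Y = _idx(Yt, spaces.environments if spaces else None)
    return float(historical_fitness_batch(replication, X, Y)[0])


def kmax_fitness(decomp: AllocationDecomposition, Yt, environments=None) -> float:
    return float(kmax_fitness_batch(decomp, _idx(Yt, environments))[0])


def _idx(seq, alphabet) -> np.ndarray:
    """History | label sequence | int sequence/array -> (1+, t+1) index array."""
    if isinstance(seq, History):
        return seq.indices[None, :]
    if isinstance(seq, np.ndarray):
        return seq.astype(np.intp) if seq.ndim == 2 else seq.astype(np.intp)[None, :]
    seq = list(seq)
    if seq and isinstance(seq[0], str):
        if alphabet is None:
            raise ValueError("label sequences need the alphabet; pass a History instead")
        return as_indices(seq, alphabet)[None, :]
    return np.asarray(seq, dtype=np.intp)[None, :]


def env_indices(model: ModelBundle, Yt) -> np.ndarray:
    return _idx(Yt, model.spaces.environments)


def signal_indices(model: ModelBundle, Zt) -> np.ndarray:
    return _idx(Zt, model.spaces.signals)


def phenotype_indices(model: ModelBundle, Xt) -> np.ndarray:
    return _idx(Xt, model.spaces.phenotypes)


# ---------------------------------------------------------------------------
# transfer-matrix dynamic programming
# ---------------------------------------------------------------------------

def _dp_individual(
    model: ModelBundle,
    Ygrow: np.ndarray,
    Ysense: np.ndarray,
    growth: np.ndarray,
    return_series: bool = False,
    return_table: bool = False,
):
    """Joint (x, z) log-abundance recursion, batched over paths.

    N'(x', z') = G(x', ygrow') * sum_{x,z} TF(x'|x,z') TS(z'|z, ysense') N(x,z)

    with per-step log growth ``growth[x', ygrow']`` (the log replication rate
    for fitness, ln TK for allocation-probability computations).  Returns the
    per-path log total at the final step (and per-step series / final table on
    request).  The initial table N0(x, z) = pS(z|y0) pF(x|z) is normalized, so
    the log total at horizon t is the fitness directly.
    """
    logTS = _log(model.sensing.kernel)  # (z, y', z')
    logTF = _log(model.switching.kernel)  # (x, z', x')
    logpS0 = _log(model.sensing.initial)  # (y, z)
    logpF0 = _log(model.switching.initial)  # (z, x)
    B, steps = Ygrow.shape[0], Ygrow.shape[1] - 1

    # logN[b, x, z]
    logN = (logpS0[Ysense[:, 0]][:, None, :] + logpF0.T[None, :, :])
    series = [_lse(logN.reshape(B, -1), axis=1)]
    for tau in range(steps):
        yg = Ygrow[:, tau + 1]
        ys = Ysense[:, tau + 1]
        # sum over previous z
        ts = logTS[:, ys, :].transpose(1, 0, 2)  # (B, z_prev, z')
        tmp = _lse(logN[:, :, :, None] + ts[:, None, :, :], axis=2)  # (B, x_prev, z')
        # sum over previous x
        tmp = _lse(tmp[:, :, :, None] + logTF[None, :, :, :], axis=1)  # (B, z', x')
        logN = tmp.transpose(0, 2, 1) + growth[:, yg].T[:, :, None]  # (B, x', z')
        series.append(_lse(logN.reshape(B, -1), axis=1))
    out = series[-1]
    extras = []
    if return_series:
        extras.append(np.stack(series, axis=1))
    if return_table:
        extras.append(logN)
    return (out, *extras) if extras else out


def _dp_common(
    model: ModelBundle,
    Ygrow: np.ndarray,
    Z: np.ndarray,
    growth: np.ndarray,
    return_series: bool = False,
    return_table: bool = False,
):
    """Phenotype-only log-abundance recursion given a realized signal path.

    N'(x') = G(x', ygrow') * sum_x TF(x'|x, z') N(x);  N0(x) = pF(x|z0).
    """
    logTF = _log(model.switching.kernel)
    logpF0 = _log(model.switching.initial)
    B, steps = Ygrow.shape[0], Ygrow.shape[1] - 1

    logN = logpF0[Z[:, 0]]  # (B, x)
    series = [_lse(logN, axis=1)]
    for tau in range(steps):
        yg = Ygrow[:, tau + 1]
        z = Z[:, tau + 1]
        tf = logTF[:, z, :].transpose(1, 0, 2)  # (B, x_prev, x')
        logN = _lse(logN[:, :, None] + tf, axis=1) + growth[:, yg].T
        series.append(_lse(logN, axis=1))
    out = series[-1]
    extras = []
    if return_series:
        extras.append(np.stack(series, axis=1))
    if return_table:
        extras.append(logN)
    return (out, *extras) if extras else out


def fitness_individual_batch(model: ModelBundle, Y: np.ndarray, **kw):
    """Psi_i[Yt] for a (B, t+1) batch of environment index paths."""
    Y = _as_paths(Y, model.spaces.ny)
    return _dp_individual(model, Y, Y, model.replication.lograte, **kw)


def fitness_common_batch(model: ModelBundle, Y: np.ndarray, Z: np.ndarray, **kw):
    """Psi_c[Yt, Zt] for batches of environment and signal index paths."""
    Y = _as_paths(Y, model.spaces.ny)
    Z = _as_paths(Z, model.spaces.nz)
    if Y.shape != Z.shape:
        raise ValueError("environment and signal paths must share horizon and batch shape")
    return _dp_common(model, Y, Z, model.replication.lograte, **kw)


def fitness_individual(model: ModelBundle, Yt) -> float:
    """Population fitness with individual sensing for one environment history."""
    return float(fitness_individual_batch(model, env_indices(model, Yt))[0])


def fitness_common(model: ModelBundle, Yt, Zt) -> float:
    """Population fitness with common sensing for one (environment, signal) pair."""
    return float(
        fitness_common_batch(model, env_indices(model, Yt), signal_indices(model, Zt))[0]
    )


# ---------------------------------------------------------------------------
# retrospective (selection-biased) path distributions
# ---------------------------------------------------------------------------

def retrospective_sensing_dist(
    model: ModelBundle, Yt, guard: int = DEFAULT_GUARD
) -> PathEnsemble:
    """PBi[Zt | Yt]: signal-history law of the grown population, traced backward.

    PBi[Zt|Yt] = sum_Xt e^{K - Psi_i} PF[Xt||Zt] PS[Zt||Yt]; computed per
    signal history by the phenotype DP (the inner sum over Xt) and normalized
    by Psi_i from the joint DP.
    """
    Y = env_indices(model, Yt)
    t = Y.shape[1] - 1
    Zs = enumerate_index_paths(model.spaces.nz, t, guard=guard)
    m = Zs.shape[0]
    Yrep = np.repeat(Y, m, axis=0)
    log_inner = _dp_common(model, Yrep, Zs, model.replication.lograte)  # ln sum_Xt e^K PF
    logPS = sensing_logprob_batch(model.sensing, Zs, Yrep)
    psi_i = fitness_individual_batch(model, Y)[0]
    logw = log_inner + logPS - psi_i
    hists = enumerate_histories(model.spaces.signals, t, guard=guard)
    return PathEnsemble(histories=hists, log_weights=logw, kind="exhaustive", horizon=t)


def retrospective_phenotype_dist(
    model: ModelBundle, Yt, Zt, guard: int = DEFAULT_GUARD
) -> PathEnsemble:
    """PBc[Xt | Yt, Zt] = e^{K - Psi_c} PF[Xt||Zt], over all phenotype histories."""
    Y = env_indices(model, Yt)
    Z = signal_indices(model, Zt)
    if Y.shape != Z.shape:
        raise ValueError("environment and signal histories must share the horizon")
    t = Y.shape[1] - 1
    Xs = enumerate_index_paths(model.spaces.nx, t, guard=guard)
    m = Xs.shape[0]
    Yrep, Zrep = np.repeat(Y, m, axis=0), np.repeat(Z, m, axis=0)
    K = historical_fitness_batch(model.replication, Xs, Yrep)
    logPF = switching_logprob_batch(model.switching, Xs, Zrep)
    psi_c = fitness_common_batch(model, Y, Z)[0]
    with np.errstate(invalid="ignore"):
        logw = np.where(np.isneginf(logPF), NEG_INF, K + logPF - psi_c)
    hists = enumerate_histories(model.spaces.phenotypes, t, guard=guard)
    return PathEnsemble(histories=hists, log_weights=logw, kind="exhaustive", horizon=t)
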