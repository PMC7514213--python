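"""Sampled environment/signal realizations and population time series.

The population recursions are deterministic given the realized environment
history (and, for common sensing, the realized shared signal history); only
the environment and the signal are random.  Initial total abundance is
normalized to 1, so the log total abundance at time t *is* the fitness.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .histories import History
from .models import ModelBundle
from .paths import (
    _log,
    _lse,
    env_indices,
    env_logprob_batch,
    fitness_common_batch,
    fitness_individual_batch,
    signal_indices,
)


def _rng(seed) -> np.random.Generator:
    """Counter-based generator: per-sample rows of one uniform block are
    independent streams, reproducible regardless of how samples are consumed."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.Generator(np.random.Philox(int(seed)))


def _categorical_rows(cum_rows: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Inverse-CDF draw per sample given per-sample cumulative rows."""
    idx = (u[:, None] >= cum_rows).sum(axis=1)
    return np.minimum(idx, cum_rows.shape[1] - 1)


def sample_paths(
    model: ModelBundle, t: int, n: int, seed
) -> Tuple[np.ndarray, np.ndarray]:
    """Draw n (environment, signal) index-path pairs of horizon t.

    Yt follows pE/TEF; Zt follows pS/TS conditionally on Yt (the common signal
    is assumed to obey the same law as individual sensing).
    """
    if t < 0 or n < 1:
        raise ValueError("need t >= 0 and n >= 1")
    rng = _rng(seed)
    u = rng.random(size=(n, 2 * (t + 1)))
    uE, uS = u[:, : t + 1], u[:, t + 1 :]

    cumT = np.cumsum(model.env.transition, axis=1)
    cumS = np.cumsum(model.sensing.kernel, axis=2)  # (z, y', z')
    cum_pE = np.cumsum(model.env.initial)
    cum_pS0 = np.cumsum(model.sensing.initial, axis=1)

    Y = np.empty((n, t + 1), dtype=np.intp)
    Z = np.empty((n, t + 1), dtype=np.intp)
    Y[:, 0] = _categorical_rows(np.broadcast_to(cum_pE, (n, cum_pE.size)), uE[:, 0])
    Z[:, 0] = _categorical_rows(cum_pS0[Y[:, 0]], uS[:, 0])
    for tau in range(t):
        Y[:, tau + 1] = _categorical_rows(cumT[Y[:, tau]], uE[:, tau + 1])
        Z[:, tau + 1] = _categorical_rows(cumS[Z[:, tau], Y[:, tau + 1]], uS[:, tau + 1])
    return Y, Z


def sample_realization(model: ModelBundle, t: int, seed) -> Tuple[History, History]:
    """One seeded (environment history, signal history) pair as History objects."""
    Y, Z = sample_paths(model, t, 1, seed)
    envs, sigs = model.spaces.environments, model.spaces.signals
    return (
        History(tuple(envs[i] for i in Y[0]), envs),
        History(tuple(sigs[i] for i in Z[0]), sigs),
    )


@dataclass
class TrajectoryRecord:
    """Per-time abundances and fitness series for one realization."""

    env_history: History
    signal_history: History
    log_abund_individual: np.ndarray  # (t+1, nx, nz)
    log_abund_common: np.ndarray  # (t+1, nx)
    psi_i: np.ndarray  # (t+1,)
    psi_c: np.ndarray  # (t+1,)


def run_trajectory(model: ModelBundle, Yt, Zt) -> TrajectoryRecord:
    """Propagate both population recursions along one realized (Yt, Zt) pair.

    The final entries of ``psi_i`` / ``psi_c`` equal the transfer-matrix
    fitness values computed in :mod:`sensegain.paths`.
    """
    Y = env_indices(model, Yt)[0]
    Z = signal_indices(model, Zt)[0]
    if Y.shape != Z.shape:
        raise ValueError("environment and signal histories must share the horizon")
    t = Y.shape[0] - 1
    logTS = _log(model.sensing.kernel)
    logTF = _log(model.switching.kernel)
    k = model.replication.lograte

    logNi = _log(model.sensing.initial)[Y[0]][None, :] + _log(model.switching.initial).T
    logNc = _log(model.switching.initial)[Z[0]]
    tabs_i, tabs_c = [logNi], [logNc]
    for tau in range(t):
        y, z = Y[tau + 1], Z[tau + 1]
        # individual: N'(x', z') = e^{k(x',y')} sum_{x,z} TF(x'|x,z') TS(z'|z,y') N(x,z)
        tmp = _lse(logNi[:, :, None] + logTS[None, :, y, :], axis=1)  # (x_prev, z')
        new_i = _lse(tmp[:, :, None] + logTF[:, :, :], axis=0)  # (z', x')
        logNi = new_i.T + k[:, y][:, None]
        # common: N'(x') = e^{k(x',y')} sum_x TF(x'|x,z') N(x)
        logNc = _lse(logNc[:, None] + logTF[:, z, :], axis=0) + k[:, y]
        tabs_i.append(logNi)
        tabs_c.append(logNc)

    psi_i = np.array([_lse(tab.reshape(-1), axis=0) for tab in tabs_i])
    psi_c = np.array([_lse(tab, axis=0) for tab in tabs_c])
    envs, sigs = model.spaces.environments, model.spaces.signals
    return TrajectoryRecord(
        env_history=History(tuple(envs[i] for i in Y), envs),
        signal_history=History(tuple(sigs[i] for i in Z), sigs),
        log_abund_individual=np.stack(tabs_i),
        log_abund_common=np.stack(tabs_c),
        psi_i=psi_i - psi_i[0],
        psi_c=psi_c - psi_c[0],
    )


@dataclass
class EnsembleSummary:
    """Per-time sample means and standard errors over realizations."""

    times: np.ndarray
    mean_psi_i: np.ndarray
    se_psi_i: np.ndarray
    mean_psi_c: np.ndarray
    se_psi_c: np.ndarray
    mean_g: np.ndarray  # per-time mean of psi_i - psi_c
    se_g: np.ndarray
    mean_psi_0: Optional[np.ndarray]
    se_psi_0: Optional[np.ndarray]
    n_realizations: int
    seed: int


def _mean_se(a: np.ndarray):
    n = a.shape[0]
    mean = a.mean(axis=0)
    se = a.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    return mean, se


def ensemble_summary(model: ModelBundle, t: int, n_realizations: int, seed: int) -> EnsembleSummary:
    """Sample means of the fitness series over seeded realizations.

    Includes the no-sensing reference Psi_0[Yt] = Kmax[Yt] + ln Q[Yt] when a
    decomposition is attached.
    """
    Y, Z = sample_paths(model, t, n_realizations, seed)
    _, psi_i = fitness_individual_batch(model, Y, return_series=True)
    _, psi_c = fitness_common_batch(model, Y, Z, return_series=True)
    g = psi_i - psi_c
    mean_i, se_i = _mean_se(psi_i)
    mean_c, se_c = _mean_se(psi_c)
    mean_g, se_g = _mean_se(g)

    mean_0 = se_0 = None
    if model.decomposition is not None:
        logT = _log(model.env.transition)
        logp0 = _log(model.env.initial)
        steps_q = logT[Y[:, :-1], Y[:, 1:]]
        logQ_prefix = np.concatenate(
            [logp0[Y[:, 0]][:, None], logp0[Y[:, 0]][:, None] + np.cumsum(steps_q, axis=1)],
            axis=1,
        )
        kmax_prefix = np.concatenate(
            [
                np.zeros((n_realizations, 1)),
                np.cumsum(model.decomposition.kmax[Y[:, 1:]], axis=1),
            ],
            axis=1,
        )
        mean_0, se_0 = _mean_se(kmax_prefix + logQ_prefix)

    return EnsembleSummary(
        times=np.arange(t + 1),
        mean_psi_i=mean_i,
        se_psi_i=se_i,
        mean_psi_c=mean_c,
        se_psi_c=se_c,
        mean_g=mean_g,
        se_g=se_g,
        mean_psi_0=mean_0,
        se_psi_0=se_0,
        n_realizations=n_realizations,
        seed=int(seed) if not isinstance(seed, np.random.Generator) else -1,
    )
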