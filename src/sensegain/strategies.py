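"""Closed-form optimal switching and allocation strategies and fitness bounds.

With as many phenotypes as environments (an identification x <-> y), the
common-sensing fitness gain <Psi_c> - <Psi_0> attains its upper bound, the
directed information I(Z->Y), when switching and allocation jointly implement
sequential Bayesian inference:

* allocation is the delta strategy TK*(y|x) = delta_{x,y} -- each phenotype
  commits all resources to its matched environment and cannot grow elsewhere
  (off-diagonal log replication rates are -inf);
* switching follows the Bayesian posterior of the next environment given the
  sensed signal and the current (matched) environment.

Under this pair Dloss = 0.  For individual sensing the same pair yields
<Psi_i*> = <Psi_0> + I + G*, a strictly higher bound when G* > 0, but it need
not maximize <Psi_i>: no numerical optimizer over (TF, TK) is provided here.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .errors import UnsupportedModelError
from .info import average_fitness, bayes_kernels, directed_information, dloss, fitness_gain_G
from .models import (
    AllocationDecomposition,
    ModelBundle,
    ReplicationModel,
    SwitchingModel,
    _simplex_rows,
)


@dataclass(frozen=True)
class StrategyPair:
    """A phenotype-switching kernel together with a metabolic allocation."""

    switching: SwitchingModel
    allocation: AllocationDecomposition
    replication: ReplicationModel

    def apply(self, model: ModelBundle) -> ModelBundle:
        """The model with switching, allocation, and replication replaced."""
        return replace(
            model,
            switching=self.switching,
            replication=self.replication,
            decomposition=self.allocation,
        )


def optimal_strategy(
    model: ModelBundle, bijection: Optional[Sequence[str]] = None
) -> StrategyPair:
    """The Bayesian-sequential-inference strategy pair (requires |Sx| = |Sy|).

    ``bijection`` optionally lists, per phenotype (in label order), the
    matched environment label; by default phenotypes and environments are
    identified by position.  The returned pair satisfies Dloss = 0.
    """
    nx, ny, nz = model.spaces.nx, model.spaces.ny, model.spaces.nz
    if nx != ny:
        raise UnsupportedModelError(
            f"the Bayesian-optimal strategy needs |Sx| = |Sy|; got {nx} phenotypes "
            f"and {ny} environments"
        )
    if not model.sensing.memoryless:
        raise UnsupportedModelError("the Bayesian-optimal strategy needs memoryless sensing")
    if bijection is None:
        match = np.arange(nx)
    else:
        envs = list(model.spaces.environments)
        match = np.array([envs.index(lbl) for lbl in bijection], dtype=np.intp)
        if sorted(match.tolist()) != list(range(ny)):
            raise UnsupportedModelError("bijection must map phenotypes onto all environments")

    bk = bayes_kernels(model)
    # switching: TF*(x'|x, z') = posterior(y'=match(x') | z', y=match(x));
    # rows for signals unreachable from y get a uniform placeholder (their
    # forward weight is zero).
    post = bk.env_posterior[np.ix_(match, np.arange(nz), match)]  # (x, z', x')
    reachable = bk.signal_predictive[match][:, :, None] > 0  # (x, z', 1)
    kernel = np.where(reachable, post, 1.0 / nx)
    post0 = bk.env_posterior0[:, match]  # (z0, x0)
    init = np.where(bk.signal_marginal[:, None] > 0, post0, 1.0 / nx)
    switching = SwitchingModel(kernel=kernel, initial=init, memoryless=False)

    # allocation: delta on the matched environment; kmax* keeps the model's
    # own matched-diagonal replication rate.
    TK = np.zeros((nx, ny))
    TK[np.arange(nx), match] = 1.0
    kmax = np.empty(ny)
    kmax[match] = model.replication.lograte[np.arange(nx), match]
    lograte = np.full((nx, ny), -np.inf)
    lograte[np.arange(nx), match] = kmax[match]
    return StrategyPair(
        switching=switching,
        allocation=AllocationDecomposition(kmax=kmax, allocation=TK),
        replication=ReplicationModel(lograte),
    )


def random_strategy(model: ModelBundle, seed: int, kmax_scale: float = 1.0) -> StrategyPair:
    """A random memoryless (TF, TK, kmax) triple for bound sweeps."""
    rng = np.random.default_rng(seed)
    nx, ny, nz = model.spaces.nx, model.spaces.ny, model.spaces.nz
    switching = SwitchingModel(
        kernel=_simplex_rows(rng, (nz, nx)), initial=_simplex_rows(rng, (nz, nx))
    )
    TK = _simplex_rows(rng, (nx, ny))
    kmax = rng.uniform(0.0, kmax_scale, size=ny)
    alloc = AllocationDecomposition(kmax=kmax, allocation=TK)
    return StrategyPair(
        switching=switching,
        allocation=alloc,
        replication=ReplicationModel(alloc.recompose_lograte()),
    )


def evaluate_bounds(model: ModelBundle, strategy: StrategyPair, t: int, guard: int = 10**7) -> dict:
    """Evaluate the information bounds on fitness under a given strategy.

    Returns the common- and individual-sensing fitness gains over the
    no-sensing baseline, the directed information I, the individual-sensing
    surplus G, and Dloss, together with:

    * ``common_bound_slack`` = I - (<Psi_c> - <Psi_0>) >= 0, with equality
      exactly when Dloss = 0 (the Bayesian-optimal pair);
    * ``individual_decomposition_residual`` =
      (<Psi_i> - <Psi_0>) - I - G + Dloss, identically zero.
    """
    m = strategy.apply(model)
    avg = average_fitness(m, t, guard=guard)
    I = directed_information(m, t, guard=guard)
    G = fitness_gain_G(m, t, guard=guard)
    dl = dloss(m, t, guard=guard)
    psi_c_gain = avg["psi_c"] - avg["psi_0"]
    psi_i_gain = avg["psi_i"] - avg["psi_0"]
    return {
        "psi_c_gain": psi_c_gain,
        "psi_i_gain": psi_i_gain,
        "directed_information": I,
        "fitness_gain_G": G,
        "dloss": dl,
        "common_bound_slack": I - psi_c_gain,
        "individual_decomposition_residual": psi_i_gain - I - G + dl,
    }
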