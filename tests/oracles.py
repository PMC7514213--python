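"""Independent brute-force oracles.

Everything here enumerates joint path spaces with plain Python loops and
linear-domain arithmetic — deliberately sharing no code with the package's
log-domain transfer-matrix implementations.  Only usable at tiny sizes.
"""
import itertools

import numpy as np


def path_product_sensing(model, Z, Y):
    """PS[Zt||Yt] by direct multiplication."""
    p = model.sensing.initial[Y[0], Z[0]]
    for tau in range(len(Y) - 1):
        p *= model.sensing.kernel[Z[tau], Y[tau + 1], Z[tau + 1]]
    return p


def path_product_switching(model, X, Z):
    p = model.switching.initial[Z[0], X[0]]
    for tau in range(len(Z) - 1):
        p *= model.switching.kernel[X[tau], Z[tau + 1], X[tau + 1]]
    return p


def path_product_env(model, Y):
    p = model.env.initial[Y[0]]
    for tau in range(len(Y) - 1):
        p *= model.env.transition[Y[tau], Y[tau + 1]]
    return p


def growth_factor(model, X, Y):
    """e^{K[Xt,Yt]}; zero if any step rate is zero."""
    g = 1.0
    for tau in range(len(Y) - 1):
        g *= np.exp(model.replication.lograte[X[tau + 1], Y[tau + 1]])
    return g


def alloc_product(model, Yalloc, X):
    p = 1.0
    for tau in range(len(X) - 1):
        p *= model.decomposition.allocation[X[tau + 1], Yalloc[tau + 1]]
    return p


def all_paths(n, t):
    return itertools.product(range(n), repeat=t + 1)


def psi_individual(model, Y):
    """ln sum_{Xt,Zt} e^K PF PS by full enumeration."""
    total = 0.0
    for X in all_paths(model.spaces.nx, len(Y) - 1):
        for Z in all_paths(model.spaces.nz, len(Y) - 1):
            total += (
                growth_factor(model, X, Y)
                * path_product_switching(model, X, Z)
                * path_product_sensing(model, Z, Y)
            )
    return np.log(total)


def psi_common(model, Y, Z):
    """ln sum_Xt e^K PF by full enumeration."""
    total = 0.0
    for X in all_paths(model.spaces.nx, len(Y) - 1):
        total += growth_factor(model, X, Y) * path_product_switching(model, X, Z)
    return np.log(total)


def retrospective_signal(model, Y):
    """PBi[Zt|Yt] over all signal paths, via the joint (Xt, Zt) enumeration."""
    t = len(Y) - 1
    norm = np.exp(psi_individual(model, Y))
    out = {}
    for Z in all_paths(model.spaces.nz, t):
        s = 0.0
        for X in all_paths(model.spaces.nx, t):
            s += (
                growth_factor(model, X, Y)
                * path_product_switching(model, X, Z)
                * path_product_sensing(model, Z, Y)
            )
        out[Z] = s / norm
    return out


def pkfs_probability(model, Yalloc, Yactual):
    """PKFS[Y'|Y] by triple enumeration over (Xt, Zt)."""
    t = len(Yactual) - 1
    total = 0.0
    for X in all_paths(model.spaces.nx, t):
        for Z in all_paths(model.spaces.nz, t):
            total += (
                alloc_product(model, Yalloc, X)
                * path_product_switching(model, X, Z)
                * path_product_sensing(model, Z, Yactual)
            )
    return total
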