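"""Histories over finite alphabets and exhaustive enumeration.

A history is an ordered sequence of states ``(s_0, ..., s_t)`` over one of the
model's three alphabets (phenotypes, environments, signals).  The horizon ``t``
counts transitions, so a history of horizon ``t`` has ``t + 1`` entries.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import EnumerationLimitError

#: default ceiling on |alphabet|**(t+1) for exhaustive enumeration
DEFAULT_GUARD = 10**7


@dataclass(frozen=True)
class History:
    """An ordered state sequence over a finite alphabet.

    Parameters
    ----------
    labels : tuple of str
        The states ``s_0 .. s_t`` in time order.
    alphabet : tuple of str
        The ordered label list of the space the history ranges over.
    """

    labels: tuple
    alphabet: tuple

    def __post_init__(self):
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "alphabet", tuple(self.alphabet))
        if len(self.labels) < 1:
            raise ValueError("a history has at least one state (horizon >= 0)")
        unknown = set(self.labels) - set(self.alphabet)
        if unknown:
            raise ValueError(f"labels {sorted(unknown)} not in alphabet {list(self.alphabet)}")

    @property
    def horizon(self) -> int:
        return len(self.labels) - 1

    @property
    def indices(self) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.alphabet)}
        return np.array([lookup[s] for s in self.labels], dtype=np.intp)

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)

    def joined(self, sep: str = "-") -> str:
        return sep.join(self.labels)


def as_history(seq, alphabet: Sequence[str]) -> History:
    """Coerce a ``History`` or a plain label sequence to a ``History``."""
    if isinstance(seq, History):
        if tuple(seq.alphabet) != tuple(alphabet):
            raise ValueError(
                f"history alphabet {list(seq.alphabet)} does not match expected {list(alphabet)}"
            )
        return seq
    return History(tuple(seq), tuple(alphabet))


def as_indices(seq, alphabet: Sequence[str]) -> np.ndarray:
    """Integer indices of a history (or label sequence) in its alphabet."""
    return as_history(seq, alphabet).indices


def enumerate_index_paths(n_states: int, t: int, guard: int = DEFAULT_GUARD) -> np.ndarray:
    """All index sequences of length ``t + 1`` over ``range(n_states)``.

    Returns an ``(n_states**(t+1), t+1)`` integer array in lexicographic order.
    """
    if n_states < 1 or t < 0:
        raise ValueError("need n_states >= 1 and t >= 0")
    total = n_states ** (t + 1)
    if total > guard:
        raise EnumerationLimitError(
            f"{n_states}**{t + 1} = {total} histories exceeds the guard of {guard}; "
            "raise `guard` explicitly to override"
        )
    if n_states == 1:
        return np.zeros((1, t + 1), dtype=np.intp)
    grids = np.indices((n_states,) * (t + 1))
    return grids.reshape(t + 1, total).T.astype(np.intp)


def enumerate_histories(alphabet: Sequence[str], t: int, guard: int = DEFAULT_GUARD):
    """All histories of horizon ``t`` over ``alphabet``, lexicographic order."""
    alphabet = tuple(alphabet)
    idx = enumerate_index_paths(len(alphabet), t, guard=guard)
    return [History(tuple(alphabet[i] for i in row), alphabet) for row in idx]


@dataclass
class PathEnsemble:
    """A collection of histories with log-weights.

    For an exhaustive ensemble over a normalized measure the log-weights
    log-sum-exp to zero.
    """

    histories: list
    log_weights: np.ndarray
    kind: str  # "exhaustive" | "sampled"
    horizon: int

    def __post_init__(self):
        self.log_weights = np.asarray(self.log_weights, dtype=float)
        if len(self.histories) != self.log_weights.shape[0]:
            raise ValueError("histories and log_weights length mismatch")
        if self.kind not in ("exhaustive", "sampled"):
            raise ValueError(f"unknown ensemble kind {self.kind!r}")

    def normalization(self) -> float:
        """log-sum-exp of the weights (0 for a normalized exhaustive ensemble)."""
        from scipy.special import logsumexp

        return float(logsumexp(self.log_weights))

    def probabilities(self) -> np.ndarray:
        return np.exp(self.log_weights)

    def to_rows(self):
        """(dash-joined history, log_weight) rows in deterministic order."""
        return [
            (h.joined() if isinstance(h, History) else "-".join(h), float(w))
            for h, w in zip(self.histories, self.log_weights)
        ]
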