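"""Bayesian / inverse-Bayesian (BIB) inference on a finite alphabet.

An agent holds ``m`` hypotheses over an alphabet of ``n`` data symbols.
Each hypothesis is a likelihood row — a conditional distribution
``P(d | h)`` over symbols — and the agent's belief is a probability
vector ``P(h)`` over hypotheses.  Plain Bayesian (B) inference updates
the belief after every observed symbol while the likelihood rows stay
fixed.  Inverse-Bayesian (IB) inference additionally rewrites the
hypothesis set itself: at each step the currently *least* probable
hypothesis ``h_s`` may have its likelihood row replaced by the empirical
symbol frequency of the last ``M`` observations.  The replacement fires
with probability ``1 - P(h_s)``, so near-useless hypotheses are recycled
almost surely while a hypothesis that still carries weight is protected.
The combination (a Bayes update followed by the probabilistic row
replacement) is the BIB system; it lets the agent track nonstationary
environments that a fixed hypothesis set cannot follow.

Decision-making reads off ``P(d | h_max)`` where ``h_max`` is the most
probable hypothesis.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DataAlphabet",
    "DataWindow",
    "InitialLikelihoodSpec",
    "BIBAgent",
    "validate_likelihood",
    "validate_belief",
    "windowed_frequency",
    "bayes_update",
    "select_hs",
    "ib_update",
    "reset_belief",
    "argmax_hypothesis",
    "predict",
    "initial_likelihood",
    "step",
]

#: tolerance for probability normalisation checks
NORM_TOL = 1e-9


@dataclass(frozen=True)
class DataAlphabet:
    """Finite alphabet of data symbols, indexed ``0 .. n-1``."""

    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"alphabet needs at least 2 symbols, got n={self.n}")


def validate_likelihood(likelihood: np.ndarray) -> np.ndarray:
    """Check a likelihood matrix: entries in [0, 1], rows summing to 1."""
    L = np.asarray(likelihood, dtype=float)
    if L.ndim != 2:
        raise ValueError("likelihood must be a 2-D (hypotheses x symbols) array")
    if np.any(L < -NORM_TOL) or np.any(L > 1 + NORM_TOL):
        raise ValueError("likelihood entries must lie in [0, 1]")
    rowsums = L.sum(axis=1)
    if np.any(np.abs(rowsums - 1.0) > NORM_TOL):
        raise ValueError(f"likelihood rows must sum to 1, got sums {rowsums}")
    return L


def validate_belief(belief: np.ndarray) -> np.ndarray:
    """Check a belief vector: entries in [0, 1], summing to 1."""
    b = np.asarray(belief, dtype=float)
    if b.ndim != 1:
        raise ValueError("belief must be a 1-D probability vector")
    if np.any(b < -NORM_TOL) or np.any(b > 1 + NORM_TOL):
        raise ValueError("belief entries must lie in [0, 1]")
    if abs(b.sum() - 1.0) > NORM_TOL:
        raise ValueError(f"belief must sum to 1, got {b.sum()}")
    return b


class DataWindow:
    """Sliding buffer of the last ``M`` observed symbol indices.

    Keeps an incremental count vector so the normalised frequency is
    O(n) per query regardless of ``M``.
    """

    def __init__(self, capacity: int, n_symbols: int):
        if capacity < 1:
            raise ValueError("window capacity M must be >= 1")
        self.capacity = int(capacity)
        self.n_symbols = int(n_symbols)
        self._buf: deque[int] = deque()
        self._counts = np.zeros(n_symbols, dtype=np.int64)

    def __len__(self) -> int:
        return len(self._buf)

    def append(self, symbol: int) -> None:
        symbol = int(symbol)
        if not 0 <= symbol < self.n_symbols:
            raise ValueError(
                f"symbol {symbol} outside alphabet of size {self.n_symbols}"
            )
        self._buf.append(symbol)
        self._counts[symbol] += 1
        if len(self._buf) > self.capacity:
            old = self._buf.popleft()
            self._counts[old] -= 1

    @property
    def counts(self) -> np.ndarray:
        return self._counts.copy()

    def copy(self) -> "DataWindow":
        w = DataWindow(self.capacity, self.n_symbols)
        w._buf = deque(self._buf)
        w._counts = self._counts.copy()
        return w


def windowed_frequency(window: DataWindow, alphabet: DataAlphabet | None = None) -> np.ndarray:
    """Normalised frequency ``f(d)`` of each symbol in the window.

    Returns an all-zero vector for an empty window: the sentinel value
    that callers must treat as "skip the IB update this step".
    """
    if alphabet is not None and alphabet.n != window.n_symbols:
        raise ValueError("window alphabet does not match the supplied alphabet")
    m = len(window)
    if m == 0:
        return np.zeros(window.n_symbols, dtype=float)
    return window.counts.astype(float) / m


def bayes_update(belief: np.ndarray, likelihood: np.ndarray, observed: int) -> np.ndarray:
    """One Bayes step: posterior ``P(h | d) ∝ P(d | h) P(h)``.

    Raises ``ZeroDivisionError`` when the observed symbol has zero
    probability under every hypothesis carrying belief mass
    (an inconsistent observation).
    """
    b = np.asarray(belief, dtype=float)
    L = np.asarray(likelihood, dtype=float)
    w = L[:, observed] * b
    denom = w.sum()
    if denom <= 0.0:
        raise ZeroDivisionError(
            f"inconsistent observation: symbol {observed} impossible under "
            "every weighted hypothesis"
        )
    return w / denom


def select_hs(belief: np.ndarray, rng: np.random.Generator) -> int | None:
    """Pick the least probable hypothesis ``h_s`` for IB replacement.

    ``h_s = argmin P(h)`` with ties broken uniformly at random; the
    index is returned with probability ``1 - P(h_s)``, otherwise
    ``None`` (no IB update this step).
    """
    b = np.asarray(belief, dtype=float)
    lo = b.min()
    ties = np.flatnonzero(b == lo)
    h_s = int(ties[rng.integers(len(ties))]) if len(ties) > 1 else int(ties[0])
    if rng.random() < 1.0 - b[h_s]:
        return h_s
    return None


def ib_update(likelihood: np.ndarray, h_s: int, freq: np.ndarray) -> np.ndarray:
    """Inverse-Bayesian step: replace row ``h_s`` with the window frequency.

    An all-zero ``freq`` (empty-window sentinel) is a no-op.
    """
    f = np.asarray(freq, dtype=float)
    L = np.array(likelihood, dtype=float, copy=True)
    if not np.any(f):
        return L
    if abs(f.sum() - 1.0) > NORM_TOL:
        raise ValueError(f"frequency vector must sum to 1, got {f.sum()}")
    L[h_s] = f
    return L


def argmax_hypothesis(belief: np.ndarray, rng: np.random.Generator) -> int:
    """Most probable hypothesis ``h_max``, ties broken uniformly at random."""
    b = np.asarray(belief, dtype=float)
    hi = b.max()
    ties = np.flatnonzero(b == hi)
    if len(ties) == 1:
        return int(ties[0])
    return int(ties[rng.integers(len(ties))])


def predict(likelihood: np.ndarray, h_max: int, symbol: int) -> float:
    """Predicted probability of ``symbol``, read from the ``h_max`` row."""
    return float(np.asarray(likelihood, dtype=float)[h_max, symbol])


@dataclass(frozen=True)
class InitialLikelihoodSpec:
    """Symmetric one-parameter initial hypothesis set.

    Hypothesis ``η_k`` puts probability ``p`` on symbol ``k`` and shares
    the remainder equally over the other ``n - 1`` symbols, so the
    hypothesis count equals the alphabet size.  ``p`` must exceed
    ``1/n`` for ``η_k`` to actually prefer symbol ``k``.
    """

    p: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("alphabet size n must be >= 2")
        if not (1.0 / self.n < self.p <= 1.0):
            raise ValueError(
                f"peak probability p must lie in (1/n, 1]; got p={self.p}, n={self.n}"
            )


def initial_likelihood(spec: InitialLikelihoodSpec) -> np.ndarray:
    """Build the n x n matrix with ``p`` on the diagonal, off-diagonal
    entries ``(1 - p) / (n - 1)``."""
    n, p = spec.n, spec.p
    off = (1.0 - p) / (n - 1)
    L = np.full((n, n), off, dtype=float)
    np.fill_diagonal(L, p)
    return L


@dataclass
class BIBAgent:
    """One inference agent: belief, likelihood, data window and RNG.

    ``mode`` is ``"b"`` (Bayes only: the likelihood never changes) or
    ``"bib"`` (Bayes followed by the probabilistic IB row replacement).
    """

    belief: np.ndarray
    likelihood: np.ndarray
    window: DataWindow
    rng: np.random.Generator
    mode: str = "bib"

    def __post_init__(self) -> None:
        self.belief = validate_belief(self.belief)
        self.likelihood = validate_likelihood(self.likelihood)
        m, n = self.likelihood.shape
        if len(self.belief) != m:
            raise ValueError("belief length must match likelihood row count")
        if self.window.n_symbols != n:
            raise ValueError("window alphabet must match likelihood columns")
        if self.mode not in ("b", "bib"):
            raise ValueError(f"mode must be 'b' or 'bib', got {self.mode!r}")

    @classmethod
    def fresh(
        cls,
        spec: InitialLikelihoodSpec,
        M: int,
        seed: int | np.random.Generator,
        mode: str = "bib",
    ) -> "BIBAgent":
        """Uniform prior, symmetric initial likelihood, empty window."""
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        return cls(
            belief=np.full(spec.n, 1.0 / spec.n),
            likelihood=initial_likelihood(spec),
            window=DataWindow(M, spec.n),
            rng=rng,
            mode=mode,
        )

    def h_max(self) -> int:
        return argmax_hypothesis(self.belief, self.rng)

    def predict(self, h_max: int, symbol: int) -> float:
        return predict(self.likelihood, h_max, symbol)


def reset_belief(belief: np.ndarray, h_s: int) -> np.ndarray:
    """Give a freshly generated hypothesis a fresh prior.

    Sets ``P(h_s) = 1/m`` and rescales the others to keep the vector
    normalised.  Without this, a replaced hypothesis whose belief has
    hit exactly zero (a window frequency carries exact zeros, and one
    observation of a missing symbol multiplies its belief to zero) can
    never re-enter the competition no matter how well its new
    likelihood row fits — the hypothesis set would silt up with dead
    rows and the inverse-Bayesian exploration would stall.
    """
    b = np.asarray(belief, dtype=float)
    m = len(b)
    out = b * ((1.0 - 1.0 / m) / (1.0 - b[h_s])) if b[h_s] < 1.0 else np.zeros(m)
    out[h_s] = 1.0 / m
    return out / out.sum()


def step(agent: BIBAgent, observed: int) -> BIBAgent:
    """Advance one agent by one observation, in place.

    Order within the step: window append, Bayes update, then (BIB mode
    only) the probabilistic IB replacement using the updated window's
    frequency; the replaced hypothesis restarts from the uniform prior
    share.  Returns the same agent for chaining.
    """
    agent.window.append(observed)
    agent.belief = bayes_update(agent.belief, agent.likelihood, observed)
    if agent.mode == "bib":
        freq = windowed_frequency(agent.window)
        if np.any(freq):
            h_s = select_hs(agent.belief, agent.rng)
            if h_s is not None:
                agent.likelihood = ib_update(agent.likelihood, h_s, freq)
                agent.belief = reset_belief(agent.belief, h_s)
    return agent
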