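"""Trajectory analysis: polarization, local-density data and BIB scoring.

Works on time-indexed 2-D positions of ``N`` individuals (tracked
animals or simulator output).  Three layers:

* kinematics — forward-difference velocities and the polarization order
  parameter ``psi``, the norm of the mean unit-velocity vector (1 =
  perfect alignment, ~N^{-1/2} for incoherent headings);
* symbolisation — each individual's local *relative* density is
  discretised to a symbol ``d in {0, 1, 2, 3}`` from the neighbour
  counts ``n_r`` (within radius r) and ``n_2r`` (within 2r):
  ``d = min(3, INT(4 n_r / n_2r))``, with ``d = 0`` for an empty
  2r-neighbourhood;
* inference scoring — each individual's symbol stream is fed to a
  Bayes-only and a BIB agent, and the per-step prediction
  ``P(d | h_max)`` is compared with the *future frequency* ``F_t(d)``,
  the empirical symbol distribution over frames ``t - M/2 .. t + M``.
  A small prediction-vs-future gap means the agent's current hypothesis
  anticipates the density it is about to experience.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bib_core import BIBAgent, InitialLikelihoodSpec, step

__all__ = [
    "TrajectoryDataset",
    "DensityParams",
    "IndividualAnalysis",
    "velocities",
    "polarization",
    "polarization_series",
    "density_datum",
    "density_series",
    "future_frequency",
    "future_frequency_series",
    "analyze_individual",
    "population_average",
    "prediction_error",
]

#: number of density symbols (alphabet {0, 1, 2, 3})
N_SYMBOLS = 4


@dataclass
class TrajectoryDataset:
    """Positions of N individuals over T frames.

    ``positions`` has shape (T, N, 2); NaN rows mark frames where an
    individual is not observed.  ``dt`` is the frame interval in
    seconds; coordinates are unit-agnostic (pixels or mm), with an
    optional mm-per-unit scale carried as metadata.
    """

    positions: np.ndarray
    dt: float = 0.1
    ids: list = field(default_factory=list)
    mm_per_unit: float | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 2:
            raise ValueError("positions must have shape (T, N, 2)")
        if self.dt <= 0:
            raise ValueError("frame interval dt must be positive")
        if not self.ids:
            self.ids = list(range(self.positions.shape[1]))
        # no gaps: within each individual's observed span every frame is present
        for i in range(self.positions.shape[1]):
            ok = np.isfinite(self.positions[:, i]).all(axis=1)
            if ok.any():
                lo, hi = np.flatnonzero(ok)[[0, -1]]
                if not ok[lo : hi + 1].all():
                    raise ValueError(
                        f"individual {self.ids[i]!r} has missing frames inside its span"
                    )

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.positions.shape[1]


@dataclass(frozen=True)
class DensityParams:
    """Inner radius r for the density symbol; the outer radius is 2r."""

    r: float

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("density radius r must be positive")


def velocities(traj: TrajectoryDataset) -> np.ndarray:
    """Forward-difference velocities, shape (T-1, N, 2), length/frame."""
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames for velocities")
    return np.diff(traj.positions, axis=0)


def polarization(vel: np.ndarray) -> float:
    """Polarization psi of one frame of velocities, shape (N, 2).

    Individuals with zero (or undefined) speed have no heading and are
    excluded; psi is the norm of the mean of the remaining unit vectors.
    Returns NaN when no individual has a defined heading.
    """
    v = np.asarray(vel, dtype=float)
    speed = np.linalg.norm(v, axis=1)
    keep = np.isfinite(speed) & (speed > 0)
    if not keep.any():
        return float("nan")
    units = v[keep] / speed[keep, None]
    return float(np.linalg.norm(units.mean(axis=0)))


def polarization_series(traj: TrajectoryDataset) -> np.ndarray:
    """psi at every frame transition, length T-1 (NaN where undefined)."""
    vel = velocities(traj)
    return np.array([polarization(vel[t]) for t in range(vel.shape[0])])


def density_datum(positions: np.ndarray, i: int, params: DensityParams) -> int:
    """Relative-density symbol of focal individual ``i`` at one frame.

    ``n_r`` and ``n_2r`` count the *other* individuals within r and 2r
    of the focal position; ``d = min(3, INT(4 n_r / n_2r))`` and 0 when
    the 2r-neighbourhood is empty.
    """
    pos = np.asarray(positions, dtype=float)
    delta = pos - pos[i]
    dist = np.hypot(delta[:, 0], delta[:, 1])
    dist[i] = np.inf  # exclude the focal individual from both counts
    n_r = int(np.sum(dist <= params.r))
    n_2r = int(np.sum(dist <= 2.0 * params.r))
    if n_2r == 0:
        return 0
    return min(N_SYMBOLS - 1, int(4.0 * n_r / n_2r))


def density_series(traj: TrajectoryDataset, params: DensityParams) -> np.ndarray:
    """Symbol stream for every individual, shape (T, N), int.

    Frames where the focal individual is unobserved get -1.  Unobserved
    neighbours never enter the counts.
    """
    T, N = traj.n_frames, traj.n_individuals
    out = np.full((T, N), -1, dtype=np.int64)
    r2 = DensityParams(params.r).r ** 2
    for t in range(T):
        pos = traj.positions[t]
        present = np.isfinite(pos).all(axis=1)
        delta = pos[:, None, :] - pos[None, :, :]
        d2 = np.einsum("ijk,ijk->ij", delta, delta)  # squared distances, NaN-safe
        np.fill_diagonal(d2, np.inf)
        with np.errstate(invalid="ignore"):
            in_r = d2 <= r2
            in_2r = d2 <= 4.0 * r2
        n_r = in_r.sum(axis=1)
        n_2r = in_2r.sum(axis=1)
        d = np.zeros(N, dtype=np.int64)
        nz = n_2r > 0
        d[nz] = np.minimum(N_SYMBOLS - 1, (4.0 * n_r[nz] / n_2r[nz]).astype(np.int64))
        d[~present] = -1
        out[t] = d
    return out


def future_frequency(series: np.ndarray, t: int, M: int) -> np.ndarray:
    """Future symbol distribution ``F_t(d)`` of one individual's stream.

    Normalised frequency over frames ``t - M/2 .. t + M`` (endpoints
    inclusive, clipped to the series bounds; unobserved frames, coded
    -1, are ignored).  Returns an all-NaN vector when the clipped
    window contains no observation.
    """
    s = np.asarray(series)
    lo = max(0, t - M // 2)
    hi = min(len(s) - 1, t + M)
    if hi < lo:
        return np.full(N_SYMBOLS, np.nan)
    chunk = s[lo : hi + 1]
    chunk = chunk[chunk >= 0]
    if chunk.size == 0:
        return np.full(N_SYMBOLS, np.nan)
    return np.bincount(chunk, minlength=N_SYMBOLS).astype(float) / chunk.size


def future_frequency_series(series: np.ndarray, M: int) -> np.ndarray:
    """``F_t(d)`` for every frame at once, shape (T, 4).

    Equivalent to calling :func:`future_frequency` per frame, via
    cumulative one-hot counts.
    """
    s = np.asarray(series)
    T = len(s)
    onehot = np.zeros((T, N_SYMBOLS), dtype=np.int64)
    obs = s >= 0
    onehot[np.flatnonzero(obs), s[obs]] = 1
    cum = np.vstack([np.zeros(N_SYMBOLS, dtype=np.int64), np.cumsum(onehot, axis=0)])
    t = np.arange(T)
    lo = np.maximum(0, t - M // 2)
    hi = np.minimum(T - 1, t + M)
    counts = cum[hi + 1] - cum[lo]
    tot = counts.sum(axis=1, keepdims=True)
    out = np.full((T, N_SYMBOLS), np.nan)
    nz = tot[:, 0] > 0
    out[nz] = counts[nz] / tot[nz]
    return out


@dataclass
class IndividualAnalysis:
    """Aligned per-frame series for one individual and one mode."""

    d: np.ndarray            # (T,) symbol stream, -1 where unobserved
    prediction: np.ndarray   # (T, 4) P(d | h_max) after each update
    future: np.ndarray       # (T, 4) F_t(d)
    valid: np.ndarray        # (T,) frames whose clipped F window is long enough
    mode: str


def analyze_individual(
    traj: TrajectoryDataset,
    i: int,
    params: DensityParams,
    M: int = 100,
    p: float = 0.7,
    mode: str = "bib",
    seed: int = 0,
    d_series: np.ndarray | None = None,
) -> IndividualAnalysis:
    """Run one inference agent over individual ``i``'s symbol stream.

    The agent starts from a uniform prior and the symmetric initial
    likelihood with peak ``p``; every observed frame advances it one
    step and records the full ``P(d | h_max)`` row and ``F_t(d)``.
    Frames whose clipped future window is shorter than ``M/2`` are
    flagged invalid and excluded from summary error metrics.
    ``d_series`` may pass a precomputed (T, N) symbol array to avoid
    recomputing densities per individual.
    """
    if traj.n_frames <= M:
        raise ValueError(f"trajectory must be longer than M={M} frames")
    if d_series is None:
        d_series = density_series(traj, params)
    s = d_series[:, i]
    T = len(s)
    agent = BIBAgent.fresh(
        InitialLikelihoodSpec(p=p, n=N_SYMBOLS), M=M,
        seed=np.random.default_rng(seed), mode=mode,
    )
    pred = np.full((T, N_SYMBOLS), np.nan)
    fut = future_frequency_series(s, M)
    valid = np.zeros(T, dtype=bool)
    for t in range(T):
        if s[t] >= 0:
            try:
                step(agent, int(s[t]))
            except ZeroDivisionError:
                pass
            h = agent.h_max()
            pred[t] = agent.likelihood[h]
        lo = max(0, t - M // 2)
        hi = min(T - 1, t + M)
        valid[t] = (hi - lo + 1) >= M // 2 and np.isfinite(fut[t]).all() and s[t] >= 0
    return IndividualAnalysis(d=s.copy(), prediction=pred, future=fut, valid=valid, mode=mode)


def population_average(
    results: list[IndividualAnalysis], symbol: int
) -> tuple[np.ndarray, np.ndarray]:
    """Unweighted per-frame mean of prediction and F over individuals.

    Individuals missing at a frame (NaN entries) are excluded from that
    frame's mean.
    """
    if not results:
        raise ValueError("need at least one individual analysis")
    pred = np.stack([r.prediction[:, symbol] for r in results])
    fut = np.stack([r.future[:, symbol] for r in results])
    with np.errstate(invalid="ignore"):
        return np.nanmean(pred, axis=0), np.nanmean(fut, axis=0)


def prediction_error(result: IndividualAnalysis, symbol: int) -> float:
    """Mean |P(symbol | h_max) - F_t(symbol)| over the valid frames."""
    m = result.valid & np.isfinite(result.prediction[:, symbol])
    if not m.any():
        return float("nan")
    return float(np.mean(np.abs(result.prediction[m, symbol] - result.future[m, symbol])))
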