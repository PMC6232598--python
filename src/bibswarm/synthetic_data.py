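"""Seeded generators for test fixtures.

Two kinds of synthetic input:

* ball-bag symbol streams — i.i.d. categorical draws whose underlying
  distribution switches between scheduled regimes (the urn scenario an
  inference agent is asked to track), emitted together with the
  per-step true distribution;
* multi-individual 2-D trajectories with programmed alternation of a
  *coherent* phase (shared heading with small angular noise plus a mild
  pull toward the group centroid: high polarization, rising local
  density) and a *dispersed* phase (independent uniform headings plus
  outward drift: low polarization, falling density).  These emulate the
  statistical structure of tracked swarm recordings — alternating
  high/low polarization episodes with matching density symbol streams —
  without claiming behavioural realism; truth labels are emitted so
  detection can be scored without circularity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trajectory_analysis import TrajectoryDataset

__all__ = [
    "BagSchedule",
    "PhaseSchedule",
    "generate_bag_stream",
    "generate_phase_trajectories",
]


@dataclass(frozen=True)
class BagSchedule:
    """Regimes of (duration in steps, symbol distribution)."""

    regimes: tuple
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.regimes:
            raise ValueError("schedule needs at least one regime")
        for dur, dist in self.regimes:
            if dur < 1:
                raise ValueError("regime durations must be positive")
            d = np.asarray(dist, float)
            if abs(d.sum() - 1.0) > 1e-9 or np.any(d < 0):
                raise ValueError("each regime distribution must be a probability vector")


def generate_bag_stream(schedule: BagSchedule) -> tuple[np.ndarray, np.ndarray]:
    """Symbol series plus the per-step true distribution, shapes (T,), (T, n)."""
    rng = np.random.default_rng(schedule.seed)
    n = len(np.asarray(schedule.regimes[0][1]))
    chunks = []
    truths = []
    for dur, dist in schedule.regimes:
        d = np.asarray(dist, float)
        if len(d) != n:
            raise ValueError("all regimes must share one alphabet size")
        chunks.append(rng.choice(n, size=dur, p=d))
        truths.append(np.tile(d, (dur, 1)))
    return np.concatenate(chunks), np.vstack(truths)


@dataclass(frozen=True)
class PhaseSchedule:
    """Programmed coherent/dispersed phases for trajectory generation.

    ``kappa`` is the von-Mises concentration of individual headings
    about the group heading in coherent phases (``None`` = no angular
    noise); ``gather_pull`` the per-frame fractional drift toward the
    centroid; ``disperse_speed`` the speed of the independent outward
    motion in dispersed phases.
    """

    phases: tuple                  # ((duration_frames, "coherent"|"dispersed"), ...)
    N: int = 30
    arena: float = 100.0
    speed: float = 3.0
    kappa: float | None = 50.0
    gather_pull: float = 0.05
    disperse_speed: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("need at least 2 individuals")
        if not self.phases:
            raise ValueError("schedule needs at least one phase")
        for dur, name in self.phases:
            if dur < 1:
                raise ValueError("phase durations must be positive")
            if name not in ("coherent", "dispersed"):
                raise ValueError(f"unknown phase {name!r}")


def generate_phase_trajectories(
    schedule: PhaseSchedule,
) -> tuple[TrajectoryDataset, np.ndarray]:
    """Trajectories with the programmed phase alternation.

    Positions are continuous across phase switches and live on the
    unbounded plane (the arena side only sets the initial spread), so
    polarization reflects the programmed headings rather than wall
    bounces.  Returns the dataset and one phase label per frame
    (label[t] names the phase governing the step out of frame t; the
    final frame repeats the last label).
    """
    rng = np.random.default_rng(schedule.seed)
    N = schedule.N
    T = sum(dur for dur, _ in schedule.phases)
    pos = np.empty((T + 1, N, 2))
    pos[0] = rng.random((N, 2)) * schedule.arena
    labels = np.empty(T, dtype=object)
    t = 0
    for dur, name in schedule.phases:
        if name == "coherent":
            group_th = rng.uniform(0.0, 2.0 * np.pi)
            for _ in range(dur):
                if schedule.kappa is None:
                    th = np.full(N, group_th)
                else:
                    th = group_th + rng.vonmises(0.0, schedule.kappa, size=N)
                vel = schedule.speed * np.stack([np.cos(th), np.sin(th)], axis=1)
                centroid = pos[t].mean(axis=0)
                vel += schedule.gather_pull * (centroid - pos[t])
                pos[t + 1] = pos[t] + vel
                labels[t] = "coherent"
                t += 1
        else:
            for _ in range(dur):
                th = rng.uniform(0.0, 2.0 * np.pi, size=N)
                vel = schedule.disperse_speed * np.stack([np.cos(th), np.sin(th)], axis=1)
                centroid = pos[t].mean(axis=0)
                away = pos[t] - centroid
                norm = np.linalg.norm(away, axis=1, keepdims=True)
                norm[norm == 0] = 1.0
                vel += 0.5 * schedule.disperse_speed * away / norm
                pos[t + 1] = pos[t] + vel
                labels[t] = "dispersed"
                t += 1
    traj = TrajectoryDataset(positions=pos, dt=0.1)
    labels = np.append(labels, labels[-1])
    return traj, labels
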