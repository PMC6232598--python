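"""Agent-based swarm model driven by alignment plus BIB density inference.

Each of ``N`` agents carries a full BIB inference state over the
relative-density alphabet {0, 1, 2, 3}.  One time step of agent ``i``:

1. observe its density symbol ``d`` (neighbour counts within r and 2r);
2. Bayes-update its belief over the four density hypotheses;
3. read off the preferred density ``d_max`` — the symbol most probable
   under the currently most probable hypothesis ``h_max``;
4. anticipate its next position ``x̂ = x + V̂`` where the anticipated
   velocity ``V̂`` is the *sum of unit velocity vectors* of all agents
   within the alignment radius ``R`` (itself included).  Summing unit
   headings rather than averaging raw velocities keeps the step length
   proportional to the local neighbour count: a crowded, coherent
   neighbourhood carries the agent far, a lone agent barely moves
   beyond its own heading, and speeds stay bounded by the group size
   instead of growing without limit;
5. evaluate the 72 candidate positions ``x̂ + u (cos θ, sin θ)``,
   θ in steps of π/36, and move to the one whose *anticipated* density
   symbol is closest to ``d_max`` (ties uniform at random).  The
   candidate density is counted against where the other agents are
   about to be — each unmoved neighbour is projected one step along
   its current velocity, already-moved neighbours stand at their new
   positions — so the choice is made against the crowd the agent will
   actually encounter, not its wake;
6. set its velocity to the realised displacement;
7. (BIB mode only) possibly replace its least probable hypothesis row
   with the empirical frequency of its own last ``M`` observations.

With Bayes-only inference the hypothesis set is frozen: once a dense
aligned swarm forms it is self-confirming and never collapses.  With
the inverse-Bayesian replacement switched on, freshly rewritten
hypotheses keep flipping the preferred density between "seek the dense
core" and "avoid it", and the swarm perpetually alternates between a
high-polarization swarming phase and a low-polarization dispersing
phase.

The inner loop is compiled with numba; randomness inside the kernels
uses numba's own seeded generator so identical seeds reproduce runs
bit-for-bit.  The module-level operations (``alignment_velocity``,
``candidate_positions``, ``choose_position``, ``agent_step``) expose
the same primitives on plain numpy state for unit-level use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from . import bib_core
from .bib_core import BIBAgent, InitialLikelihoodSpec

__all__ = [
    "SwarmParams",
    "SwarmState",
    "SwarmResult",
    "alignment_velocity",
    "candidate_positions",
    "choose_position",
    "agent_step",
    "init_state",
    "run_simulation",
    "count_collapse_cycles",
]

N_SYMBOLS = 4
N_CANDIDATES = 72
_TWO_PI = 2.0 * np.pi


# ----------------------------------------------------------------------
# numba kernels
# ----------------------------------------------------------------------

@njit(cache=True)
def _seed_kernel(seed):
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _minimg(dx, wrapL):
    # minimum-image convention; wrapL <= 0 means no wrapping
    if wrapL > 0.0:
        if dx > 0.5 * wrapL:
            dx -= wrapL
        elif dx < -0.5 * wrapL:
            dx += wrapL
    return dx


@njit(cache=True)
def _density_symbol(px, py, pos, skip, r, wrapL):
    """Relative-density symbol at point (px, py) against pos, skipping
    index ``skip`` (pass -1 to include everyone)."""
    r2 = r * r
    r2o = 4.0 * r2
    n_r = 0
    n_2r = 0
    for j in range(pos.shape[0]):
        if j == skip:
            continue
        dx = _minimg(pos[j, 0] - px, wrapL)
        dy = _minimg(pos[j, 1] - py, wrapL)
        d2 = dx * dx + dy * dy
        if d2 <= r2o:
            n_2r += 1
            if d2 <= r2:
                n_r += 1
    if n_2r == 0:
        return 0
    d = int(4.0 * n_r / n_2r)
    if d > 3:
        d = 3
    return d


@njit(cache=True)
def _alignment(i, pos, vel, R, wrapL, vout):
    """Anticipated velocity: sum of unit headings over agents within R
    of agent i (i included; zero-speed agents have no heading)."""
    R2 = R * R
    sx = 0.0
    sy = 0.0
    for j in range(pos.shape[0]):
        dx = _minimg(pos[j, 0] - pos[i, 0], wrapL)
        dy = _minimg(pos[j, 1] - pos[i, 1], wrapL)
        if dx * dx + dy * dy <= R2:
            sp = np.sqrt(vel[j, 0] * vel[j, 0] + vel[j, 1] * vel[j, 1])
            if sp > 0.0:
                sx += vel[j, 0] / sp
                sy += vel[j, 1] / sp
    vout[0] = sx
    vout[1] = sy


@njit(cache=True)
def _candidate_scores(xhx, xhy, ant, skip, d_max, r, u, wrapL,
                      cand_cos, cand_sin, relx, rely, scores):
    """|d(candidate) - d_max| for the 72 candidates around (xhx, xhy),
    counted against the anticipated positions ``ant`` of the others.

    Fast path: others are prefiltered to those within 2r + u of the
    anticipated position (only they can enter a candidate's
    2r-neighbourhood), valid when the arena is large enough that the
    minimum image of that ball is unambiguous; otherwise every
    candidate is scored with the full minimum-image count.
    """
    r2 = r * r
    r2o = 4.0 * r2
    if wrapL > 0.0 and wrapL <= 2.0 * (2.0 * r + u):
        for c in range(N_CANDIDATES):
            cx = xhx + u * cand_cos[c]
            cy = xhy + u * cand_sin[c]
            d = _density_symbol(cx, cy, ant, skip, r, wrapL)
            s = d - d_max
            scores[c] = s if s >= 0 else -s
        return
    lim2 = (2.0 * r + u) * (2.0 * r + u) + 1e-9
    k = 0
    for j in range(ant.shape[0]):
        if j == skip:
            continue
        dx = _minimg(ant[j, 0] - xhx, wrapL)
        dy = _minimg(ant[j, 1] - xhy, wrapL)
        if dx * dx + dy * dy <= lim2:
            relx[k] = dx
            rely[k] = dy
            k += 1
    for c in range(N_CANDIDATES):
        cx = u * cand_cos[c]
        cy = u * cand_sin[c]
        n_r = 0
        n_2r = 0
        for jj in range(k):
            ddx = relx[jj] - cx
            ddy = rely[jj] - cy
            d2 = ddx * ddx + ddy * ddy
            if d2 <= r2o:
                n_2r += 1
                if d2 <= r2:
                    n_r += 1
        if n_2r == 0:
            d = 0
        else:
            d = int(4.0 * n_r / n_2r)
            if d > 3:
                d = 3
        s = d - d_max
        scores[c] = s if s >= 0 else -s


@njit(cache=True)
def _argmax_tie(v):
    hi = v[0]
    for k in range(1, v.shape[0]):
        if v[k] > hi:
            hi = v[k]
    cnt = 0
    for k in range(v.shape[0]):
        if v[k] == hi:
            cnt += 1
    pick = 0 if cnt == 1 else np.random.randint(0, cnt)
    for k in range(v.shape[0]):
        if v[k] == hi:
            if pick == 0:
                return k
            pick -= 1
    return 0


@njit(cache=True)
def _argmin_tie(v):
    lo = v[0]
    for k in range(1, v.shape[0]):
        if v[k] < lo:
            lo = v[k]
    cnt = 0
    for k in range(v.shape[0]):
        if v[k] == lo:
            cnt += 1
    pick = 0 if cnt == 1 else np.random.randint(0, cnt)
    for k in range(v.shape[0]):
        if v[k] == lo:
            if pick == 0:
                return k
            pick -= 1
    return 0


@njit(cache=True)
def _pick_min_score(scores):
    lo = scores[0]
    for c in range(1, N_CANDIDATES):
        if scores[c] < lo:
            lo = scores[c]
    cnt = 0
    for c in range(N_CANDIDATES):
        if scores[c] == lo:
            cnt += 1
    pick = 0 if cnt == 1 else np.random.randint(0, cnt)
    for c in range(N_CANDIDATES):
        if scores[c] == lo:
            if pick == 0:
                return c
            pick -= 1
    return 0


@njit(cache=True)
def _agent_step_kernel(i, pos_r, vel_r, pos_w, vel_w, belief, lik,
                       win, win_len, win_ptr, win_counts,
                       r, R, u, L, wrapL, reflect, bib,
                       cand_cos, cand_sin, relx, rely, scores, vout, w4,
                       moved, ant):
    """One full update of agent i.  Reads neighbours from pos_r/vel_r,
    writes agent i into pos_w/vel_w (pass the same arrays for the
    asynchronous immediately-visible update).  ``moved`` flags agents
    already updated this sweep; candidate densities are counted against
    their realised positions and the projected positions
    ``x_j + V_j`` of the rest."""
    # (1) observe own density symbol and push it into the window
    d_obs = _density_symbol(pos_r[i, 0], pos_r[i, 1], pos_r, i, r, wrapL)
    M = win.shape[1]
    if win_len[i] == M:
        old = win[i, win_ptr[i]]
        win_counts[i, old] -= 1
    else:
        win_len[i] += 1
    win[i, win_ptr[i]] = d_obs
    win_counts[i, d_obs] += 1
    win_ptr[i] = (win_ptr[i] + 1) % M

    # (2) Bayes update (skip on an inconsistent observation)
    denom = 0.0
    for h in range(N_SYMBOLS):
        w4[h] = lik[i, h, d_obs] * belief[i, h]
        denom += w4[h]
    if denom > 0.0:
        for h in range(N_SYMBOLS):
            belief[i, h] = w4[h] / denom

    # (3) preferred density d_max via h_max
    h_max = _argmax_tie(belief[i])
    d_max = _argmax_tie(lik[i, h_max])

    # (4) anticipated position via alignment
    _alignment(i, pos_r, vel_r, R, wrapL, vout)
    xhx = pos_r[i, 0] + vout[0]
    xhy = pos_r[i, 1] + vout[1]

    # (5) candidate choice against the anticipated crowd
    for j in range(pos_r.shape[0]):
        if moved[j] == 1:
            ant[j, 0] = pos_w[j, 0]
            ant[j, 1] = pos_w[j, 1]
        else:
            ant[j, 0] = pos_r[j, 0] + vel_r[j, 0]
            ant[j, 1] = pos_r[j, 1] + vel_r[j, 1]
    _candidate_scores(xhx, xhy, ant, i, d_max, r, u, wrapL,
                      cand_cos, cand_sin, relx, rely, scores)
    c = _pick_min_score(scores)
    nx = xhx + u * cand_cos[c]
    ny = xhy + u * cand_sin[c]

    # (6) move; velocity is the unwrapped displacement
    vel_w[i, 0] = nx - pos_r[i, 0]
    vel_w[i, 1] = ny - pos_r[i, 1]
    if reflect:
        if nx < 0.0:
            nx = -nx
        elif nx > L:
            nx = 2.0 * L - nx
        if ny < 0.0:
            ny = -ny
        elif ny > L:
            ny = 2.0 * L - ny
    else:
        nx = nx % L
        ny = ny % L
    pos_w[i, 0] = nx
    pos_w[i, 1] = ny

    # (7) inverse-Bayesian replacement of the least probable hypothesis;
    # the fresh hypothesis restarts from the uniform prior share
    if bib:
        h_s = _argmin_tie(belief[i])
        if np.random.random() < 1.0 - belief[i, h_s]:
            inv = 1.0 / win_len[i]
            for d in range(N_SYMBOLS):
                lik[i, h_s, d] = win_counts[i, d] * inv
            b_old = belief[i, h_s]
            if b_old < 1.0:
                scale = (1.0 - 1.0 / N_SYMBOLS) / (1.0 - b_old)
                for h in range(N_SYMBOLS):
                    belief[i, h] *= scale
            else:
                for h in range(N_SYMBOLS):
                    belief[i, h] = 0.0
            belief[i, h_s] = 1.0 / N_SYMBOLS
            tot = 0.0
            for h in range(N_SYMBOLS):
                tot += belief[i, h]
            for h in range(N_SYMBOLS):
                belief[i, h] /= tot


@njit(cache=True)
def _polarization(vel):
    sx = 0.0
    sy = 0.0
    cnt = 0
    for k in range(vel.shape[0]):
        sp = np.sqrt(vel[k, 0] * vel[k, 0] + vel[k, 1] * vel[k, 1])
        if sp > 0.0:
            sx += vel[k, 0] / sp
            sy += vel[k, 1] / sp
            cnt += 1
    if cnt == 0:
        return np.nan
    return np.sqrt(sx * sx + sy * sy) / cnt


@njit(cache=True)
def _run_kernel(pos, vel, belief, lik, win, win_len, win_ptr, win_counts,
                r, R, u, L, periodic, async_order, bib, T, traj, psi):
    N = pos.shape[0]
    wrapL = L if periodic else 0.0
    reflect = not periodic
    order = np.empty(N, np.int64)
    relx = np.empty(N, np.float64)
    rely = np.empty(N, np.float64)
    scores = np.empty(N_CANDIDATES, np.int64)
    vout = np.empty(2, np.float64)
    w4 = np.empty(N_SYMBOLS, np.float64)
    cand_cos = np.empty(N_CANDIDATES, np.float64)
    cand_sin = np.empty(N_CANDIDATES, np.float64)
    for c in range(N_CANDIDATES):
        th = c * (_TWO_PI / N_CANDIDATES)
        cand_cos[c] = np.cos(th)
        cand_sin[c] = np.sin(th)
    pos_snap = np.empty((N, 2), np.float64)
    vel_snap = np.empty((N, 2), np.float64)
    moved = np.zeros(N, np.int64)
    ant = np.empty((N, 2), np.float64)
    for t in range(T):
        for k in range(N):
            moved[k] = 0
        if async_order:
            for k in range(N):
                order[k] = k
            for k in range(N - 1, 0, -1):
                jj = np.random.randint(0, k + 1)
                tmp = order[k]
                order[k] = order[jj]
                order[jj] = tmp
            for k in range(N):
                _agent_step_kernel(order[k], pos, vel, pos, vel, belief, lik,
                                   win, win_len, win_ptr, win_counts,
                                   r, R, u, L, wrapL, reflect, bib,
                                   cand_cos, cand_sin, relx, rely, scores,
                                   vout, w4, moved, ant)
                moved[order[k]] = 1
        else:
            pos_snap[:, :] = pos
            vel_snap[:, :] = vel
            for k in range(N):
                _agent_step_kernel(k, pos_snap, vel_snap, pos, vel, belief,
                                   lik, win, win_len, win_ptr, win_counts,
                                   r, R, u, L, wrapL, reflect, bib,
                                   cand_cos, cand_sin, relx, rely, scores,
                                   vout, w4, moved, ant)
        psi[t] = _polarization(vel)
        for k in range(N):
            traj[t, k, 0] = pos[k, 0]
            traj[t, k, 1] = pos[k, 1]


# ----------------------------------------------------------------------
# public API
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class SwarmParams:
    """Control parameters of the swarm model.

    ``r`` is the density radius (the outer count uses 2r), ``R`` the
    alignment radius, ``p`` the initial likelihood peak, ``u`` the step
    length, ``M`` the IB window, ``L`` the arena side (default 10 r).
    ``boundary`` is ``"periodic"`` or ``"reflecting"``; ``order`` is
    ``"async"`` (shuffled sequential, moves immediately visible) or
    ``"sync"`` (all agents read the same snapshot).
    """

    N: int = 100
    r: float = 30.0
    R: float = 30.0
    p: float = 0.7
    u: float = 1.0
    M: int = 100
    L: float | None = None
    boundary: str = "periodic"
    order: str = "async"
    T: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("need at least 2 agents")
        if min(self.r, self.R, self.u) <= 0:
            raise ValueError("r, R and u must be positive")
        if not (1.0 / N_SYMBOLS < self.p <= 1.0):
            raise ValueError(f"p must lie in (1/4, 1], got {self.p}")
        if self.M < 1 or self.T < 1:
            raise ValueError("M and T must be positive")
        if self.boundary not in ("periodic", "reflecting"):
            raise ValueError(f"unknown boundary mode {self.boundary!r}")
        if self.order not in ("async", "sync"):
            raise ValueError(f"unknown update order {self.order!r}")
        if self.L is None:
            object.__setattr__(self, "L", 10.0 * self.r)
        if self.L <= 0:
            raise ValueError("arena side L must be positive")


@dataclass
class SwarmState:
    """Plain-numpy swarm state for the module-level operations."""

    positions: np.ndarray            # (N, 2)
    velocities: np.ndarray           # (N, 2)
    agents: list[BIBAgent]           # per-agent inference state

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        if self.positions.shape != self.velocities.shape:
            raise ValueError("positions and velocities must have equal shape")
        if len(self.agents) != self.positions.shape[0]:
            raise ValueError("one BIBAgent per individual required")


@dataclass
class SwarmResult:
    """Output of one simulation run."""

    psi: np.ndarray          # (T,) polarization after each step
    positions: np.ndarray    # (T, N, 2)
    params: SwarmParams
    mode: str
    beliefs: np.ndarray | None = None      # (N, 4) final beliefs
    likelihoods: np.ndarray | None = None  # (N, 4, 4) final likelihoods


def _wrap_delta(delta: np.ndarray, wrapL: float) -> np.ndarray:
    if wrapL > 0:
        delta = delta - wrapL * np.round(delta / wrapL)
    return delta


def _density_py(point: np.ndarray, others: np.ndarray, r: float, wrapL: float = 0.0) -> int:
    """Density symbol of a point against a set of other positions."""
    if others.shape[0] == 0:
        return 0
    delta = _wrap_delta(np.asarray(others, float) - np.asarray(point, float), wrapL)
    d2 = np.einsum("ij,ij->i", delta, delta)
    n_2r = int(np.sum(d2 <= 4.0 * r * r))
    if n_2r == 0:
        return 0
    n_r = int(np.sum(d2 <= r * r))
    return min(3, int(4.0 * n_r / n_2r))


def alignment_velocity(
    i: int, positions: np.ndarray, velocities: np.ndarray, R: float, wrapL: float = 0.0
) -> np.ndarray:
    """Anticipated velocity V̂: sum of the unit velocity vectors of the
    set Γ(i) of agents within R of agent i, the focal agent included
    (so Γ(i) is never empty; zero-speed members contribute nothing).

    The unnormalised sum makes the anticipated displacement scale with
    the coherent neighbour count, which keeps speeds bounded by the
    group size and gives crowded coherent regions their momentum."""
    delta = _wrap_delta(np.asarray(positions, float) - np.asarray(positions[i], float), wrapL)
    inR = np.einsum("ij,ij->i", delta, delta) <= R * R
    v = np.asarray(velocities, float)[inR]
    speed = np.linalg.norm(v, axis=1)
    keep = speed > 0
    if not keep.any():
        return np.zeros(2)
    return (v[keep] / speed[keep, None]).sum(axis=0)


def candidate_positions(xhat: np.ndarray, u: float) -> np.ndarray:
    """The 72 candidate positions on the u-circle around the anticipated
    position, at angles 0, π/36, …, (duplicate 2π removed)."""
    if u <= 0:
        raise ValueError("step length u must be positive")
    th = np.arange(N_CANDIDATES) * (_TWO_PI / N_CANDIDATES)
    return np.asarray(xhat, float) + u * np.stack([np.cos(th), np.sin(th)], axis=1)


def choose_position(
    candidates: np.ndarray,
    others: np.ndarray,
    d_max: int,
    r: float,
    rng: np.random.Generator,
    wrapL: float = 0.0,
) -> np.ndarray:
    """Candidate whose density symbol against ``others`` (typically the
    anticipated positions of the other agents) is closest to d_max;
    ties broken uniformly at random."""
    cands = np.asarray(candidates, float)
    if cands.shape[0] == 0:
        raise ValueError("need at least one candidate")
    scores = np.array(
        [abs(_density_py(c, others, r, wrapL) - d_max) for c in cands]
    )
    ties = np.flatnonzero(scores == scores.min())
    return cands[ties[rng.integers(len(ties))]].copy()


def agent_step(
    i: int,
    state: SwarmState,
    params: SwarmParams,
    rng: np.random.Generator,
    mode: str = "bib",
) -> None:
    """Pure-numpy single-agent update, in place (reference path for the
    compiled kernel; asynchronous semantics — reads the live state and
    treats every other agent as not yet moved, so candidate densities
    are counted against their projected positions ``x_j + V_j``)."""
    wrapL = params.L if params.boundary == "periodic" else 0.0
    pos, vel = state.positions, state.velocities
    agent = state.agents[i]
    others = np.delete(pos, i, axis=0)
    others_ant = np.delete(pos + vel, i, axis=0)

    d_obs = _density_py(pos[i], others, params.r, wrapL)
    agent.window.append(d_obs)
    try:
        agent.belief = bib_core.bayes_update(agent.belief, agent.likelihood, d_obs)
    except ZeroDivisionError:
        pass
    h_max = bib_core.argmax_hypothesis(agent.belief, rng)
    row = agent.likelihood[h_max]
    ties = np.flatnonzero(row == row.max())
    d_max = int(ties[rng.integers(len(ties))]) if len(ties) > 1 else int(ties[0])

    vhat = alignment_velocity(i, pos, vel, params.R, wrapL)
    xhat = pos[i] + vhat
    cands = candidate_positions(xhat, params.u)
    new = choose_position(cands, others_ant, d_max, params.r, rng, wrapL)

    vel[i] = new - pos[i]
    if params.boundary == "periodic":
        new = new % params.L
    else:
        new = np.where(new < 0, -new, new)
        new = np.where(new > params.L, 2 * params.L - new, new)
    pos[i] = new

    if mode == "bib":
        freq = bib_core.windowed_frequency(agent.window)
        if np.any(freq):
            h_s = bib_core.select_hs(agent.belief, rng)
            if h_s is not None:
                agent.likelihood = bib_core.ib_update(agent.likelihood, h_s, freq)
                agent.belief = bib_core.reset_belief(agent.belief, h_s)


def init_state(params: SwarmParams, rng: np.random.Generator, mode: str = "bib") -> SwarmState:
    """Uniform positions in the arena, headings uniform on the u-circle,
    uniform priors and the symmetric initial likelihood."""
    pos = rng.random((params.N, 2)) * params.L
    th = rng.random(params.N) * _TWO_PI
    vel = params.u * np.stack([np.cos(th), np.sin(th)], axis=1)
    spec = InitialLikelihoodSpec(p=params.p, n=N_SYMBOLS)
    agents = [
        BIBAgent.fresh(spec, params.M, np.random.default_rng(rng.integers(2**31)), mode=mode)
        for _ in range(params.N)
    ]
    return SwarmState(positions=pos, velocities=vel, agents=agents)


def run_simulation(params: SwarmParams, mode: str = "bib") -> SwarmResult:
    """Run the compiled simulation for ``params.T`` steps.

    All randomness (initial conditions and every in-run tie-break /
    coin-flip) derives from ``params.seed``; identical seed and
    parameters reproduce the run bit-for-bit.
    """
    if mode not in ("b", "bib"):
        raise ValueError(f"mode must be 'b' or 'bib', got {mode!r}")
    rng = np.random.default_rng(params.seed)
    pos = rng.random((params.N, 2)) * params.L
    th = rng.random(params.N) * _TWO_PI
    vel = params.u * np.stack([np.cos(th), np.sin(th)], axis=1)
    belief = np.full((params.N, N_SYMBOLS), 1.0 / N_SYMBOLS)
    lik = np.broadcast_to(
        bib_core.initial_likelihood(InitialLikelihoodSpec(p=params.p, n=N_SYMBOLS)),
        (params.N, N_SYMBOLS, N_SYMBOLS),
    ).copy()
    win = np.zeros((params.N, params.M), dtype=np.int64)
    win_len = np.zeros(params.N, dtype=np.int64)
    win_ptr = np.zeros(params.N, dtype=np.int64)
    win_counts = np.zeros((params.N, N_SYMBOLS), dtype=np.int64)
    traj = np.empty((params.T, params.N, 2))
    psi = np.empty(params.T)
    _seed_kernel(int(rng.integers(2**31)))
    _run_kernel(pos, vel, belief, lik, win, win_len, win_ptr, win_counts,
                float(params.r), float(params.R), float(params.u),
                float(params.L), params.boundary == "periodic",
                params.order == "async", mode == "bib", int(params.T),
                traj, psi)
    return SwarmResult(psi=psi, positions=traj, params=params, mode=mode,
                       beliefs=belief, likelihoods=lik)


def count_collapse_cycles(psi: np.ndarray, high: float = 0.9, low: float = 0.5) -> int:
    """Number of downward crossings of ``low`` after ``psi`` first
    exceeds ``high`` (collapse/re-formation cycles of the swarm).

    After each counted collapse, psi must climb back above ``high``
    before another collapse can be counted.
    """
    psi = np.asarray(psi, float)
    above = np.flatnonzero(psi > high)
    if len(above) == 0:
        return 0
    cycles = 0
    armed = True  # armed once psi has been above `high`
    for x in psi[above[0]:]:
        if armed and x < low:
            cycles += 1
            armed = False
        elif not armed and x > high:
            armed = True
    return cycles
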