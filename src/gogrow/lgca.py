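"""Stochastic lattice-gas cellular automaton (LGCA) for go-or-grow dynamics.

State lives on a 2-D square lattice with periodic boundaries.  Every node
carries ``K`` channels, each holding at most one cell (exclusion principle):
``b = 4`` velocity channels (east, north, west, south) for migratory cells
and ``K - b`` rest channels for proliferative cells.  One automaton step is
the composition of three operators, applied to every node:

1. reaction — death (prob ``r_d`` per cell), birth (prob ``r_b`` per resting
   cell into a free rest channel of the same node), and the phenotype
   redraw governed by the switch probability ``r_s`` of
   :mod:`gogrow.switching`;
2. reorientation — a uniform random permutation of the velocity-channel
   occupancies at each node;
3. propagation — deterministic shift of each velocity channel's cell to the
   neighbouring node it points at.

All randomness flows through a single :class:`numpy.random.Generator`, so a
seeded trajectory is bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .switching import SwitchParams, switch_probability

__all__ = [
    "LatticeConfig",
    "ModelParams",
    "LatticeState",
    "SimulationResult",
    "empty_state",
    "init_disk_state",
    "reaction_step",
    "reorientation_step",
    "propagation_step",
    "step",
    "run",
    "averaged_density",
    "write_trajectory",
    "write_snapshot",
]

# Velocity-channel unit vectors as (drow, dcol): east, north, west, south.
CHANNEL_VECTORS = ((0, 1), (-1, 0), (0, -1), (1, 0))


@dataclass(frozen=True)
class LatticeConfig:
    """Geometry of the 2-D periodic square lattice.

    ``b`` is fixed to 4 (the square-lattice neighbourhood); ``K >= b`` is the
    per-node carrying capacity, so ``K - b`` rest channels are available.
    """

    width: int = 100
    height: int = 100
    K: int = 8
    b: int = 4

    def __post_init__(self) -> None:
        if self.b != 4:
            raise ValueError("only the 2-D square lattice with b=4 is supported")
        if self.K < self.b:
            raise ValueError(f"K must be >= b, got K={self.K} < b={self.b}")
        if self.width < 1 or self.height < 1:
            raise ValueError("lattice dimensions must be >= 1")

    @property
    def n_nodes(self) -> int:
        return self.width * self.height


@dataclass(frozen=True)
class ModelParams:
    """Full parameterization of one stochastic simulation."""

    r_b: float
    r_d: float
    switch: SwitchParams
    lattice: LatticeConfig = field(default_factory=LatticeConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        for name, val in (("r_b", self.r_b), ("r_d", self.r_d)):
            if not (0.0 <= val <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {val}")
        if self.r_d > 0 and not (self.r_d < self.r_b < 1.0):
            warnings.warn(
                "recommended parameter range is 0 < r_d << r_b << 1; "
                f"got r_b={self.r_b}, r_d={self.r_d}",
                stacklevel=2,
            )

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class LatticeState:
    """Per-node, per-channel binary occupancy.

    ``occupancy`` has shape ``(height, width, K)`` with channels ``0..b-1``
    the velocity channels and ``b..K-1`` the rest channels.
    """

    occupancy: np.ndarray
    b: int
    time: int = 0

    @property
    def K(self) -> int:
        return self.occupancy.shape[2]

    @property
    def n_total(self) -> int:
        return int(self.occupancy.sum())

    @property
    def n_move(self) -> int:
        return int(self.occupancy[:, :, : self.b].sum())

    @property
    def n_rest(self) -> int:
        return int(self.occupancy[:, :, self.b :].sum())

    def node_counts(self) -> np.ndarray:
        """Cell count n(r) per node, shape (height, width)."""
        return self.occupancy.sum(axis=2)

    def node_density(self) -> np.ndarray:
        """Local density rho(r) = n(r)/K per node."""
        return self.node_counts() / self.K

    def copy(self) -> "LatticeState":
        return LatticeState(self.occupancy.copy(), self.b, self.time)


def empty_state(cfg: LatticeConfig) -> LatticeState:
    occ = np.zeros((cfg.height, cfg.width, cfg.K), dtype=bool)
    return LatticeState(occ, cfg.b)


def averaged_density(state: LatticeState) -> float:
    """Lattice-averaged density rho_tilde = n_total / (K * |L|)."""
    h, w, K = state.occupancy.shape
    return state.n_total / (K * h * w)


def init_disk_state(
    cfg: LatticeConfig,
    radius: float,
    occupy_prob: float,
    rng: np.random.Generator,
    n_rest: int = 1,
    n_vel: int = 1,
) -> LatticeState:
    """Seed a compact tumor: a disk of nodes around the lattice center.

    Every node within Euclidean distance ``radius`` of the center is,
    independently with probability ``occupy_prob``, given ``n_rest`` cells in
    uniformly chosen rest channels and ``n_vel`` cells in uniformly chosen
    velocity channels.  The defaults (one of each, local density 2/K)
    reproduce the reference initial condition; larger values place the
    initial colony at higher local density, which is how initial conditions
    above the Allee threshold are prepared.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if not (0.0 <= occupy_prob <= 1.0):
        raise ValueError("occupy_prob must lie in [0, 1]")
    if 2 * radius > min(cfg.width, cfg.height):
        raise ValueError(
            "disk of radius %.3g self-overlaps on the periodic %dx%d lattice"
            % (radius, cfg.width, cfg.height)
        )
    if not (0 <= n_vel <= cfg.b and 0 <= n_rest <= cfg.K - cfg.b):
        raise ValueError("n_rest/n_vel exceed the available channels")
    if n_rest + n_vel == 0:
        raise ValueError("at least one cell per occupied node is required")

    state = empty_state(cfg)
    cr, cc = cfg.height // 2, cfg.width // 2
    rows, cols = np.ogrid[: cfg.height, : cfg.width]
    in_disk = (rows - cr) ** 2 + (cols - cc) ** 2 <= radius**2
    chosen = in_disk & (rng.random((cfg.height, cfg.width)) < occupy_prob)
    ri, ci = np.nonzero(chosen)
    # uniformly chosen channel subsets via random ranking per class
    if n_vel > 0 and ri.size:
        vel_rank = np.argsort(rng.random((ri.size, cfg.b)), axis=1)
        sel = vel_rank[:, :n_vel]
        state.occupancy[ri[:, None], ci[:, None], sel] = True
    if n_rest > 0 and ri.size:
        rest_rank = np.argsort(rng.random((ri.size, cfg.K - cfg.b)), axis=1)
        sel = cfg.b + rest_rank[:, :n_rest]
        state.occupancy[ri[:, None], ci[:, None], sel] = True
    return state


def _take_channel(arr: np.ndarray, ch: np.ndarray) -> np.ndarray:
    """arr[(i, j, ch[i, j])] for a (H, W) channel-index array."""
    return np.take_along_axis(arr, ch[:, :, None], axis=2)[:, :, 0]


def reaction_step(
    state: LatticeState, params: ModelParams, rng: np.random.Generator
) -> LatticeState:
    """Death, birth, and phenotype redraw, independently at every node.

    Sub-order (documented, the operator composition itself does not fix it):
    (1) each cell dies with probability r_d; (2) each surviving resting cell
    attempts one division with probability r_b, the offspring going into a
    uniformly chosen free rest channel of the same node, silently failing at
    capacity; (3) each surviving cell redraws its phenotype — resting with
    probability r_s(rho), moving otherwise — where rho is the node density
    at entry to the reaction step.  Cells are processed in uniformly random
    per-node order; a redraw whose target class has no free channel is
    blocked and the cell keeps its class.  Offspring born in (2) do not
    redraw until the next step.
    """
    occ = state.occupancy.copy()
    H, W, K = occ.shape
    b = state.b
    Kr = K - b
    rho_entry = occ.sum(axis=2) / K

    # (1) death: independent thinning of every occupied channel.
    if params.r_d > 0:
        occ &= rng.random(occ.shape) >= params.r_d

    # (2) birth: per node, Binomial(surviving resting cells, r_b) attempts
    # fill uniformly chosen free rest channels until capacity.
    newborn = np.zeros((H, W, K), dtype=bool)
    if params.r_b > 0 and Kr > 0:
        rest = occ[:, :, b:]
        n_rest = rest.sum(axis=2)
        attempts = rng.binomial(n_rest, params.r_b)
        free = Kr - n_rest
        births = np.minimum(attempts, free)
        if births.any():
            # rank free rest channels in uniform random order; occupied ones
            # get +inf keys so they sort last and are never selected.
            keys = rng.random(rest.shape)
            keys[rest] = np.inf
            order = np.argsort(keys, axis=2)
            ranks = np.argsort(order, axis=2)
            fill = ranks < births[:, :, None]
            occ[:, :, b:] |= fill
            newborn[:, :, b:] = fill

    # (3) phenotype redraw in uniformly random per-node cell order.
    sp = params.switch
    r_s = switch_probability(rho_entry, sp)
    want_rest = rng.random((H, W, K)) < np.asarray(r_s)[:, :, None]
    perm = np.argsort(rng.random((H, W, K)), axis=2)
    done = newborn.copy()  # offspring of this step keep the resting phenotype
    free_rest = Kr - occ[:, :, b:].sum(axis=2)
    free_vel = b - occ[:, :, :b].sum(axis=2)
    for p_idx in range(K):
        ch = perm[:, :, p_idx]
        active = _take_channel(occ, ch) & ~_take_channel(done, ch)
        if not active.any():
            continue
        wr = _take_channel(want_rest, ch)
        is_vel = ch < b
        to_rest = active & is_vel & wr & (free_rest > 0)
        to_vel = active & ~is_vel & ~wr & (free_vel > 0)
        stay = active & ~to_rest & ~to_vel

        ri, ci = np.nonzero(to_rest)
        if ri.size:
            # destination: first free rest channel — channels within a class
            # are exchangeable, so this has the same law as a uniform choice.
            dest = b + np.argmax(~occ[ri, ci, b:], axis=1)
            occ[ri, ci, ch[ri, ci]] = False
            occ[ri, ci, dest] = True
            done[ri, ci, dest] = True
            free_rest[ri, ci] -= 1
            free_vel[ri, ci] += 1
        ri, ci = np.nonzero(to_vel)
        if ri.size:
            dest = np.argmax(~occ[ri, ci, :b], axis=1)
            occ[ri, ci, ch[ri, ci]] = False
            occ[ri, ci, dest] = True
            done[ri, ci, dest] = True
            free_vel[ri, ci] -= 1
            free_rest[ri, ci] += 1
        ri, ci = np.nonzero(stay)
        if ri.size:
            done[ri, ci, ch[ri, ci]] = True

    return LatticeState(occ, b, state.time)


def reorientation_step(
    state: LatticeState, rng: np.random.Generator
) -> LatticeState:
    """Uniform random permutation of the velocity channels at every node."""
    occ = state.occupancy.copy()
    b = state.b
    H, W, _ = occ.shape
    perm = np.argsort(rng.random((H, W, b)), axis=2)
    occ[:, :, :b] = np.take_along_axis(occ[:, :, :b], perm, axis=2)
    return LatticeState(occ, b, state.time)


def propagation_step(state: LatticeState) -> LatticeState:
    """Deterministic shift: the cell in velocity channel i moves to the
    neighbour node in direction c_i, same channel, with periodic wrap."""
    occ = state.occupancy.copy()
    for i, (dr, dc) in enumerate(CHANNEL_VECTORS[: state.b]):
        occ[:, :, i] = np.roll(state.occupancy[:, :, i], shift=(dr, dc), axis=(0, 1))
    return LatticeState(occ, state.b, state.time)


def step(
    state: LatticeState, params: ModelParams, rng: np.random.Generator
) -> LatticeState:
    """One full automaton step: reaction, reorientation, propagation."""
    out = reaction_step(state, params, rng)
    out = reorientation_step(out, rng)
    out = propagation_step(out)
    out.time = state.time + 1
    return out


@dataclass
class SimulationResult:
    """Trajectory observables plus the final lattice state."""

    records: pd.DataFrame
    final_state: LatticeState
    extinct: bool
    snapshots: Optional[list] = None


def _observe(state: LatticeState) -> dict:
    n_tot = state.n_total
    return {
        "step": state.time,
        "n_total": n_tot,
        "n_rest": state.n_rest,
        "n_move": state.n_move,
        "rho_avg": averaged_density(state),
        "extinct": n_tot == 0,
    }


def run(
    initial_state: LatticeState,
    params: ModelParams,
    n_steps: int,
    record_every: int = 1,
    rng: Optional[np.random.Generator] = None,
    snapshot_every: Optional[int] = None,
) -> SimulationResult:
    """Iterate the automaton, recording observables at a fixed cadence.

    Terminates early (with the extinct flag raised and a final record
    emitted) when the population reaches the absorbing state n_total = 0.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    if record_every < 1:
        raise ValueError("record_every must be >= 1")
    if rng is None:
        rng = params.rng()

    state = initial_state.copy()
    records = [_observe(state)]
    snapshots = [] if snapshot_every else None
    if snapshot_every:
        snapshots.append((state.time, state.copy()))
    extinct = state.n_total == 0
    for _ in range(n_steps):
        if extinct:
            break
        state = step(state, params, rng)
        recorded = False
        if state.time % record_every == 0:
            records.append(_observe(state))
            recorded = True
        if snapshot_every and state.time % snapshot_every == 0:
            snapshots.append((state.time, state.copy()))
        if state.n_total == 0:
            extinct = True
            if not recorded:
                records.append(_observe(state))
    return SimulationResult(pd.DataFrame(records), state, extinct, snapshots)


def write_trajectory(records: pd.DataFrame, path) -> None:
    """Trajectory CSV: step, n_total, n_rest, n_move, rho_avg, extinct flag."""
    cols = ["step", "n_total", "n_rest", "n_move", "rho_avg", "extinct"]
    records.loc[:, cols].to_csv(path, index=False)


def write_snapshot(state: LatticeState, path) -> None:
    """Per-node (n_rest, n_move) grid in long CSV format (row, col, ...)."""
    n_rest = state.occupancy[:, :, state.b :].sum(axis=2)
    n_move = state.occupancy[:, :, : state.b].sum(axis=2)
    H, W = n_rest.shape
    rows, cols = np.divmod(np.arange(H * W), W)
    pd.DataFrame(
        {
            "row": rows,
            "col": cols,
            "n_rest": n_rest.ravel(),
            "n_move": n_move.ravel(),
        }
    ).to_csv(Path(path), index=False)
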