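"""The stochastic trial loop.

The model follows initial-state dynamics on a lattice where each site holds
at most one cell.  An elementary trial draws a site uniformly at random; a
vacant site ends the trial.  A cell attempts to divide with probability
p_div, otherwise to diffuse, into a uniformly drawn face direction; targets
outside the domain or occupied reject the attempt (no-flux boundaries).
Division succeeds with unit probability.  A diffusion jump succeeds with
probability exp(n*eps_cc + m*eps_cs), where n is the number of occupied
neighbors and m the number of adhesive wall contacts at the cell's current
site, times exp(eps_g) if the jump is upward.  After every trial the model
time advances by |ln rho| / N, so one Monte Carlo step (MCS) corresponds on
average to N trials.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import IntEnum
from typing import NamedTuple

import numpy as np

from . import _kernel
from .analysis import KineticsTrace, Snapshot
from .geometry import LatticeDomain
from .params import SimParams

DEFAULT_MAX_TRIALS = 10**10


class Outcome(IntEnum):
    """Result of one elementary trial."""

    NOOP = _kernel.NOOP  # vacant site drawn
    MOVED = _kernel.MOVED
    DIVIDED = _kernel.DIVIDED
    REJECTED = _kernel.REJECTED


class MoveContext(NamedTuple):
    """Local context of a proposed diffusion jump, evaluated at the cell's
    current site (initial-state dynamics)."""

    n: int  # occupied nearest neighbors, 0..6
    m: int  # adhesive wall contacts, 0..6
    is_up: bool  # proposed jump increases z


class RngStream:
    """Seeded splitmix64 stream: identical seed, identical draw sequence."""

    def __init__(self, seed: int):
        self.seed = int(seed)
        self.state = np.array([np.uint64(self.seed & 0xFFFFFFFFFFFFFFFF)],
                              dtype=np.uint64)

    def u64(self) -> int:
        return int(_kernel.next_u64(self.state))

    def uniform(self) -> float:
        """rho on (0, 1]."""
        return float(_kernel.uniform(self.state))

    def randint(self, n: int) -> int:
        """Uniform integer in [0, n)."""
        if n <= 0:
            raise ValueError("n must be positive")
        return int(_kernel.randbelow(self.state, n))

    def spawn(self) -> "RngStream":
        """An independent child stream (seeded from this stream)."""
        return RngStream(self.u64())


@dataclass
class SimState:
    """Mutable simulation state shared with the compiled kernel."""

    occ: np.ndarray  # uint8 occupancy grid (full slab shape)
    counters: np.ndarray  # int64[2] = (n_cells, trials)
    time_box: np.ndarray  # float64[1] = elapsed time in MCS

    @property
    def n_cells(self) -> int:
        return int(self.counters[0])

    @property
    def trials(self) -> int:
        return int(self.counters[1])

    @property
    def time(self) -> float:
        return float(self.time_box[0])

    def coords(self) -> np.ndarray:
        return np.argwhere(self.occ.astype(bool)).astype(np.int32)

    def theta(self, domain: LatticeDomain) -> float:
        return self.n_cells / domain.N

    def check_invariants(self, domain: LatticeDomain) -> None:
        """Debug assertions: single occupancy and containment."""
        if not (self.occ <= 1).all():
            raise AssertionError("multiple occupancy detected")
        if (self.occ.astype(bool) & ~domain.mask).any():
            raise AssertionError("occupied site outside the domain")
        if int(self.occ.sum()) != self.n_cells:
            raise AssertionError("n_cells counter out of sync")


def seed_cells(domain: LatticeDomain, n_seed: int, rng: RngStream) -> SimState:
    """Occupy n_seed distinct in-domain sites uniformly at random (t = 0)."""
    if n_seed < 1:
        raise ValueError(f"n_seed={n_seed} must be >= 1")
    if n_seed > domain.N:
        raise ValueError(f"n_seed={n_seed} exceeds domain size N={domain.N}")
    # Floyd's algorithm: uniform sample without replacement in O(n_seed).
    chosen: set[int] = set()
    for j in range(domain.N - n_seed, domain.N):
        t = rng.randint(j + 1)
        chosen.add(j if t in chosen else t)
    occ = np.zeros(domain.dims, dtype=np.uint8)
    picks = domain.sites[sorted(chosen)]
    occ[picks[:, 0], picks[:, 1], picks[:, 2]] = 1
    return SimState(
        occ=occ,
        counters=np.array([n_seed, 0], dtype=np.int64),
        time_box=np.zeros(1, dtype=np.float64),
    )


def diffusion_acceptance(ctx: MoveContext, params: SimParams) -> float:
    """exp(n*eps_cc + m*eps_cs [+ eps_g if upward]); in (0, 1] for
    attractive (non-positive) energies."""
    e = ctx.n * params.eps_cc + ctx.m * params.eps_cs
    if ctx.is_up:
        e += params.eps_g
    return math.exp(e)


def acceptance_table(params: SimParams) -> np.ndarray:
    """Precomputed acc[n, m, is_up] = diffusion_acceptance((n, m, is_up))
    for all reachable contexts (n + m <= 6), shared with the kernels."""
    acc = np.zeros((7, 7, 2))
    for n in range(7):
        for m in range(7):
            for up in (0, 1):
                acc[n, m, up] = diffusion_acceptance(
                    MoveContext(n=n, m=m, is_up=bool(up)), params
                )
    return acc


def advance_time(domain: LatticeDomain, rng: RngStream) -> float:
    """One time increment |ln rho| / N; rho is drawn on (0, 1] so the
    increment is finite."""
    return -math.log(rng.uniform()) / domain.N


def mc_trial(
    state: SimState, domain: LatticeDomain, params: SimParams, rng: RngStream
) -> Outcome:
    """Execute one elementary trial in place and return its outcome."""
    out = _kernel.trial(
        state.occ, domain.mask, domain.wall_m, domain.sites,
        domain.periodic, params.p_div, acceptance_table(params),
        rng.state, state.time_box,
    )
    state.counters[1] += 1
    if out == _kernel.DIVIDED:
        state.counters[0] += 1
    return Outcome(out)


def make_cell_list(
    state: SimState, domain: LatticeDomain
) -> tuple[np.ndarray, np.ndarray]:
    """Occupied-cell list and site->row map for the event-driven kernel."""
    coords = state.coords()
    cells = np.zeros((domain.N, 3), dtype=np.int32)
    cells[: len(coords)] = coords
    slot = np.full(domain.dims, -1, dtype=np.int32)
    slot[coords[:, 0], coords[:, 1], coords[:, 2]] = np.arange(
        len(coords), dtype=np.int32
    )
    return cells, slot


def advance_trials(
    state: SimState,
    domain: LatticeDomain,
    params: SimParams,
    rng: RngStream,
    n_trials: int,
    cells: np.ndarray | None = None,
    cell_slot: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Advance the state by exactly n_trials elementary trials (event-driven;
    statistically identical to n_trials calls of mc_trial).  Returns the
    cell-list arrays so repeated calls can reuse them."""
    if cells is None or cell_slot is None:
        cells, cell_slot = make_cell_list(state, domain)
    rec_t = np.zeros(1)
    rec_n = np.zeros(1, dtype=np.int64)
    rec_fill = np.zeros(1, dtype=np.int64)
    target = state.trials + int(n_trials)
    _kernel.run_events(
        state.occ, domain.mask, domain.wall_m, domain.sites, domain.periodic,
        params.p_div, acceptance_table(params),
        rng.state, state.time_box, state.counters, cells, cell_slot,
        2**62, target, 2**62, rec_t, rec_n, rec_fill,
    )
    return cells, cell_slot


def _theta_to_count(theta: float, N: int) -> int:
    """Smallest cell count whose occupancy reaches theta."""
    return int(math.ceil(theta * N - 1e-9))


def _snapshot(state: SimState, domain: LatticeDomain, params: SimParams) -> Snapshot:
    meta = {
        "params": params.to_dict(),
        "dims": list(domain.dims),
        "N": domain.N,
        "periodic": domain.periodic,
        "R": domain.R,
        "z_split": domain.z_split,
    }
    return Snapshot(
        coords=state.coords(),
        time=state.time,
        theta=state.n_cells / domain.N,
        meta=meta,
    )


def run_until_occupancy(
    domain: LatticeDomain,
    params: SimParams,
    rng: RngStream | None = None,
    record_every: int | None = None,
    max_trials: int = DEFAULT_MAX_TRIALS,
    state: SimState | None = None,
) -> tuple[KineticsTrace, list[Snapshot]]:
    """Run from a random seeding until occupancy reaches params.theta_stop.

    Kinetics (time, n_cells) are recorded every ``record_every`` trials
    (default: every N trials, about one MCS) and a snapshot is frozen the
    first time occupancy crosses each value in params.snapshot_thetas.  A
    trial budget guards against unreachable targets (e.g. p_div = 0); on
    exhaustion a warning is issued and the partial results are returned.
    """
    if rng is None:
        rng = RngStream(params.rng_seed)
    N = domain.N
    stop_n = _theta_to_count(params.theta_stop, N)
    if params.n_seed > N:
        raise ValueError(f"n_seed={params.n_seed} exceeds N={N}")
    if record_every is None:
        record_every = N
    if state is None:
        state = seed_cells(domain, params.n_seed, rng)

    snap_counts = [_theta_to_count(t, N) for t in params.snapshot_thetas]
    snapshots: list[Snapshot] = []
    pending = list(snap_counts)
    # Snapshot thresholds already satisfied by the initial configuration.
    while pending and state.n_cells >= pending[0]:
        snapshots.append(_snapshot(state, domain, params))
        pending.pop(0)

    rec_cap = 4096
    rec_t = np.zeros(rec_cap, dtype=np.float64)
    rec_n = np.zeros(rec_cap, dtype=np.int64)
    rec_fill = np.zeros(1, dtype=np.int64)
    # The seeded configuration is the first kinetics point.
    rec_t[0] = state.time
    rec_n[0] = state.n_cells
    rec_fill[0] = 1

    cells, cell_slot = make_cell_list(state, domain)
    acc = acceptance_table(params)
    exhausted = False
    while state.n_cells < stop_n and not exhausted:
        target = pending[0] if pending else stop_n
        while True:
            status = _kernel.run_events(
                state.occ, domain.mask, domain.wall_m, domain.sites,
                domain.periodic, params.p_div, acc,
                rng.state, state.time_box, state.counters,
                cells, cell_slot,
                target, max_trials, record_every, rec_t, rec_n, rec_fill,
            )
            if status == _kernel.RECORD_FULL:
                rec_cap *= 2
                rec_t = np.concatenate([rec_t, np.zeros(rec_cap - len(rec_t))])
                rec_n = np.concatenate(
                    [rec_n, np.zeros(rec_cap - len(rec_n), dtype=np.int64)]
                )
                continue
            break
        if status == _kernel.TRIALS_EXHAUSTED:
            warnings.warn(
                f"trial budget {max_trials} exhausted at n_cells="
                f"{state.n_cells} (theta={state.n_cells / N:.4f}) before "
                f"reaching theta_stop={params.theta_stop}; returning partial "
                "results",
                RuntimeWarning,
                stacklevel=2,
            )
            exhausted = True
        while pending and state.n_cells >= pending[0]:
            snapshots.append(_snapshot(state, domain, params))
            pending.pop(0)

    # Final kinetics point.
    k = int(rec_fill[0])
    if k == 0 or rec_n[k - 1] != state.n_cells or rec_t[k - 1] != state.time:
        if k >= len(rec_t):
            rec_t = np.concatenate([rec_t, np.zeros(1)])
            rec_n = np.concatenate([rec_n, np.zeros(1, dtype=np.int64)])
        rec_t[k] = state.time
        rec_n[k] = state.n_cells
        k += 1
    trace = KineticsTrace(
        time=rec_t[:k].copy(),
        n_cells=rec_n[:k].copy(),
        N=N,
        meta={"params": params.to_dict(), "dims": list(domain.dims)},
    )
    return trace, snapshots
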