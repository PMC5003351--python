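"""Validation harness: lattice-gas aggregation threshold and analytic
single-cell equilibrium oracles.

Aggregation threshold
---------------------
An attractive lattice gas on the simple cubic lattice phase-separates
(aggregates) when the nearest-neighbor attraction exceeds a critical
magnitude of about 0.89 kT (the Ising critical coupling 0.2216544 mapped
through eps = 4 J / kT).  The scan measures this on a periodic cube at half
filling with division disabled, using the engine's own initial-state
diffusion dynamics (the stationary distribution is the equilibrium one by
detailed balance).

The order parameter is the replicate-averaged largest-cluster mass
fraction, with clusters defined by the bond-activated (Coniglio-Klein)
droplet rule: two occupied nearest-neighbor sites belong to the same droplet
if a bond between them is open, which happens with probability
1 - exp(-|eps_cc| / 2).  Droplets defined this way acquire a giant component
exactly at the thermodynamic transition, so the 0.5 crossing of the order
parameter tracks the aggregation threshold.  Purely geometric (face-adjacent)
clusters are reported alongside but cannot detect the threshold at half
filling: occupancy 0.5 is far above the site-percolation threshold 0.3116,
so a geometric giant cluster exists even in the non-interacting gas.

Single-cell oracles
-------------------
With division disabled, a single cell is a biased random walker whose
stationary law follows from detailed balance of the jump acceptances:

* barometric: with gravity eps_g < 0 in a 1 x 1 x H column,
  P(z) ∝ exp(eps_g * z) (truncated geometric);
* wall affinity: with eps_cs < 0, site occupancy ∝ exp(-m * eps_cs);
* free walker: with all energies zero, MSD(t) = t (one accepted unit jump
  per MCS on average);
* early growth: for small p_div and dilute occupancy the population grows
  exponentially at rate ~ p_div per MCS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from . import _kernel
from .analysis import fit_growth_rate
from .engine import RngStream, advance_trials, seed_cells, run_until_occupancy
from .geometry import LatticeDomain, build_box_domain, build_periodic_domain, build_well_domain
from .params import SimParams


# ------------------------------------------------------------------------
# Cluster labeling on periodic lattices, with optional bond activation.
# ------------------------------------------------------------------------
def largest_cluster_fraction(
    occ: np.ndarray,
    bond_p: float = 1.0,
    rng: RngStream | None = None,
    periodic: bool = True,
) -> float:
    """Mass fraction of the largest cluster of occupied sites.

    Adjacent (face-neighbor) occupied pairs are joined with probability
    ``bond_p``; ``bond_p = 1`` gives plain geometric connectivity, while
    ``bond_p = 1 - exp(-|eps|/2)`` gives Coniglio-Klein droplets.  Wrapping
    across the boundaries is included when ``periodic``.
    """
    occb = occ.astype(bool)
    n_occ = int(occb.sum())
    if n_occ == 0:
        return 0.0
    idx = np.full(occ.shape, -1, dtype=np.int64)
    idx[occb] = np.arange(n_occ)
    rows_all, cols_all = [], []
    for ax in range(3):
        if periodic:
            nb = np.roll(occb, -1, axis=ax)  # nb[i] <=> site i+1 occupied
            pair = occb & nb
            r = idx[pair]
            c = np.roll(idx, -1, axis=ax)[pair]
        else:
            sl_lo = [slice(None)] * 3
            sl_hi = [slice(None)] * 3
            sl_lo[ax] = slice(0, -1)
            sl_hi[ax] = slice(1, None)
            pair = occb[tuple(sl_lo)] & occb[tuple(sl_hi)]
            r = idx[tuple(sl_lo)][pair]
            c = idx[tuple(sl_hi)][pair]
        rows_all.append(r)
        cols_all.append(c)
    rows = np.concatenate(rows_all)
    cols = np.concatenate(cols_all)
    if bond_p < 1.0:
        if rng is None:
            raise ValueError("bond_p < 1 requires an RngStream")
        u = np.array([rng.uniform() for _ in range(len(rows))])
        keep = u < bond_p
        rows, cols = rows[keep], cols[keep]
    graph = sparse.coo_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(n_occ, n_occ)
    )
    _, labels = sparse.csgraph.connected_components(graph, directed=False)
    return int(np.bincount(labels).max()) / n_occ


def ck_bond_probability(eps_cc: float) -> float:
    """Coniglio-Klein bond probability 1 - exp(-|eps_cc| / 2)."""
    return 1.0 - math.exp(-abs(eps_cc) / 2.0)


# ------------------------------------------------------------------------
@dataclass(frozen=True)
class ThresholdScan:
    """Result of an aggregation-threshold scan."""

    eps_grid: np.ndarray  # attraction magnitudes |eps_cc|
    order_parameter: np.ndarray  # mean largest-droplet fraction per |eps|
    order_spread: np.ndarray  # std over replicates
    geometric_fraction: np.ndarray  # plain face-connected fraction (diagnostic)
    estimate: float | None  # interpolated 0.5 crossing; None if inconclusive
    L: int
    occupancy: float
    equil_mcs: float
    measure_mcs: float
    n_seeds: int

    @property
    def conclusive(self) -> bool:
        return self.estimate is not None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "abs_eps_cc": self.eps_grid,
                "largest_droplet_fraction": self.order_parameter,
                "spread": self.order_spread,
                "largest_geometric_fraction": self.geometric_fraction,
            }
        )


def _interpolate_crossing(x: np.ndarray, y: np.ndarray, level: float = 0.5) -> float | None:
    """|eps| where the averaged order parameter crosses ``level`` rising.

    Uses the last upward crossing so residual noise below the transition
    cannot pull the estimate down.  Returns None when no bracketing pair
    exists (inconclusive scan).
    """
    crossings = [
        i for i in range(len(x) - 1) if y[i] < level <= y[i + 1]
    ]
    if not crossings:
        return None
    i = crossings[-1]
    f = (level - y[i]) / (y[i + 1] - y[i])
    return float(x[i] + f * (x[i + 1] - x[i]))


def equilibrate_lattice_gas(
    domain: LatticeDomain,
    eps_cc: float,
    occupancy: float,
    rng: RngStream,
    mcs: float,
):
    """Seed round(occupancy * N) cells and run pure-diffusion dynamics for
    ``mcs`` Monte Carlo steps; returns the mutable state for measurement."""
    n = int(round(occupancy * domain.N))
    state = seed_cells(domain, n, rng)
    params = SimParams(
        eps_cc=-abs(eps_cc), eps_cs=0.0, eps_g=0.0, p_div=0.0,
        n_seed=n, theta_stop=1.0, snapshot_thetas=(1.0,),
    )
    advance_trials(state, domain, params, rng, int(mcs) * domain.N)
    return state


def estimate_aggregation_threshold(
    eps_grid=None,
    L: int = 12,
    occupancy: float = 0.5,
    equil_mcs: float = 2e4,
    measure_mcs: float = 1e4,
    n_measure: int = 50,
    n_seeds: int = 3,
    seed: int = 12345,
    cluster_rule: str = "droplet",
) -> ThresholdScan:
    """Scan the cell-cell attraction magnitude and estimate where the
    largest-droplet mass fraction crosses 0.5.

    For each |eps| on the grid (default 0.3 to 1.5, step 0.1) and each
    replicate seed, round(occupancy * L^3) cells are placed at random on a
    periodic L^3 lattice, equilibrated with the engine's diffusion dynamics
    (division disabled) for ``equil_mcs`` MCS, and the order parameter is
    averaged over ``n_measure`` samples spread across ``measure_mcs`` further
    MCS.  ``cluster_rule`` is "droplet" (bond-activated, detects the
    thermodynamic threshold) or "geometric" (plain face connectivity).
    """
    if eps_grid is None:
        eps_grid = np.round(np.arange(0.3, 1.5001, 0.1), 10)
    eps_grid = np.asarray(sorted(abs(float(e)) for e in eps_grid))
    if L < 4:
        raise ValueError("L must be >= 4")
    if cluster_rule not in ("droplet", "geometric"):
        raise ValueError(f"unknown cluster_rule {cluster_rule!r}")
    domain = build_periodic_domain(L)
    master = RngStream(seed)
    sample_gap = max(1, int(measure_mcs / n_measure)) * domain.N

    order = np.zeros(len(eps_grid))
    spread = np.zeros(len(eps_grid))
    geom = np.zeros(len(eps_grid))
    for k, eps in enumerate(eps_grid):
        params = SimParams(
            eps_cc=-eps, eps_cs=0.0, eps_g=0.0, p_div=0.0,
            n_seed=1, theta_stop=1.0, snapshot_thetas=(1.0,),
        )
        bond_p = ck_bond_probability(eps)
        rep_means = []
        rep_geo = []
        for _ in range(n_seeds):
            rng = master.spawn()
            state = seed_cells(domain, int(round(occupancy * domain.N)), rng)
            clist = advance_trials(
                state, domain, params, rng, int(equil_mcs) * domain.N
            )
            vals, geos = [], []
            for _ in range(n_measure):
                advance_trials(state, domain, params, rng, sample_gap, *clist)
                if cluster_rule == "droplet":
                    vals.append(
                        largest_cluster_fraction(state.occ, bond_p, rng=rng)
                    )
                else:
                    vals.append(largest_cluster_fraction(state.occ))
                geos.append(largest_cluster_fraction(state.occ))
            rep_means.append(np.mean(vals))
            rep_geo.append(np.mean(geos))
        order[k] = np.mean(rep_means)
        spread[k] = np.std(rep_means)
        geom[k] = np.mean(rep_geo)

    estimate = _interpolate_crossing(eps_grid, order, 0.5)
    return ThresholdScan(
        eps_grid=eps_grid,
        order_parameter=order,
        order_spread=spread,
        geometric_fraction=geom,
        estimate=estimate,
        L=L,
        occupancy=occupancy,
        equil_mcs=equil_mcs,
        measure_mcs=measure_mcs,
        n_seeds=n_seeds,
    )


# ------------------------------------------------------------------------
# Single-cell equilibrium oracles.
# ------------------------------------------------------------------------
def truncated_geometric_mean(eps_g: float, H: int) -> float:
    """Closed-form mean of P(z) ∝ exp(eps_g * z) on z = 0..H-1."""
    z = np.arange(H)
    w = np.exp(eps_g * z)
    return float((z * w).sum() / w.sum())


def _sample_single_cell(domain, params, rng, n_samples, sample_every=None):
    """Time-averaged per-site visit counts of a single diffusing cell."""
    state = seed_cells(domain, 1, rng)
    counts = np.zeros(domain.dims, dtype=np.int64)
    if sample_every is None:
        sample_every = domain.N
    from .engine import acceptance_table

    _kernel.run_sample_occupancy(
        state.occ, domain.mask, domain.wall_m, domain.sites, domain.periodic,
        params.p_div, acceptance_table(params),
        rng.state, state.time_box, state.counters,
        n_samples, sample_every, counts,
    )
    return counts


def barometric_oracle(
    eps_g: float = -0.03, H: int = 80, n_samples: int = 8_000_000, seed: int = 7
) -> dict:
    """Stationary mean height of one cell under gravity in a 1 x 1 x H
    column vs the truncated-geometric closed form."""
    domain = build_box_domain((1, 1, H))
    params = SimParams(eps_cc=0.0, eps_cs=0.0, eps_g=eps_g, p_div=0.0,
                       n_seed=1, theta_stop=1.0, snapshot_thetas=(1.0,))
    # Every trial selects the single column cell when N == H; sampling each
    # ~N/4 trials keeps samples cheap but weakly correlated.
    counts = _sample_single_cell(
        domain, params, RngStream(seed), n_samples, sample_every=max(1, H // 4)
    )
    prof = counts[0, 0, :]
    measured = float((np.arange(H) * prof).sum() / prof.sum())
    target = truncated_geometric_mean(eps_g, H)
    return {
        "name": "barometric_mean_height",
        "value": measured,
        "target": target,
        "rel_error": abs(measured - target) / target,
        "tolerance": 0.05,
        "passed": abs(measured - target) / target < 0.05,
    }


def wall_affinity_oracle(
    eps_cs: float = -1.2, box: int = 6, n_samples: int = 3_000_000, seed: int = 8
) -> dict:
    """Occupancy ratio of wall-contact (m = 1) to interior (m = 0) sites for
    one adhesive cell vs the detailed-balance prediction exp(-eps_cs)."""
    domain = build_box_domain((box, box, box))
    params = SimParams(eps_cc=0.0, eps_cs=eps_cs, eps_g=0.0, p_div=0.0,
                       n_seed=1, theta_stop=1.0, snapshot_thetas=(1.0,))
    counts = _sample_single_cell(
        domain, params, RngStream(seed), n_samples,
        sample_every=max(1, domain.N // 8),
    )
    m = domain.wall_m
    mean_contact = counts[m == 1].mean()
    mean_interior = counts[m == 0].mean()
    measured = float(mean_contact / mean_interior)
    target = math.exp(-eps_cs)
    return {
        "name": "wall_affinity_occupancy_ratio",
        "value": measured,
        "target": target,
        "rel_error": abs(measured - target) / target,
        "tolerance": 0.10,
        "passed": abs(measured - target) / target < 0.10,
    }


def msd_oracle(
    box: int = 21, t_max: int = 30, n_segments: int = 600, seed: int = 9
) -> dict:
    """Mean squared displacement of a free walker: slope vs t should be 1
    lattice-unit^2 per MCS (one accepted unit jump per MCS on average).

    Runs independent segments in an open box large enough that the walker
    never reaches a wall within t_max.
    """
    domain = build_box_domain((box, box, box))
    params = SimParams(eps_cc=0.0, eps_cs=0.0, eps_g=0.0, p_div=0.0,
                       n_seed=1, theta_stop=1.0, snapshot_thetas=(1.0,))
    from .engine import acceptance_table

    master = RngStream(seed)
    acc = acceptance_table(params)
    start = (box // 2, box // 2, box // 2)
    times = np.arange(1, t_max + 1, dtype=float)
    sq = np.zeros(t_max)
    rec_t = np.zeros(1)
    rec_n = np.zeros(1, dtype=np.int64)
    for _ in range(n_segments):
        rng = master.spawn()
        occ = np.zeros(domain.dims, dtype=np.uint8)
        occ[start] = 1
        counters = np.array([1, 0], dtype=np.int64)
        time_box = np.zeros(1)
        for i in range(t_max):
            rec_fill = np.zeros(1, dtype=np.int64)
            _kernel.run_chunk(
                occ, domain.mask, domain.wall_m, domain.sites, domain.periodic,
                params.p_div, acc,
                rng.state, time_box, counters, 2**62,
                counters[1] + domain.N, 2**62, rec_t, rec_n, rec_fill,
            )
            pos = np.argwhere(occ)[0]
            sq[i] += float(((pos - np.array(start)) ** 2).sum())
    msd = sq / n_segments
    slope = float(np.linalg.lstsq(
        times.reshape(-1, 1), msd, rcond=None
    )[0][0])
    return {
        "name": "free_walker_msd_slope",
        "value": slope,
        "target": 1.0,
        "rel_error": abs(slope - 1.0),
        "tolerance": 0.10,
        "passed": abs(slope - 1.0) < 0.10,
    }


def early_growth_oracle(
    p_div: float = 1e-2,
    dims: tuple[int, int, int] = (30, 30, 40),
    R: float = 15.0,
    z_split: int = 15,
    n_seeds: int = 5,
    seed: int = 10,
) -> dict:
    """Replicate-averaged exponential growth rate in the dilute window vs
    p_div (free diffusion: all adhesion energies zero)."""
    domain = build_well_domain(dims, R=R, z_split=z_split)
    rates = []
    for k in range(n_seeds):
        params = SimParams(
            eps_cc=0.0, eps_cs=0.0, eps_g=0.0, p_div=p_div, n_seed=5,
            theta_stop=0.025, snapshot_thetas=(0.025,), rng_seed=seed + k,
        )
        trace, _ = run_until_occupancy(domain, params)
        rates.append(fit_growth_rate(trace, window=(10 / domain.N, 0.02)))
    rate = float(np.mean(rates))
    return {
        "name": "early_growth_rate",
        "value": rate,
        "target": p_div,
        "rel_error": abs(rate - p_div) / p_div,
        "tolerance": 0.20,
        "passed": abs(rate - p_div) / p_div < 0.20,
        "replicates": [float(r) for r in rates],
    }


def run_oracle_suite(fast: bool = False) -> pd.DataFrame:
    """Run the four analytic oracles with fixed seeds and return a report
    table (statistic, measured value, analytic target, tolerance, pass)."""
    scale = 10 if fast else 1
    results = [
        barometric_oracle(n_samples=8_000_000 // scale),
        wall_affinity_oracle(n_samples=3_000_000 // scale),
        msd_oracle(n_segments=600 // scale),
        early_growth_oracle(n_seeds=5 if not fast else 2),
    ]
    return pd.DataFrame(results)
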