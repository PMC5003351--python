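"""Numba-compiled core: RNG and the elementary Monte Carlo trial loop.

Everything here operates on plain numpy arrays so it can be jit-compiled;
the user-facing wrappers live in :mod:`microwell_mc.engine`.

Random numbers come from a splitmix64 generator with an explicit one-word
state passed into every kernel, which keeps runs reproducible and lets the
single-trial path (used by tests) and the bulk loops consume the same kind
of stream.  Uniform variates are mapped to (0, 1] so that ``|ln rho|`` is
always finite.

Diffusion acceptance probabilities depend only on (n, m, is_up) with
n + m <= 6, so every kernel receives them as a precomputed 7 x 7 x 2 table
``acc[n, m, is_up] = exp(n*eps_cc + m*eps_cs + is_up*eps_g)``.

Two bulk drivers exist:

* :func:`run_chunk` — the literal per-trial loop;
* :func:`run_events` — an exact event-driven equivalent that skips runs of
  vacant-site trials: the number of trials up to and including the next
  occupied-site hit is geometric with success probability theta, and the
  time contributed by j trials is a Gamma(j) / N variate (a sum of j unit
  exponentials), drawn lazily at recording boundaries.  Both samplings are
  exact in distribution, so the two drivers generate the same stochastic
  process; only the per-seed draw sequences differ.

Draw order within one trial of the literal driver (fixed, part of the
reproducibility contract): site index, branch rho, direction,
diffusion-acceptance rho (only when a diffusion move reaches a vacant
in-domain target), time rho.
"""

import numpy as np
from numba import njit, uint64

# Direction order: +x, -x, +y, -y, +z, -z (index 4 is the upward jump).
_DX = np.array([1, -1, 0, 0, 0, 0], dtype=np.int64)
_DY = np.array([0, 0, 1, -1, 0, 0], dtype=np.int64)
_DZ = np.array([0, 0, 0, 0, 1, -1], dtype=np.int64)

# Trial outcome codes.
NOOP, MOVED, DIVIDED, REJECTED = 0, 1, 2, 3

# Chunk-run exit statuses.
REACHED_TARGET, TRIALS_EXHAUSTED, RECORD_FULL = 0, 1, 2


# ---------------------------------------------------------------- RNG ----
@njit(cache=True, inline="always")
def next_u64(rng):
    """Advance the splitmix64 state (rng: uint64[1]) and return 64 bits."""
    rng[0] = rng[0] + uint64(0x9E3779B97F4A7C15)
    z = rng[0]
    z = (z ^ (z >> uint64(30))) * uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> uint64(27))) * uint64(0x94D049BB133111EB)
    return z ^ (z >> uint64(31))


@njit(cache=True, inline="always")
def uniform(rng):
    """Uniform variate on (0, 1] with 53-bit resolution."""
    return (np.float64(next_u64(rng) >> uint64(11)) + 1.0) * (2.0**-53)


@njit(cache=True, inline="always")
def randbelow(rng, n):
    """Uniform integer in [0, n) by rejection (exactly unbiased)."""
    nn = uint64(n)
    thresh = (uint64(0) - nn) % nn  # 2**64 mod n
    u = next_u64(rng)
    while u < thresh:
        u = next_u64(rng)
    return np.int64(u % nn)


@njit(cache=True, inline="always")
def fast_randbelow(rng, n):
    """Uniform integer in [0, n): multiply-shift (floor(u * n / 2**64),
    division-free; bias O(n / 2**64) is negligible for n < 2**32)."""
    u = next_u64(rng)
    nn = uint64(n)
    uh = u >> uint64(32)
    ul = u & uint64(0xFFFFFFFF)
    return np.int64((uh * nn + ((ul * nn) >> uint64(32))) >> uint64(32))


@njit(cache=True, inline="always")
def standard_normal(rng):
    """Box-Muller standard normal."""
    u1 = uniform(rng)
    u2 = uniform(rng)
    return np.sqrt(-2.0 * np.log(u1)) * np.cos(6.283185307179586 * u2)


@njit(cache=True)
def gamma_int(rng, k):
    """Gamma(k, 1) variate for integer shape k >= 0 (sum of k unit
    exponentials).  Small shapes sum logs directly; larger shapes use the
    Marsaglia-Tsang squeeze, which is exact."""
    if k <= 0:
        return 0.0
    if k < 16:
        s = 0.0
        for _ in range(k):
            s -= np.log(uniform(rng))
        return s
    d = k - 1.0 / 3.0
    c = 1.0 / np.sqrt(9.0 * d)
    while True:
        x = standard_normal(rng)
        v = 1.0 + c * x
        if v <= 0.0:
            continue
        v = v * v * v
        u = uniform(rng)
        if np.log(u) < 0.5 * x * x + d - d * v + d * np.log(v):
            return d * v


# -------------------------------------------------------------- trial ----
@njit(cache=True, inline="always")
def _count_occupied_nn(occ, x, y, z, periodic):
    nx, ny, nz = occ.shape
    n = 0
    for k in range(6):
        tx = x + _DX[k]
        ty = y + _DY[k]
        tz = z + _DZ[k]
        if periodic:
            tx %= nx
            ty %= ny
            tz %= nz
        elif tx < 0 or tx >= nx or ty < 0 or ty >= ny or tz < 0 or tz >= nz:
            continue
        if occ[tx, ty, tz]:
            n += 1
    return n


@njit(cache=True, inline="always")
def _attempt(occ, mask, wall, periodic, p_div, acc, rng, x, y, z):
    """Division/diffusion attempt of the (occupied) cell at (x, y, z).

    Draws branch rho, direction, and (for diffusion reaching a vacant
    in-domain target) the acceptance rho, compared against the precomputed
    acceptance table acc[n, m, is_up].  Mutates occ; returns
    (outcome, tx, ty, tz) where (tx, ty, tz) is the target site of a MOVED
    or DIVIDED outcome.
    """
    nx, ny, nz = occ.shape
    rho = uniform(rng)
    k = fast_randbelow(rng, 6)
    tx = x + _DX[k]
    ty = y + _DY[k]
    tz = z + _DZ[k]
    ok = True
    if periodic:
        tx %= nx
        ty %= ny
        tz %= nz
    elif (tx < 0 or tx >= nx or ty < 0 or ty >= ny
          or tz < 0 or tz >= nz or not mask[tx, ty, tz]):
        ok = False
    if not ok or occ[tx, ty, tz]:
        return REJECTED, x, y, z
    if rho < p_div:
        occ[tx, ty, tz] = 1  # daughter cell; parent stays put
        return DIVIDED, tx, ty, tz
    n = _count_occupied_nn(occ, x, y, z, periodic)
    m = wall[x, y, z]
    up = 1 if _DZ[k] == 1 else 0  # gravity penalizes upward jumps only
    if uniform(rng) < acc[n, m, up]:
        occ[x, y, z] = 0
        occ[tx, ty, tz] = 1
        return MOVED, tx, ty, tz
    return REJECTED, x, y, z


@njit(cache=True)
def trial(occ, mask, wall, sites, periodic, p_div, acc, rng, time_box):
    """One elementary MC trial; mutates occ and time_box in place.

    A site is chosen uniformly over the N in-domain sites.  Vacant: the
    trial ends (NOOP).  Occupied: the cell divides if rho < p_div, else it
    tries to diffuse.  Either way a face direction is drawn uniformly; an
    out-of-domain or occupied target rejects the attempt.  Division succeeds
    with unit probability; diffusion succeeds with probability
    acc[n, m, is_up] = exp(n*eps_cc + m*eps_cs [+ eps_g if upward])
    evaluated at the cell's current site (initial-state dynamics).  Time
    then advances by |ln rho| / N.  Returns the outcome code (DIVIDED
    implies one new cell).
    """
    N = sites.shape[0]
    idx = randbelow(rng, N)
    x = np.int64(sites[idx, 0])
    y = np.int64(sites[idx, 1])
    z = np.int64(sites[idx, 2])
    outcome = NOOP
    if occ[x, y, z]:
        outcome, _, _, _ = _attempt(
            occ, mask, wall, periodic, p_div, acc, rng, x, y, z,
        )
    time_box[0] += -np.log(uniform(rng)) / N
    return outcome


@njit(cache=True)
def run_chunk(occ, mask, wall, sites, periodic, p_div, acc,
              rng, time_box, counters, stop_n, max_trials,
              record_every, rec_t, rec_n, rec_fill):
    """Literal per-trial loop: run until the cell count reaches stop_n, the
    trial budget max_trials is exhausted, or the record buffer fills.

    counters: int64[2] = (n_cells, trials), updated in place.
    Kinetics (time, n_cells) are appended every record_every trials.
    """
    N = sites.shape[0]
    inv_n = 1.0 / N
    until_rec = record_every - (counters[1] % record_every)
    status = TRIALS_EXHAUSTED
    t = time_box[0]
    while counters[1] < max_trials and counters[0] < stop_n:
        idx = fast_randbelow(rng, N)
        x = np.int64(sites[idx, 0])
        y = np.int64(sites[idx, 1])
        z = np.int64(sites[idx, 2])
        if occ[x, y, z]:
            out, _, _, _ = _attempt(
                occ, mask, wall, periodic, p_div, acc, rng, x, y, z,
            )
            if out == DIVIDED:
                counters[0] += 1
        t += -np.log(uniform(rng)) * inv_n
        counters[1] += 1
        until_rec -= 1
        if until_rec == 0:
            until_rec = record_every
            if rec_fill[0] >= rec_t.shape[0]:
                status = RECORD_FULL
                break
            rec_t[rec_fill[0]] = t
            rec_n[rec_fill[0]] = counters[0]
            rec_fill[0] += 1
    time_box[0] = t
    if counters[0] >= stop_n:
        status = REACHED_TARGET
    return status


@njit(cache=True)
def run_events(occ, mask, wall, sites, periodic, p_div, acc,
               rng, time_box, counters, cells, cell_slot,
               stop_n, max_trials, record_every, rec_t, rec_n, rec_fill):
    """Event-driven loop, exactly equivalent in distribution to run_chunk.

    Vacant-site trials are skipped in blocks: with n cells among N sites the
    number of trials up to and including the next occupied-site hit is
    geometric with success probability theta = n / N, and the hit cell is
    then uniform over the n cells, which requires the occupied-cell list
    ``cells`` (int32, capacity x 3) and the reverse map ``cell_slot``
    (site -> row, -1 when vacant), both maintained in place.

    Per-trial time increments are i.i.d. Exp(1)/N independent of the state,
    so the elapsed time of j trials is accumulated as Gamma(j)/N, drawn
    lazily whenever the clock must be observed (a kinetics record or chunk
    exit).  This is exact, not an approximation.
    """
    N = sites.shape[0]
    inv_n = 1.0 / N
    until_rec = record_every - (counters[1] % record_every)
    status = TRIALS_EXHAUSTED
    t = time_box[0]
    pending = np.int64(0)  # trials whose time increment is not yet drawn
    while counters[1] < max_trials and counters[0] < stop_n:
        n = counters[0]
        theta = n * inv_n
        if n >= N:
            k = np.int64(1)
        else:
            u = uniform(rng)
            k = np.int64(1) + np.int64(np.log(u) / np.log1p(-theta))
        if counters[1] + k > max_trials:
            # Budget ends inside the vacant gap; the truncated leading gap
            # trials are all vacant hits, so no event occurs.
            k = max_trials - counters[1]
            event = False
        else:
            event = True
        gap = k - 1 if event else k
        while gap > 0:
            j = gap if gap < until_rec else until_rec
            pending += j
            counters[1] += j
            until_rec -= j
            gap -= j
            if until_rec == 0:
                until_rec = record_every
                t += gamma_int(rng, pending) * inv_n
                pending = 0
                if rec_fill[0] >= rec_t.shape[0]:
                    time_box[0] = t
                    return RECORD_FULL
                rec_t[rec_fill[0]] = t
                rec_n[rec_fill[0]] = counters[0]
                rec_fill[0] += 1
        if not event:
            break
        c = fast_randbelow(rng, n)
        x = np.int64(cells[c, 0])
        y = np.int64(cells[c, 1])
        z = np.int64(cells[c, 2])
        out, tx, ty, tz = _attempt(
            occ, mask, wall, periodic, p_div, acc, rng, x, y, z,
        )
        if out == DIVIDED:
            cells[n, 0] = tx
            cells[n, 1] = ty
            cells[n, 2] = tz
            cell_slot[tx, ty, tz] = n
            counters[0] += 1
        elif out == MOVED:
            cells[c, 0] = tx
            cells[c, 1] = ty
            cells[c, 2] = tz
            cell_slot[x, y, z] = -1
            cell_slot[tx, ty, tz] = c
        pending += 1
        counters[1] += 1
        until_rec -= 1
        if until_rec == 0:
            until_rec = record_every
            t += gamma_int(rng, pending) * inv_n
            pending = 0
            if rec_fill[0] >= rec_t.shape[0]:
                time_box[0] = t
                return RECORD_FULL
            rec_t[rec_fill[0]] = t
            rec_n[rec_fill[0]] = counters[0]
            rec_fill[0] += 1
    t += gamma_int(rng, pending) * inv_n
    time_box[0] = t
    if counters[0] >= stop_n:
        status = REACHED_TARGET
    return status


@njit(cache=True)
def run_sample_occupancy(occ, mask, wall, sites, periodic, p_div, acc,
                         rng, time_box, counters,
                         n_samples, sample_every, visit_counts):
    """Run trials, accumulating the occupancy grid into visit_counts every
    sample_every trials, n_samples times.  Trial-cadence sampling gives an
    unbiased time average because the per-trial time increments are i.i.d.
    and independent of the state."""
    for s in range(n_samples):
        for _ in range(sample_every):
            out = trial(occ, mask, wall, sites, periodic, p_div, acc,
                        rng, time_box)
            counters[1] += 1
            if out == DIVIDED:
                counters[0] += 1
        visit_counts += occ
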