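# Methods

## Model

`microwell_mc` simulates the proliferation, diffusion, and aggregation of
cells in a single hemispherical-bottom microwell as a kinetic Monte Carlo
process on a simple cubic lattice.  Each lattice site is vacant or holds one
cell.  Cells perform two kinds of moves:

* **division** — a cell with a vacant nearest-neighbor (nn) site places a
  daughter there; the parent stays put;
* **diffusion** — a cell jumps to a vacant nn site.

An elementary trial draws a site uniformly at random among the N in-domain
sites.  If it is vacant the trial ends.  Otherwise a uniform ρ ∈ (0, 1]
selects division (ρ < p_div) or diffusion (ρ > p_div; the measure-zero tie
goes to diffusion), and a face direction is drawn uniformly among all six;
a target outside the domain or occupied rejects the attempt (no-flux
boundaries).  Division succeeds with unit probability.  Diffusion succeeds
with probability

    exp(n·ε_cc + m·ε_cs + [ε_g if the jump is upward])

where n is the number of occupied nn sites and m the number of adhesive
wall contacts, both evaluated at the cell's **current** site
(initial-state dynamics: single cells diffuse fast, cells inside aggregates
slowly; the destination's environment is ignored).  All energies are
dimensionless (units of k_BT) and non-positive.  Gravity applies only to
upward diffusion jumps, never to division placement.

After every trial the clock advances by |ln ρ| / N with a fresh ρ ∈ (0, 1],
so one Monte Carlo step (MCS) corresponds on average to N trials.  There is
no cell death, no collective aggregate motion, and no nutrient or oxygen
field; these are deliberate model boundaries, not omissions.

## Geometry

The default domain is a 60 × 60 × 80 slab cut to a hemisphere of radius
R = 30 below z = 30 and a cylinder of the same radius above it (0-based
indices, z up).  The axis sits at ((nx−1)/2, (ny−1)/2) = (29.5, 29.5) so the
mask is symmetric on the even lattice; membership is boundary-inclusive on
squared distances at integer site coordinates.  Positions outside the mask
or the slab are walls: they block moves and count toward m — except across
the top plane (z = 79), which blocks motion but contributes no adhesion,
because physically that plane crosses the culture medium.  N = 196,516 for
the default geometry (within 1% of the continuum volume ⅔πR³ + πR²h).

A fully in-domain box (`build_box_domain`, used by the single-cell oracles)
and a periodic cube (`build_periodic_domain`, used by the threshold scan)
share the same engine.

## Parameters

| name | default | meaning |
|------|---------|---------|
| ε_cc | −1.2 | cell–cell nn attraction; above the ~0.89 aggregation threshold, so cells form compact aggregates |
| ε_cs | 0 (−1.2 in the wall-adhesion regime) | cell–surface attraction at wall contacts |
| ε_g  | 0 (−0.03 in the gravity regime) | penalty exp(ε_g) on upward jumps; produces sedimentation with a ~33-layer gravitational height |
| p_div | 1e−4 (1, 1e−2 in other regimes) | division/diffusion rate ratio; real cell diffusion is fast relative to division, so small values are the physical regime |
| n_seed | 5 | initial cells, placed uniformly at random |
| ϑ_stop | 0.4 | terminal occupancy (fraction of N occupied) |
| snapshot ϑ | 0.2, 0.4 | occupancies at which configurations are frozen |

The five named presets `fig5`…`fig9` (see `microwell_mc.SCENARIOS`) cover:
no diffusion (p_div = 1), slow diffusion (1e−2), rapid diffusion (1e−4),
rapid diffusion + wall adhesion (ε_cs = −1.2), and rapid diffusion +
gravity (ε_g = −0.03), all at ε_cc = −1.2.

## Implementation notes

* **Drivers.**  The literal per-trial loop (`_kernel.run_chunk`) and an
  event-driven loop (`_kernel.run_events`) are both provided; the latter is
  the production driver.  It skips blocks of vacant-site trials using the
  fact that, at occupancy ϑ, the number of trials up to and including the
  next occupied-site hit is geometric(ϑ) and the hit cell is uniform over
  the cells; the time contributed by j trials is Gamma(j)/N (a sum of j
  unit exponentials), drawn lazily whenever the clock is observed.  Both
  samplings are exact in distribution — the two drivers simulate the same
  process, which a test verifies by comparing ensemble statistics.  They
  differ only in how many random draws they consume per unit of work, so
  per-seed trajectories are reproducible within a driver, not across
  drivers.
* **RNG.**  A splitmix64 generator with an explicit one-word state is
  compiled into the kernels; identical seeds give bit-identical runs, and
  the state can be handed between the single-trial path used in tests and
  the bulk loops.  The generator is unit-tested against an independent
  big-integer reference implementation.  Uniform variates live on (0, 1],
  which also guards the |ln ρ| time increment against ρ = 0.
* **Acceptance table.**  Diffusion acceptances depend only on
  (n, m, is_up) with n + m ≤ 6, so they are precomputed into a 7×7×2 table.
* **Direction proposal.**  Directions are drawn uniformly over all six
  faces and out-of-domain targets are rejected (rather than proposing only
  feasible directions), which keeps per-direction attempt rates uniform.
* **Kinetics cadence.**  (time, n_cells) is recorded every N trials
  (≈ 1 MCS) by default; snapshots are frozen the first time the cell count
  reaches ⌈ϑ·N⌉ for each requested ϑ.  A trial budget (default 10^10)
  terminates mis-parameterized runs (e.g. p_div = 0 with an unreachable
  ϑ_stop) with a warning instead of hanging.

## Analysis definitions

Clusters ("aggregates") are maximal face-connected components of occupied
sites — the same 6-neighbor topology the jump and adhesion rules use;
diagonal contacts do not connect.  `ClusterStats.sizes` covers every
component (they sum to the cell count); `n_aggregates(min_size=2)` counts
multicellular aggregates, since a minimum size is otherwise arbitrary.
Output ordering is deterministic (size descending, then lexicographic
centroid).  Note that aggregate counts are only meaningful while the well
is dilute: at the terminal occupancy ϑ = 0.4 the aggregates of every
diffusive regime have merged into a single percolating cluster holding
>95% of the cells (40% volume filling is above the percolation threshold
of compact blobs), and the rapid-diffusion regimes additionally carry an
equilibrium monomer/dimer vapor (detachment at rate e^{n·ε_cc}) that
inflates raw cluster counts.  The regime-comparison tests therefore
evaluate the aggregate population (counts and mean sizes of clusters of
at least two cells) at the ϑ = 0.2 snapshot, where aggregates are still
separate.  The rendered "cross-section along the main axis" is the union
of the two central slices (y = ny/2 − 1 and ny/2) projected together, since
an even lattice has no exact axial plane and a single slice would split
on-axis structures by parity.  The exponential growth rate is the
least-squares slope of ln n_cells vs time over the dilute window
ϑ ∈ [2·n_seed/N, 0.02], where each isolated cell divides at rate ≈ p_div
per MCS.

## Validation

**Aggregation threshold.**  The attractive lattice gas on the simple cubic
lattice phase-separates when |ε_cc| exceeds ≈ 0.89 (the Ising critical
coupling K_c ≈ 0.2217 mapped through ε = 4J/k_BT gives 0.8866).  The scan
(`estimate_aggregation_threshold`) runs the engine's own diffusion dynamics
(p_div = 0; the stationary law is the equilibrium one by detailed balance)
on a periodic 12³ lattice at half filling: 13 attraction magnitudes
0.3…1.5 in steps of 0.1, 3 replicate seeds each, 2×10⁴ MCS equilibration
and 10⁴ MCS of measurement (50 samples), chosen as the smallest budgets
that equilibrate the coarsening dynamics at this size.  The order parameter
is the replicate-averaged mass fraction of the largest **bond-activated
droplet**: occupied nn pairs are joined with probability
1 − exp(−|ε_cc|/2), the Coniglio–Klein prescription whose giant-droplet
onset coincides with the thermodynamic transition.  Plain geometric
(face-adjacent) clusters cannot detect the threshold at half filling —
occupancy 0.5 is far above the simple-cubic site-percolation threshold
0.3116, so a geometric giant cluster exists even at ε = 0 (the scan reports
that column too, as a diagnostic).  The estimate is the interpolated |ε|
where the averaged order parameter last crosses 0.5 rising; a
non-bracketing scan is reported as inconclusive, never extrapolated.  At
L = 12 the measured crossing lands near 0.95–1.0, above the infinite-volume
0.886 as expected from finite-size rounding and the 0.5-crossing
convention, and within the ±0.15 band used for the check.

**Single-cell oracles** (`run_oracle_suite`) exercise the production engine
against closed forms derived from detailed balance:

* *barometric*: one cell in a 1×1×80 column with ε_g = −0.03; stationary
  P(z) ∝ exp(ε_g z), so the mean height is the truncated-geometric mean
  (≈ 24.8 for these values); checked within 5%.
* *wall affinity*: one cell in a 6³ box with ε_cs = −1.2; escape rates
  scale as exp(m ε_cs), so site occupancy ∝ exp(−m ε_cs) and the
  contact/interior occupancy ratio is e^1.2 ≈ 3.32; checked within 10%.
* *free walker*: all energies zero; each cell is hit on average once per
  MCS and every proposed jump is accepted, so MSD(t) = t; the slope is
  checked within 10% over 30 MCS × 400 independent segments in a 21³ box
  (large enough that walls are never reached).
* *early growth*: p_div = 10⁻² with all energies zero on the half-scale
  well; the replicate-averaged (5 seeds) dilute-window rate is checked
  within 20% of p_div.

## Problem sizes in the test suite

The regime-comparison tests (aggregate counts and sizes across diffusion
rates, wall-adhesion contact fractions, gravity height profiles) run on the
half-scale 30 × 30 × 40 well (R = 15, z_split = 15, N = 24,596) with five
replicate seeds per regime to ϑ = 0.4; the qualitative orderings they
assert are scale-independent, and the full-scale 60 × 60 × 80 geometry
remains the library and CLI default.  The threshold scan runs at its full
prescribed budgets.

## Known limitations

* The lattice imposes a cubic anisotropy on aggregate shapes; surface
  energies are not isotropic, so "spheroids" are faceted at low
  temperature-equivalents.
* ϑ-based stopping measures global occupancy; in the gravity regime the
  bottom of the well is much denser than the top at ϑ = 0.4.
* The threshold scan is a coarse check against the known critical point,
  not a finite-size-scaling measurement; its 0.5-crossing convention and
  the droplet definition shift the estimate by O(0.1) at L = 12.
* Aggregate (collective) diffusion and sedimentation are not modeled;
  single-cell moves only.  Cell death, signaling, and nutrient limitation
  are out of scope.
* Wall-clock cost grows with occupied-site events, so strongly adhesive,
  slowly dividing regimes (many rejected jump attempts inside aggregates)
  are the slowest.
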