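"""Quantitative analysis of simulation output.

Clusters ("aggregates") are maximal face-connected components of occupied
sites — the same 6-neighbor topology the jump and adhesion rules use.
Growth kinetics are summarized by an exponential fit over the dilute window,
where each isolated cell divides at rate ~ p_div per MCS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, sparse

from .geometry import LatticeDomain

_FACE_STRUCTURE = ndimage.generate_binary_structure(3, 1)

#: Cross-section category codes.
WALL, VACANT, CELL = 0, 1, 2


@dataclass(frozen=True)
class Snapshot:
    """A frozen configuration: coordinates of occupied sites at one instant."""

    coords: np.ndarray  # (n, 3) int array of occupied sites
    time: float  # MCS
    theta: float  # occupancy n / N
    meta: dict = field(default_factory=dict)  # params echo, seed, dims, ...

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=np.int32).reshape(-1, 3)
        object.__setattr__(self, "coords", coords)

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]

    def occupancy_grid(self, dims: tuple[int, int, int]) -> np.ndarray:
        occ = np.zeros(dims, dtype=np.uint8)
        if self.n_cells:
            occ[self.coords[:, 0], self.coords[:, 1], self.coords[:, 2]] = 1
        return occ

    def dims(self) -> tuple[int, int, int]:
        d = self.meta.get("dims")
        if d is None:
            raise ValueError("snapshot metadata carries no lattice dims")
        return tuple(int(v) for v in d)


@dataclass(frozen=True)
class KineticsTrace:
    """(time, cell count) series of one run; ϑ = n_cells / N."""

    time: np.ndarray
    n_cells: np.ndarray
    N: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "time", np.asarray(self.time, dtype=np.float64))
        object.__setattr__(self, "n_cells", np.asarray(self.n_cells, dtype=np.int64))

    @property
    def theta(self) -> np.ndarray:
        return self.n_cells / self.N

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.time, "n_cells": self.n_cells, "theta": self.theta}
        )


@dataclass(frozen=True)
class ClusterStats:
    """Connected-component summary of a snapshot.

    ``sizes`` covers every cluster (they sum to the cell count); aggregates
    in the multicellular sense can be counted with :meth:`n_aggregates`.
    """

    n_clusters: int
    sizes: np.ndarray  # descending
    centroids: np.ndarray  # (k, 3), ordered like sizes
    mean_height: float

    @property
    def largest_fraction(self) -> float:
        total = int(self.sizes.sum())
        return float(self.sizes[0]) / total if total else 0.0

    def n_aggregates(self, min_size: int = 2) -> int:
        return int(np.count_nonzero(self.sizes >= min_size))


class GrowthFitError(ValueError):
    """Raised when a kinetics window cannot support an exponential fit."""


# ------------------------------------------------------------------------
def _label_periodic(occ: np.ndarray) -> tuple[np.ndarray, int]:
    """Face-connected labeling with periodic wrapping on every axis."""
    n_occ = int(occ.sum())
    idx = np.full(occ.shape, -1, dtype=np.int64)
    idx[occ.astype(bool)] = np.arange(n_occ)
    rows, cols = [], []
    for ax in range(3):
        nb = np.roll(occ, -1, axis=ax)  # nb[i] <=> site i+1 occupied
        both = occ.astype(bool) & nb.astype(bool)
        rows.append(idx[both])
        cols.append(np.roll(idx, -1, axis=ax)[both])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    graph = sparse.coo_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(n_occ, n_occ)
    )
    n_comp, labels = sparse.csgraph.connected_components(graph, directed=False)
    return labels, n_comp


def label_clusters(
    snapshot: Snapshot, domain: LatticeDomain | None = None
) -> ClusterStats:
    """Maximal face-connected components of the occupied sites.

    Output ordering is deterministic: by size descending, ties broken by
    lexicographic centroid.  An empty snapshot yields zero clusters.
    """
    if snapshot.n_cells == 0:
        return ClusterStats(
            n_clusters=0,
            sizes=np.zeros(0, dtype=np.int64),
            centroids=np.zeros((0, 3)),
            mean_height=float("nan"),
        )
    dims = domain.dims if domain is not None else snapshot.dims()
    occ = snapshot.occupancy_grid(dims)
    periodic = bool(domain.periodic) if domain is not None else False
    if periodic:
        flat_labels, k = _label_periodic(occ)
        per_site_label = flat_labels  # aligned with occupied-site order below
        occupied = np.argwhere(occ.astype(bool))
        labels_of_coords = per_site_label
    else:
        lab, k = ndimage.label(occ, structure=_FACE_STRUCTURE)
        occupied = np.argwhere(occ.astype(bool))
        labels_of_coords = lab[occupied[:, 0], occupied[:, 1], occupied[:, 2]] - 1
    sizes = np.bincount(labels_of_coords, minlength=k).astype(np.int64)
    centroids = np.zeros((k, 3))
    for ax in range(3):
        centroids[:, ax] = (
            np.bincount(labels_of_coords, weights=occupied[:, ax], minlength=k) / sizes
        )
    order = np.lexsort(
        (centroids[:, 2], centroids[:, 1], centroids[:, 0], -sizes)
    )
    sizes = sizes[order]
    centroids = centroids[order]
    mean_height = float(occupied[:, 2].mean())
    return ClusterStats(
        n_clusters=int(k), sizes=sizes, centroids=centroids, mean_height=mean_height
    )


def fit_growth_rate(
    trace: KineticsTrace, window: tuple[float, float] | None = None
) -> float:
    """Least-squares exponential growth rate (per MCS) of ln n_cells vs time.

    ``window`` is an occupancy (ϑ) range; the default covers the dilute
    regime [2 * n_0 / N, 0.02] where n_0 is the initial cell count.
    """
    if window is None:
        if len(trace.n_cells) == 0:
            raise GrowthFitError("empty trace")
        window = (2.0 * trace.n_cells[0] / trace.N, 0.02)
    lo, hi = window
    theta = trace.theta
    sel = (theta >= lo) & (theta <= hi)
    t = trace.time[sel]
    n = trace.n_cells[sel]
    if len(t) < 10:
        raise GrowthFitError(
            f"only {len(t)} kinetics points in window {window}; need >= 10"
        )
    if n[-1] <= n[0]:
        raise GrowthFitError("cell count does not grow within the window")
    slope, _ = np.polyfit(t, np.log(n), 1)
    return float(slope)


def cross_section(
    snapshot: Snapshot,
    domain: LatticeDomain,
    plane: tuple[str, int | tuple[int, ...]] | None = None,
) -> np.ndarray:
    """Categorical 2D section (codes WALL / VACANT / CELL).

    ``plane`` is (axis, index) or (axis, (i1, i2, ...)); multiple indices are
    projected together (union).  The default is the vertical mid-plane
    through the well axis: the union of slices y = ny//2 - 1 and y = ny//2,
    so on-axis structures are not split by the even lattice's parity.
    """
    axes = {"x": 0, "y": 1, "z": 2}
    if plane is None:
        plane = ("y", (domain.dims[1] // 2 - 1, domain.dims[1] // 2))
    axis_name, index = plane
    if axis_name not in axes:
        raise ValueError(f"unknown axis {axis_name!r}")
    ax = axes[axis_name]
    indices = (index,) if np.isscalar(index) else tuple(index)
    for i in indices:
        if not (0 <= i < domain.dims[ax]):
            raise ValueError(f"plane index {i} outside axis {axis_name} of "
                             f"extent {domain.dims[ax]}")
    occ = snapshot.occupancy_grid(domain.dims)
    take = lambda a: a.take(indices=list(indices), axis=ax)  # noqa: E731
    inside = take(domain.mask).any(axis=ax)
    cells = take(occ).astype(bool).any(axis=ax)
    grid = np.full(inside.shape, WALL, dtype=np.int8)
    grid[inside] = VACANT
    grid[cells] = CELL
    return grid


@dataclass(frozen=True)
class HeightProfile:
    counts: np.ndarray  # cells per z layer
    mean_height: float


def height_profile(snapshot: Snapshot, domain: LatticeDomain | None = None) -> HeightProfile:
    """Per-layer cell counts and mean height; gravity pulls the mean down."""
    nz = (domain.dims if domain is not None else snapshot.dims())[2]
    if snapshot.n_cells == 0:
        return HeightProfile(counts=np.zeros(nz, dtype=np.int64), mean_height=float("nan"))
    z = snapshot.coords[:, 2]
    counts = np.bincount(z, minlength=nz).astype(np.int64)
    return HeightProfile(counts=counts, mean_height=float(z.mean()))


def wall_contact_fraction(snapshot: Snapshot, domain: LatticeDomain) -> float:
    """Fraction of cells touching at least one adhesive wall (m >= 1)."""
    if snapshot.n_cells == 0:
        return float("nan")
    c = snapshot.coords
    m = domain.wall_m[c[:, 0], c[:, 1], c[:, 2]]
    return float(np.mean(m >= 1))
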