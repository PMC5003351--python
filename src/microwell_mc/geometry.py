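"""Discretized microwell geometry.

The simulated well is a slab of a simple-cubic lattice cut down to a
hemisphere in the lower part (``z < z_split``) capped by a cylinder above
(``z_split <= z <= top_z``), mimicking a hemispherical-bottom microwell.
Sites are indexed 0-based with z pointing up.  A site belongs to the well iff

* ``z < z_split``:  ``(x - cx)**2 + (y - cy)**2 + (z - z_split)**2 <= R**2``
* ``z >= z_split``: ``(x - cx)**2 + (y - cy)**2 <= R**2``

with the well axis at ``(cx, cy) = ((nx-1)/2, (ny-1)/2)`` so that the mask
is symmetric on an even-sized lattice.  Membership is boundary-inclusive and
evaluated at integer site coordinates.

Positions outside the slab and outside the mask are both "wall": moves and
divisions targeting them are rejected (no-flux boundaries) and they count as
cell-surface contacts for adhesion — except across the top plane
(``z = top_z``), which blocks motion but contributes no adhesion because the
physical plane there crosses the culture solution, not a wall.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Fixed direction order used everywhere a face direction is enumerated or
#: drawn at random: +x, -x, +y, -y, +z, -z.
DIRECTIONS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
    dtype=np.int64,
)


@dataclass(frozen=True)
class LatticeDomain:
    """An immutable lattice domain: site mask, neighbor structure, wall contacts.

    Attributes
    ----------
    dims : (nx, ny, nz) lattice extents.
    mask : boolean array of shape ``dims``; True where the site is in-domain.
    periodic : if True, neighbors wrap around every axis (validation mode);
        the mask must then be all-True and there are no walls.
    R, z_split, axis_center, top_z : well geometry parameters (meaningless
        for periodic/box domains but kept for provenance).
    """

    dims: tuple[int, int, int]
    mask: np.ndarray
    periodic: bool = False
    R: float | None = None
    z_split: int | None = None
    axis_center: tuple[float, float] | None = None
    top_z: int = field(default=-1)
    # Derived, filled in __post_init__ (object.__setattr__ because frozen).
    N: int = field(default=0, init=False)
    sites: np.ndarray = field(default=None, init=False, repr=False)
    site_index: np.ndarray = field(default=None, init=False, repr=False)
    wall_m: np.ndarray = field(default=None, init=False, repr=False)

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.shape != tuple(self.dims):
            raise ValueError(f"mask shape {mask.shape} != dims {self.dims}")
        if self.periodic and not mask.all():
            raise ValueError("periodic domains must be fully in-domain")
        n = int(mask.sum())
        if n == 0:
            raise ValueError("empty domain: no in-domain sites")
        top_z = self.top_z if self.top_z >= 0 else self.dims[2] - 1
        object.__setattr__(self, "top_z", top_z)
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "N", n)
        sites = np.argwhere(mask).astype(np.int32)
        object.__setattr__(self, "sites", sites)
        site_index = np.full(self.dims, -1, dtype=np.int32)
        site_index[mask] = np.arange(n, dtype=np.int32)
        object.__setattr__(self, "site_index", site_index)
        object.__setattr__(self, "wall_m", self._compute_wall_contacts())

    def _compute_wall_contacts(self) -> np.ndarray:
        """Per-site count of adhesive wall contacts (int8, 0 outside)."""
        nx, ny, nz = self.dims
        m = np.zeros(self.dims, dtype=np.int8)
        if self.periodic:
            return m
        for dx, dy, dz in DIRECTIONS:
            # A contact in direction d exists where the neighbor position is
            # out-of-slab or out-of-mask; crossing the top plane is exempt.
            contact = np.zeros(self.dims, dtype=bool)
            shifted = np.zeros(self.dims, dtype=bool)
            src = [slice(None)] * 3
            dst = [slice(None)] * 3
            for ax, d in enumerate((dx, dy, dz)):
                if d == 1:
                    src[ax] = slice(1, None)
                    dst[ax] = slice(0, -1)
                elif d == -1:
                    src[ax] = slice(0, -1)
                    dst[ax] = slice(1, None)
            shifted[tuple(dst)] = self.mask[tuple(src)]
            contact = ~shifted  # neighbor missing or out-of-slab
            if dz == 1:
                contact[:, :, self.top_z] = False  # top plane: no adhesion
            m += contact.astype(np.int8)
        m[~self.mask] = 0
        return m

    # ------------------------------------------------------------------
    def is_inside(self, site: tuple[int, int, int]) -> bool:
        x, y, z = site
        nx, ny, nz = self.dims
        if not (0 <= x < nx and 0 <= y < ny and 0 <= z < nz):
            return False
        return bool(self.mask[x, y, z])

    def _require_inside(self, site: tuple[int, int, int]) -> None:
        if not self.is_inside(site):
            raise ValueError(f"site {tuple(site)} is not in-domain")

    def neighbors(self, site: tuple[int, int, int]) -> list[tuple[int, int, int]]:
        """In-domain face neighbors of an in-domain site, in the fixed
        direction order +x, -x, +y, -y, +z, -z (wrapping if periodic)."""
        self._require_inside(site)
        x, y, z = (int(c) for c in site)
        nx, ny, nz = self.dims
        out: list[tuple[int, int, int]] = []
        for dx, dy, dz in DIRECTIONS:
            px, py, pz = x + dx, y + dy, z + dz
            if self.periodic:
                px, py, pz = px % nx, py % ny, pz % nz
                out.append((px, py, pz))
                continue
            if 0 <= px < nx and 0 <= py < ny and 0 <= pz < nz and self.mask[px, py, pz]:
                out.append((px, py, pz))
        return out

    def wall_contacts(self, site: tuple[int, int, int]) -> int:
        """Number m of adhesive wall contacts at an in-domain site.

        Counts face-adjacent positions that are out-of-domain, excluding the
        position reached by crossing the top plane (adhesion to the top
        boundary is neglected: that plane crosses the solution).
        """
        self._require_inside(site)
        x, y, z = (int(c) for c in site)
        return int(self.wall_m[x, y, z])

    def occupancy(self, n_cells: int) -> float:
        """Occupancy ϑ = fraction of in-domain sites occupied."""
        return n_cells / self.N


def well_mask(
    dims: tuple[int, int, int],
    R: float,
    z_split: int,
    axis_center: tuple[float, float],
) -> np.ndarray:
    """Boolean membership mask of the hemisphere + cylinder well."""
    nx, ny, nz = dims
    cx, cy = axis_center
    x, y, z = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    r2 = (x - cx) ** 2 + (y - cy) ** 2
    hemi = r2 + (z - z_split) ** 2 <= R**2
    cyl = r2 <= R**2
    return np.where(z < z_split, hemi, cyl)


def build_well_domain(
    dims: tuple[int, int, int] = (60, 60, 80),
    R: float = 30.0,
    z_split: int = 30,
    axis_center: tuple[float, float] | None = None,
) -> LatticeDomain:
    """Build the hemispherical-bottom microwell domain.

    Defaults reproduce the 60 x 60 x 80 slab with hemisphere radius 30 and
    hemisphere/cylinder boundary at z = 30.
    """
    nx, ny, nz = dims
    if nx <= 0 or ny <= 0 or nz <= 0:
        raise ValueError(f"dims must be positive, got {dims}")
    if R <= 0:
        raise ValueError("R must be positive")
    if R > min(nx, ny) / 2:
        raise ValueError(f"R={R} exceeds min(nx, ny)/2 = {min(nx, ny) / 2}")
    if not (0 <= z_split <= nz):
        raise ValueError(f"z_split={z_split} outside [0, {nz}]")
    if axis_center is None:
        axis_center = ((nx - 1) / 2, (ny - 1) / 2)
    mask = well_mask(dims, R, z_split, axis_center)
    if not mask.any():
        raise ValueError("geometry parameters produce an empty domain")
    return LatticeDomain(
        dims=tuple(dims),
        mask=mask,
        periodic=False,
        R=float(R),
        z_split=int(z_split),
        axis_center=tuple(axis_center),
        top_z=nz - 1,
    )


def build_box_domain(dims: tuple[int, int, int]) -> LatticeDomain:
    """A fully in-domain rectangular box with adhesive walls on every face
    except the (exempt) top plane.  Used by the single-cell oracles, e.g. a
    1 x 1 x H column for the sedimentation (barometric) test."""
    nx, ny, nz = dims
    if nx <= 0 or ny <= 0 or nz <= 0:
        raise ValueError(f"dims must be positive, got {dims}")
    return LatticeDomain(
        dims=tuple(dims), mask=np.ones(dims, dtype=bool), periodic=False,
        top_z=nz - 1,
    )


def build_periodic_domain(L: int) -> LatticeDomain:
    """An L^3 periodic cube (validation mode): every site has 6 neighbors and
    zero wall contacts.  The bulk lattice-gas threshold is measured here so
    the well geometry does not confound it."""
    if L < 4:
        raise ValueError(f"periodic domain requires L >= 4, got L={L}")
    dims = (L, L, L)
    return LatticeDomain(dims=dims, mask=np.ones(dims, dtype=bool), periodic=True)
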