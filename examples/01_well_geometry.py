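"""Build the discretized microwell and inspect its geometry.

The well is a 60 x 60 x 80 lattice slab cut to a hemisphere (z < 30) capped
by a cylinder (30 <= z <= 79).  N is the number of in-domain sites — the
denominator of the occupancy theta and of the per-trial time increment.
"""

import numpy as np

import microwell_mc as mw

well = mw.build_well_domain()
print(f"dims={well.dims}, R={well.R}, z_split={well.z_split}")
print(f"N = {well.N} lattice sites")
hemi = 2 / 3 * np.pi * well.R**3
cyl = np.pi * well.R**2 * (well.dims[2] - well.z_split)
print(f"continuum volume estimate = {hemi + cyl:.0f} (discretization is ~1% off)")

# Wall contacts drive cell-surface adhesion; the top plane is exempt because
# it crosses the culture solution, not a wall.
m = well.wall_m[well.mask]
print(f"sites touching a wall: {(m > 0).sum()} ({100 * (m > 0).mean():.1f}%)")
print(f"wall contacts at the bottom pole  {well.wall_contacts((30, 30, 1))}")
print(f"wall contacts at the top plane    {well.wall_contacts((30, 30, 79))} (exempt)")
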