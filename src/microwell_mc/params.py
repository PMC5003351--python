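"""Model parameters and the named scenario presets.

All interaction energies are dimensionless (normalized to k_B T) and
attractive, i.e. <= 0:

* ``eps_cc`` — cell-cell nearest-neighbor attraction (default -1.2, above
  the lattice-gas aggregation threshold |eps| ~ 0.89 so cells aggregate),
* ``eps_cs`` — cell-surface (wall) attraction,
* ``eps_g``  — gravity bias: upward jump acceptance carries an extra factor
  exp(eps_g), producing sedimentation,
* ``p_div`` — dimensionless division/diffusion rate ratio: an attempt on an
  occupied site becomes a division attempt with probability p_div and a
  diffusion attempt otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass(frozen=True)
class SimParams:
    eps_cc: float = -1.2
    eps_cs: float = 0.0
    eps_g: float = 0.0
    p_div: float = 1e-4
    n_seed: int = 5
    theta_stop: float = 0.4
    snapshot_thetas: tuple[float, ...] = (0.2, 0.4)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("eps_cc", "eps_cs", "eps_g"):
            v = getattr(self, name)
            if v > 0:
                raise ValueError(
                    f"{name}={v} is positive; interaction energies are "
                    "attractive and must be <= 0"
                )
        if not 0.0 <= self.p_div <= 1.0:
            raise ValueError(f"p_div={self.p_div} outside [0, 1]")
        if self.n_seed < 1:
            raise ValueError(f"n_seed={self.n_seed} must be >= 1")
        if not 0.0 < self.theta_stop <= 1.0:
            raise ValueError(f"theta_stop={self.theta_stop} outside (0, 1]")
        snaps = tuple(float(t) for t in self.snapshot_thetas)
        if any(t <= 0 or t > self.theta_stop for t in snaps):
            raise ValueError(
                f"snapshot_thetas {snaps} must lie in (0, theta_stop="
                f"{self.theta_stop}]"
            )
        if list(snaps) != sorted(snaps):
            raise ValueError("snapshot_thetas must be ascending")
        object.__setattr__(self, "snapshot_thetas", snaps)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["snapshot_thetas"] = list(self.snapshot_thetas)
        return d

    def replace(self, **kw) -> "SimParams":
        d = self.to_dict()
        d.update(kw)
        d["snapshot_thetas"] = tuple(d["snapshot_thetas"])
        return SimParams(**d)


#: The five published parameter regimes, by the figure that shows them:
#: fig5 — no diffusion; fig6 — slow diffusion; fig7 — rapid diffusion;
#: fig8 — rapid diffusion + wall adhesion; fig9 — rapid diffusion + gravity.
SCENARIOS: dict[str, dict[str, float]] = {
    "fig5": {"p_div": 1.0, "eps_cc": -1.2, "eps_cs": 0.0, "eps_g": 0.0},
    "fig6": {"p_div": 1e-2, "eps_cc": -1.2, "eps_cs": 0.0, "eps_g": 0.0},
    "fig7": {"p_div": 1e-4, "eps_cc": -1.2, "eps_cs": 0.0, "eps_g": 0.0},
    "fig8": {"p_div": 1e-4, "eps_cc": -1.2, "eps_cs": -1.2, "eps_g": 0.0},
    "fig9": {"p_div": 1e-4, "eps_cc": -1.2, "eps_cs": 0.0, "eps_g": -0.03},
}


def scenario_params(name: str, **overrides) -> SimParams:
    """SimParams for a named preset; explicit overrides win."""
    if name not in SCENARIOS:
        raise KeyError(
            f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}"
        )
    kw = dict(SCENARIOS[name])
    kw.update(overrides)
    return SimParams(**kw)
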