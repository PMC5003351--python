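"""Configuration files, snapshot/trace serialization, and figure export.

Snapshots and kinetics traces are plain comma-separated tables preceded by
``# key=json`` header lines carrying the full parameter set and RNG seed, so
every output file contains enough metadata to regenerate itself exactly.
Run configurations are flat TOML documents; unknown keys are rejected to
guard against silently misspelled energy names.
"""

from __future__ import annotations

import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .analysis import KineticsTrace, Snapshot, cross_section
from .geometry import LatticeDomain, build_periodic_domain, build_well_domain
from .params import SCENARIOS, SimParams, scenario_params

log = logging.getLogger("microwell_mc")

_GEOMETRY_KEYS = {"nx": int, "ny": int, "nz": int, "R": float, "z_split": int}
_PARAM_KEYS = {
    "eps_cc": float, "eps_cs": float, "eps_g": float, "p_div": float,
    "n_seed": int, "theta_stop": float, "snapshot_thetas": list,
    "rng_seed": int,
}
_OUTPUT_KEYS = {"outdir": str, "record_every": int, "images": bool}
_ALL_KEYS = {"scenario": str, **_GEOMETRY_KEYS, **_PARAM_KEYS, **_OUTPUT_KEYS}


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration: geometry + model params + output."""

    dims: tuple[int, int, int] = (60, 60, 80)
    R: float = 30.0
    z_split: int = 30
    params: SimParams = field(default_factory=SimParams)
    scenario: str | None = None
    outdir: str = "runs"
    record_every: int | None = None
    images: bool = False

    def build_domain(self) -> LatticeDomain:
        return build_well_domain(self.dims, R=self.R, z_split=self.z_split)

    def to_flat_dict(self) -> dict:
        d: dict = {}
        if self.scenario is not None:
            d["scenario"] = self.scenario
        d.update(nx=self.dims[0], ny=self.dims[1], nz=self.dims[2],
                 R=self.R, z_split=self.z_split)
        d.update(self.params.to_dict())
        d.update(outdir=self.outdir, images=self.images)
        if self.record_every is not None:
            d["record_every"] = self.record_every
        return d


def config_from_mapping(raw: dict, source: str = "<mapping>") -> RunConfig:
    unknown = set(raw) - set(_ALL_KEYS)
    if unknown:
        raise ValueError(
            f"{source}: unknown config keys {sorted(unknown)}; "
            f"valid keys are {sorted(_ALL_KEYS)}"
        )
    for key, typ in _ALL_KEYS.items():
        if key in raw:
            v = raw[key]
            if typ is float and isinstance(v, int) and not isinstance(v, bool):
                v = float(v)
            if not isinstance(v, typ) or isinstance(v, bool) and typ is not bool:
                raise ValueError(
                    f"{source}: key {key!r} must be {typ.__name__}, "
                    f"got {type(v).__name__} ({v!r})"
                )
            raw[key] = v

    scenario = raw.get("scenario")
    param_kw: dict = {}
    if scenario is not None:
        if scenario not in SCENARIOS:
            raise ValueError(
                f"{source}: unknown scenario {scenario!r}; "
                f"choose from {sorted(SCENARIOS)}"
            )
        param_kw.update(SCENARIOS[scenario])
    for key in _PARAM_KEYS:
        if key in raw:
            if scenario is not None and key in SCENARIOS[scenario] \
                    and raw[key] != SCENARIOS[scenario][key]:
                log.warning(
                    "config overrides scenario %s: %s=%r (preset %r)",
                    scenario, key, raw[key], SCENARIOS[scenario][key],
                )
            param_kw[key] = raw[key]
    if "snapshot_thetas" in param_kw:
        param_kw["snapshot_thetas"] = tuple(
            float(t) for t in param_kw["snapshot_thetas"]
        )
    try:
        params = SimParams(**param_kw)
    except ValueError as exc:
        raise ValueError(f"{source}: {exc}") from exc

    dims = (raw.get("nx", 60), raw.get("ny", 60), raw.get("nz", 80))
    return RunConfig(
        dims=dims,
        R=raw.get("R", dims[0] / 2),
        z_split=raw.get("z_split", dims[2] * 30 // 80),
        params=params,
        scenario=scenario,
        outdir=raw.get("outdir", "runs"),
        record_every=raw.get("record_every"),
        images=raw.get("images", False),
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a flat TOML run configuration."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path, "rb") as fh:
        try:
            raw = tomllib.load(fh)
        except tomllib.TOMLDecodeError as exc:
            raise ValueError(f"{path}: not valid TOML: {exc}") from exc
    return config_from_mapping(raw, source=str(path))


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {v!r}")


def dump_config(config: RunConfig, path: str | Path) -> None:
    """Write a RunConfig as flat TOML (round-trips through load_config)."""
    lines = [f"{k} = {_toml_value(v)}" for k, v in config.to_flat_dict().items()]
    Path(path).write_text("\n".join(lines) + "\n")


# ------------------------------------------------------------- tables ----
def _write_table(path: Path, meta: dict, header: str, rows_iter) -> None:
    with open(path, "w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}={json.dumps(value)}\n")
        fh.write(header + "\n")
        for row in rows_iter:
            fh.write(row + "\n")


def _read_meta(path: Path) -> tuple[dict, list[str]]:
    meta: dict = {}
    rows: list[str] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    header_seen = False
    for ln in lines:
        if ln.startswith("#"):
            body = ln[1:].strip()
            if "=" not in body:
                raise ValueError(f"{path}: malformed header line {ln!r}")
            key, val = body.split("=", 1)
            try:
                meta[key.strip()] = json.loads(val)
            except json.JSONDecodeError as exc:
                raise ValueError(
                    f"{path}: malformed header value in {ln!r}"
                ) from exc
        elif not header_seen:
            header_seen = True
        elif ln.strip():
            rows.append(ln)
    if not header_seen:
        raise ValueError(f"{path}: missing column header")
    return meta, rows


def write_snapshot(snapshot: Snapshot, path: str | Path) -> None:
    """Snapshot -> delimited table of occupied-site coordinates."""
    meta = dict(snapshot.meta)
    meta["time"] = snapshot.time
    meta["theta"] = snapshot.theta
    meta["n_cells"] = snapshot.n_cells
    _write_table(
        Path(path), meta, "x,y,z",
        (f"{x},{y},{z}" for x, y, z in snapshot.coords),
    )


def _domain_from_meta(meta: dict) -> LatticeDomain | None:
    dims = meta.get("dims")
    if dims is None:
        return None
    dims = tuple(int(v) for v in dims)
    if meta.get("periodic") and dims[0] == dims[1] == dims[2]:
        return build_periodic_domain(dims[0])
    if meta.get("R") is not None and meta.get("z_split") is not None:
        return build_well_domain(dims, R=meta["R"], z_split=meta["z_split"])
    return None


def read_snapshot(
    path: str | Path, domain: LatticeDomain | None = None
) -> Snapshot:
    """Read a snapshot written by :func:`write_snapshot`, validating every
    coordinate against the domain mask (rebuilt from the header when not
    supplied)."""
    path = Path(path)
    meta, rows = _read_meta(path)
    for key in ("time", "theta"):
        if key not in meta:
            raise ValueError(f"{path}: header lacks required key {key!r}")
    coords = np.zeros((len(rows), 3), dtype=np.int32)
    for i, row in enumerate(rows):
        parts = row.split(",")
        if len(parts) != 3:
            raise ValueError(f"{path}: malformed data row {row!r}")
        try:
            coords[i] = [int(p) for p in parts]
        except ValueError as exc:
            raise ValueError(f"{path}: malformed data row {row!r}") from exc
    check_domain = domain if domain is not None else _domain_from_meta(meta)
    if check_domain is not None:
        for xyz in coords:
            if not check_domain.is_inside(tuple(xyz)):
                raise ValueError(
                    f"{path}: coordinate {tuple(int(v) for v in xyz)} lies "
                    "outside the domain mask"
                )
    time = float(meta.pop("time"))
    theta = float(meta.pop("theta"))
    meta.pop("n_cells", None)
    return Snapshot(coords=coords, time=time, theta=theta, meta=meta)


def write_trace(trace: KineticsTrace, path: str | Path) -> None:
    meta = dict(trace.meta)
    meta["N"] = trace.N
    _write_table(
        Path(path), meta, "time,n_cells,theta",
        (
            f"{float(t)!r},{int(n)},{float(n / trace.N)!r}"
            for t, n in zip(trace.time, trace.n_cells)
        ),
    )


def read_trace(path: str | Path) -> KineticsTrace:
    path = Path(path)
    meta, rows = _read_meta(path)
    if "N" not in meta:
        raise ValueError(f"{path}: header lacks required key 'N'")
    time = np.zeros(len(rows))
    n_cells = np.zeros(len(rows), dtype=np.int64)
    for i, row in enumerate(rows):
        parts = row.split(",")
        if len(parts) != 3:
            raise ValueError(f"{path}: malformed data row {row!r}")
        time[i] = float(parts[0])
        n_cells[i] = int(parts[1])
    N = int(meta.pop("N"))
    return KineticsTrace(time=time, n_cells=n_cells, N=N, meta=meta)


def write_manifest(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


# ------------------------------------------------------------ figures ----
def render_cross_section(
    snapshot: Snapshot,
    domain: LatticeDomain,
    path: str | Path | None = None,
    plane=None,
    ax=None,
):
    """Render a vertical cross-section: wall black, vacant well white,
    cells red (matching the published figures' convention)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    grid = cross_section(snapshot, domain, plane=plane)
    cmap = ListedColormap(["black", "white", "red"])
    created = ax is None
    if created:
        _, ax = plt.subplots(figsize=(4, 4 * grid.shape[1] / grid.shape[0]))
    ax.imshow(grid.T, origin="lower", cmap=cmap, vmin=0, vmax=2,
              interpolation="nearest")
    ax.set_xlabel("x (lattice units)")
    ax.set_ylabel("z (lattice units)")
    ax.set_title(
        f"t = {snapshot.time:.0f} MCS,  ϑ = {snapshot.theta:.2f}"
    )
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
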