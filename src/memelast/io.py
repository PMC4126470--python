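"""Trajectory and report I/O plus run-configuration handling.

Configurations travel as extended-XYZ text (per-frame ``Lattice`` and
``Properties=species:S:1:pos:R:3``), a format every molecular viewer
opens; molecule topology (bead-index chains, explicit bonds) goes in a
JSON sidecar because extended XYZ has no bond records.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .core import BeadKind, Configuration

__all__ = ["RunConfig", "load_config", "write_extxyz", "read_extxyz",
           "save_configuration", "load_configuration", "write_report"]

#: bead kind <-> extxyz species label (element-like, viewer friendly)
KIND_TO_SPECIES = {BeadKind.head: "N", BeadKind.tail: "C", BeadKind.solvent: "O"}
SPECIES_TO_KIND = {v: k for k, v in KIND_TO_SPECIES.items()}


# ----------------------------------------------------------------------
# extended XYZ
# ----------------------------------------------------------------------
def write_extxyz(path, configs, mode: str = "w") -> None:
    """Write one or more Configurations as extended-XYZ frames."""
    if isinstance(configs, Configuration):
        configs = [configs]
    with open(path, mode) as fh:
        for cfg in configs:
            lx, ly, lz = cfg.box
            pbc = " ".join("T" if p else "F" for p in cfg.periodic)
            fh.write(f"{cfg.n_beads}\n")
            fh.write(
                f'Lattice="{lx:.17g} 0 0 0 {ly:.17g} 0 0 0 {lz:.17g}" '
                f'Properties=species:S:1:pos:R:3 pbc="{pbc}"\n')
            for kind, (x, y, z) in zip(cfg.kinds, cfg.positions):
                sp = KIND_TO_SPECIES[BeadKind(int(kind))]
                fh.write(f"{sp} {x:.17g} {y:.17g} {z:.17g}\n")


def read_extxyz(path) -> list:
    """Read extended-XYZ frames; returns Configurations without topology
    (every bead its own molecule — attach topology via the sidecar)."""
    frames = []
    with open(path) as fh:
        while True:
            line = fh.readline()
            if not line.strip():
                break
            n = int(line)
            header = fh.readline()
            box = _parse_lattice(header)
            pbc = _parse_pbc(header)
            kinds = np.empty(n, dtype=np.int64)
            pos = np.empty((n, 3))
            for i in range(n):
                parts = fh.readline().split()
                kinds[i] = int(SPECIES_TO_KIND[parts[0]])
                pos[i] = [float(v) for v in parts[1:4]]
            frames.append(Configuration(
                positions=pos, kinds=kinds,
                molecules=[[i] for i in range(n)],
                box=box, periodic=pbc))
    return frames


def _parse_lattice(header: str) -> np.ndarray:
    key = 'Lattice="'
    i = header.index(key) + len(key)
    vals = [float(v) for v in header[i:header.index('"', i)].split()]
    return np.array([vals[0], vals[4], vals[8]])


def _parse_pbc(header: str):
    key = 'pbc="'
    if key not in header:
        return (True, True, True)
    i = header.index(key) + len(key)
    flags = header[i:header.index('"', i)].split()
    return tuple(f.upper().startswith("T") for f in flags)


def save_configuration(path, config: Configuration) -> None:
    """Write config as <path>.extxyz + <path>.topology.json sidecar."""
    path = Path(path)
    base = path.with_suffix("") if path.suffix == ".extxyz" else path
    write_extxyz(base.with_suffix(".extxyz"), config)
    topo = {"molecules": [list(map(int, m)) for m in config.molecules]}
    if config.bonds is not None:
        topo["bonds"] = config.bonds.tolist()
    base.with_suffix(".topology.json").write_text(json.dumps(topo))


def load_configuration(path) -> Configuration:
    path = Path(path)
    base = path.with_suffix("") if path.suffix == ".extxyz" else path
    cfg = read_extxyz(base.with_suffix(".extxyz"))[-1]
    topo_path = base.with_suffix(".topology.json")
    if topo_path.exists():
        topo = json.loads(topo_path.read_text())
        cfg.molecules = [list(m) for m in topo["molecules"]]
        if "bonds" in topo:
            cfg.bonds = np.asarray(topo["bonds"], dtype=np.int64)
    return cfg


# ----------------------------------------------------------------------
# run configuration
# ----------------------------------------------------------------------
class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ForceFieldOverrides(_Strict):
    nu_fene: float = 100.0
    r0: float = 0.7
    dr_m: float = 0.2
    nu_ba: float = 4.7


class MCSection(_Strict):
    sweeps: int = 2_000_000          # equilibration length at full scale
    displacement_max: float = 0.15
    box_move_max: float = 0.01
    sample_stride: int = 1
    adapt_acceptance: bool = True
    target_acceptance: float = 0.4


class PoissonSection(_Strict):
    eta: float = 0.05
    axis: str = "y"
    relax_sweeps: int = 20000
    anneal_sweeps: int = 400
    burn_in: int = 5000


class SpectrumSection(_Strict):
    grid_spacing: float = 2.0
    qsq_min: float = 0.5
    qsq_max: float = 1.0
    frame_stride: int = 100


class RunConfig(_Strict):
    """Fully-resolved run configuration; unknown keys are rejected."""

    phase: str = "fluid"
    nx: int = 12
    ny: int = 24
    solvent_density: float = 0.3
    seed: int = 0
    forcefield: ForceFieldOverrides = ForceFieldOverrides()
    mc: MCSection = MCSection()
    poisson: PoissonSection = PoissonSection()
    spectrum: SpectrumSection = SpectrumSection()
    out_dir: str = "."

    def resolved_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(self.resolved_yaml().encode()).hexdigest()[:12]


def load_config(path) -> RunConfig:
    """Load a YAML run configuration; defaults fill anything omitted.

    Unknown or mistyped keys raise with the offending key named.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    try:
        return RunConfig(**data)
    except ValidationError as e:
        raise ValueError(f"invalid run configuration {path}: {e}") from e


def write_report(path, payload: dict, config: RunConfig | None = None) -> None:
    """JSON report stamped with package version and resolved-config hash."""
    from . import __version__
    out = dict(payload)
    out["_provenance"] = {"package": "memelast", "version": __version__}
    if config is not None:
        out["_provenance"]["config_sha256"] = config.digest()
    Path(path).write_text(json.dumps(out, indent=2, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
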