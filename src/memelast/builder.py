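"""Initial bilayer construction and membrane descriptors.

Bilayers are built as two leaflets of straight 7-bead amphiphiles
(head outermost, six tail beads toward the midplane) on a square
lateral lattice whose spacing realises a requested area per lipid.
Phantom-solvent beads fill the remaining volume uniformly at a target
number density.  The interdigitated phase is built with the leaflets
offset by half a lattice vector and overlapped so the tails of
opposing leaflets interpenetrate.

Descriptors reported for a configuration: mean chain length (head to
terminal tail bead), bilayer thickness (distance between leaflet head
planes), area per lipid, and the chain order parameter
S_z = <(3 cos^2 a - 1)/2> over tail-tail bonds, with a the bond angle
to the z (bilayer-normal) axis.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core import BEADS_PER_LIPID, BeadKind, Configuration
from .forcefield import ForceFieldParams

__all__ = ["PhasePoint", "PHASES", "MembraneDescriptors", "PackingError",
           "LeafletError", "build_bilayer", "membrane_descriptors"]


@dataclass(frozen=True)
class PhasePoint:
    """A (P, T) state point plus its thermalisation-bump temperature."""

    name: str
    P: float
    T: float
    T_anneal: float


#: State points of the three bilayer phases, with the temperature each is
#: bumped to while re-thermalising after an axial rescale.
PHASES = {
    "gel": PhasePoint("gel", P=2.0, T=1.08, T_anneal=1.2),
    "fluid": PhasePoint("fluid", P=1.0, T=1.3, T_anneal=1.4),
    "interdigitated": PhasePoint("interdigitated", P=0.5, T=1.16, T_anneal=1.3),
}

#: Equilibrium area per lipid used to seed construction (shortens
#: equilibration); measured values for each phase.
_AREA_PER_LIPID = {"gel": 0.96, "fluid": 1.68, "interdigitated": 1.8}


class PackingError(ValueError):
    """Initial construction places an active pair closer than 0.8 sigma."""


class LeafletError(ValueError):
    """Leaflets cannot be identified (no bimodal head-height distribution)."""


@dataclass
class MembraneDescriptors:
    chain_length_mean: float
    thickness: float
    area_per_lipid: float
    order_parameter: float

    def __post_init__(self):
        if self.area_per_lipid <= 0 or self.thickness <= 0:
            raise ValueError("area per lipid and thickness must be positive")
        if not -0.5 - 1e-9 <= self.order_parameter <= 1 + 1e-9:
            raise ValueError("order parameter outside [-0.5, 1]")


def _straight_chain(head_xy, z_head, direction, r0):
    """7 bead positions: head at z_head, tails marching along direction."""
    pos = np.zeros((BEADS_PER_LIPID, 3))
    for k in range(BEADS_PER_LIPID):
        pos[k, 0] = head_xy[0]
        pos[k, 1] = head_xy[1]
        pos[k, 2] = z_head + direction * k * r0
    return pos


def build_bilayer(nx: int, ny: int, phase: PhasePoint | str, *,
                  area_per_lipid_init: float | None = None,
                  solvent_density: float = 0.3,
                  solvent_pad: float = 8.0,
                  leaflet_gap: float = 1.0,
                  seed: int = 0,
                  ff: ForceFieldParams | None = None) -> Configuration:
    """Construct a bilayer of 2*nx*ny lipids plus phantom solvent.

    Parameters
    ----------
    nx, ny : int
        Lipids per row / column of each leaflet (>= 2).
    phase : PhasePoint or str
        Target phase; sets the default initial area per lipid and, for
        ``interdigitated``, the interpenetrating construction.
    area_per_lipid_init : float, optional
        Initial lateral area per lipid (sigma^2); defaults to the
        phase's equilibrium value.
    solvent_density : float
        Number density (beads/sigma^3) of phantom solvent filling the
        box outside the membrane slab.  The default places a 64x64
        fluid system in the tens of thousands of solvent beads.
    solvent_pad : float
        Water-slab thickness above and below the membrane (sigma).
    leaflet_gap : float
        Terminal-tail to terminal-tail separation between leaflets for
        the non-interdigitated construction.
    seed : int
        Seeds solvent placement; identical seeds rebuild bit-identically.
    """
    if isinstance(phase, str):
        phase = PHASES[phase]
    if nx < 2 or ny < 2:
        raise ValueError("nx, ny must be >= 2")
    if ff is None:
        ff = ForceFieldParams()
    r0 = ff.r0
    if area_per_lipid_init is None:
        area_per_lipid_init = _AREA_PER_LIPID.get(phase.name, 1.68)
    a = math.sqrt(area_per_lipid_init)
    Lx, Ly = nx * a, ny * a
    chain_len = (BEADS_PER_LIPID - 1) * r0

    interdig = phase.name == "interdigitated"
    if interdig:
        # heads at +-d/2 around the midplane with the tails overlapping;
        # half-lattice lateral offset keeps opposing chains apart
        d_init = chain_len + 0.6
    else:
        d_init = 2 * chain_len + leaflet_gap
    Lz = d_init + 2.0 * solvent_pad
    z_mid = Lz / 2.0

    positions = []
    kinds = []
    molecules = []
    idx = 0
    for leaflet in (+1, -1):
        # head outermost, tails marching toward the midplane
        z_head = z_mid + leaflet * d_init / 2.0
        for ix in range(nx):
            for iy in range(ny):
                x = (ix + 0.25) * a
                y = (iy + 0.25) * a
                if interdig and leaflet < 0:
                    x += 0.5 * a
                    y += 0.5 * a
                chain = _straight_chain((x % Lx, y % Ly), z_head, -leaflet, r0)
                positions.append(chain)
                kinds.extend([BeadKind.head] + [BeadKind.tail] * 6)
                molecules.append(list(range(idx, idx + BEADS_PER_LIPID)))
                idx += BEADS_PER_LIPID

    positions = np.vstack(positions)
    box = np.array([Lx, Ly, Lz])

    # phantom solvent: uniform in the two slabs outside the membrane
    rng = np.random.default_rng(seed)
    margin = 1.0
    half = d_init / 2.0 + margin
    slab = solvent_pad - margin
    n_solv = int(round(solvent_density * Lx * Ly * 2 * max(slab, 0.0)))
    if n_solv > 0:
        sx = rng.uniform(0, Lx, n_solv)
        sy = rng.uniform(0, Ly, n_solv)
        off = rng.uniform(0, slab, n_solv)
        sign = np.where(rng.random(n_solv) < 0.5, 1.0, -1.0)
        sz = (z_mid + sign * (half + off)) % Lz
        solv = np.column_stack([sx, sy, sz])
        positions = np.vstack([positions, solv])
        for i in range(n_solv):
            molecules.append([idx])
            idx += 1
        kinds.extend([BeadKind.solvent] * n_solv)

    cfg = Configuration(positions=positions, kinds=np.array(kinds),
                        molecules=molecules, box=box).wrap()
    _check_packing(cfg, ff)
    return cfg


def _check_packing(cfg: Configuration, ff: ForceFieldParams, factor: float = 0.8):
    """Reject constructions with active pairs closer than factor*sigma_pair."""
    max_sig = max(p.sigma_lj for p in ff.pair_table.values() if p.active)
    tree = cKDTree(cfg.positions % cfg.box, boxsize=cfg.box)
    pairs = tree.query_pairs(factor * max_sig, output_type="ndarray")
    if len(pairs) == 0:
        return
    bonded = {tuple(sorted(b)) for b in cfg.bond_array()}
    pos = cfg.positions
    for i, j in pairs:
        i, j = int(i), int(j)
        if (min(i, j), max(i, j)) in bonded:
            continue
        p = ff.pair(cfg.kinds[i], cfg.kinds[j])
        if not p.active:
            continue
        d = cfg.minimum_image(pos[j] - pos[i])
        r = float(np.linalg.norm(d))
        if r < factor * p.sigma_lj:
            # second neighbours along a straight chain sit at 2*r0 = 1.4,
            # beyond 0.8*sigma for every pair, so any hit is a real clash
            raise PackingError(
                f"beads {i} and {j} at r={r:.3f} < {factor}*sigma={factor * p.sigma_lj:.3f}")


# ----------------------------------------------------------------------
def _circular_mean(z, L):
    ang = z * (2 * np.pi / L)
    return (math.atan2(np.sin(ang).mean(), np.cos(ang).mean()) % (2 * np.pi)) * L / (2 * np.pi)


def membrane_descriptors(config: Configuration,
                         min_separation: float = 1.0) -> MembraneDescriptors:
    """Measure chain length, thickness, area per lipid and S_z.

    Leaflets are assigned at analysis time by the sign of the head
    height relative to the instantaneous midplane (circular mean of all
    lipid-bead z, so a bilayer drifting through the periodic z boundary
    is handled).  Raises :class:`LeafletError` when the head-height
    distribution is not bimodal (separation < ``min_separation`` or an
    empty leaflet).
    """
    lipids = config.lipids
    if not lipids:
        raise LeafletError("configuration contains no lipid chains")
    pos = config.positions
    box = config.box
    Lz = box[2]
    lipid_beads = np.concatenate(lipids)
    z_mid = _circular_mean(pos[lipid_beads, 2], Lz)
    # recentre so the membrane sits near Lz/2
    zc = (pos[:, 2] - z_mid + Lz / 2.0) % Lz

    heads = np.array([m[0] for m in lipids])
    tails_last = np.array([m[-1] for m in lipids])
    zh = zc[heads]
    upper = zh > Lz / 2.0
    if upper.all() or (~upper).all():
        raise LeafletError("all heads on one side of the midplane")
    z_up = float(zh[upper].mean())
    z_lo = float(zh[~upper].mean())
    d = z_up - z_lo
    if d < min_separation:
        raise LeafletError(f"head-height modes separated by only {d:.3f} sigma")

    n_per_leaflet = len(lipids) / 2.0
    A = float(box[0] * box[1] / n_per_leaflet)

    dvec = config.minimum_image(pos[tails_last] - pos[heads])
    l_mean = float(np.linalg.norm(dvec, axis=1).mean())

    # tail-tail bonds: consecutive pairs excluding the head-tail bond
    pairs = []
    for m in lipids:
        for a, b in zip(m[1:-1], m[2:]):
            pairs.append((a, b))
    pairs = np.asarray(pairs)
    bv = config.minimum_image(pos[pairs[:, 1]] - pos[pairs[:, 0]])
    cos2 = bv[:, 2] ** 2 / (bv * bv).sum(axis=1)
    s_z = float((1.5 * cos2 - 0.5).mean())

    return MembraneDescriptors(chain_length_mean=l_mean, thickness=d,
                               area_per_lipid=A, order_parameter=s_z)
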