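"""Interaction potentials of the coarse-grained amphiphile model.

Three terms define the model Hamiltonian:

* a FENE (finitely extensible nonlinear elastic) spring between
  consecutive beads of a chain,
      V_FENE(r) = -(nu_FENE/2) dr_m^2 ln[1 - ((r - r0)/dr_m)^2],
  diverging at |r - r0| = dr_m;
* a harmonic bond-angle penalty on chain bending,
      V_ba(theta) = nu_ba (1 - cos theta),
  with theta = 0 for a straight chain;
* a shifted, truncated soft-core pair potential between non-bonded
  beads,
      V_sc(r) = [V_LJ(r) - V_LJ(r_c)] * theta(r_c - r),
      V_LJ(r) = eps [(sigma/r)^12 - 2 (sigma/r)^6],
  whose minimum is -eps at r = sigma.  Pairs with r_c = 1 sigma are
  purely repulsive.  Solvent-solvent pairs do not interact at all
  (phantom solvent).

The canonical parameter set (the model's published table) is the
default `ForceFieldParams()`.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core import BeadKind, Configuration

__all__ = [
    "PairParams",
    "ForceFieldParams",
    "FeneDomainError",
    "fene_energy",
    "bond_angle_energy",
    "soft_core_energy",
    "total_energy",
    "delta_energy",
    "BeadMove",
    "BoxScale",
]

N_KINDS = 3


class FeneDomainError(ValueError):
    """A bond left the FENE domain |r - r0| < dr_m (bond broken).

    Signals an illegal move or a too-large rescale factor; carries the
    offending bond when known.
    """

    def __init__(self, r, bond=None):
        self.r = r
        self.bond = bond
        msg = f"FENE bond length {r:.6g} outside domain"
        if bond is not None:
            msg += f" (bond {tuple(int(i) for i in bond)})"
        super().__init__(msg)


@dataclass(frozen=True)
class PairParams:
    """Soft-core parameters for one unordered bead-kind pair.

    ``r_c_mult`` is the cutoff in multiples of this pair's sigma_lj;
    ``active=False`` marks the non-interacting (phantom) pair.
    """

    epsilon: float = 1.0
    sigma_lj: float = 1.0
    r_c_mult: float = 1.0
    active: bool = True

    @property
    def r_cut(self) -> float:
        return self.r_c_mult * self.sigma_lj


def _default_pair_table():
    h, t, s = BeadKind.head, BeadKind.tail, BeadKind.solvent
    return {
        frozenset((t, t)): PairParams(1.0, 1.0, 2.0, True),
        frozenset((h, t)): PairParams(1.0, 1.05, 1.0, True),
        frozenset((h, h)): PairParams(1.0, 1.1, 1.0, True),
        frozenset((s, h)): PairParams(1.0, 1.1, 1.0, True),
        frozenset((s, t)): PairParams(1.0, 1.1, 1.0, True),
        frozenset((s, s)): PairParams(0.0, 1.0, 0.0, False),
    }


@dataclass
class ForceFieldParams:
    """All constants of the model, defaulting to the canonical set.

    ``bond_style`` selects the bonded term: ``"fene"`` for the lipid
    model, ``"harmonic"`` (0.5 k (r - r0)^2 with k = ``harmonic_k``)
    for the toy spring networks used as protocol oracles.

    ``exclude_bonded`` removes directly bonded pairs from the soft-core
    sum (second neighbours along a chain still interact); the FENE term
    already accounts for the bonded pair.
    """

    nu_fene: float = 100.0
    r0: float = 0.7
    dr_m: float = 0.2
    nu_ba: float = 4.7
    pair_table: dict = field(default_factory=_default_pair_table)
    bond_style: str = "fene"
    harmonic_k: float = 100.0
    exclude_bonded: bool = True

    def __post_init__(self):
        if self.dr_m <= 0 or self.r0 <= 0 or self.nu_fene <= 0:
            raise ValueError("nu_fene, r0, dr_m must be positive")
        if self.nu_ba < 0:
            raise ValueError("nu_ba must be non-negative")
        if self.bond_style not in ("fene", "harmonic"):
            raise ValueError(f"unknown bond_style {self.bond_style!r}")

    # ------------------------------------------------------------------
    def pair(self, kind_a, kind_b) -> PairParams:
        return self.pair_table[frozenset((BeadKind(kind_a), BeadKind(kind_b)))]

    def tables(self):
        """Dense (3,3) arrays (eps, sigma, r_cut^2, shift, active) for kernels.

        ``shift`` is V_LJ(r_cut), subtracted so the potential is
        continuous (and exactly zero) at the cutoff.
        """
        eps = np.zeros((N_KINDS, N_KINDS))
        sig = np.zeros((N_KINDS, N_KINDS))
        rc2 = np.zeros((N_KINDS, N_KINDS))
        shift = np.zeros((N_KINDS, N_KINDS))
        active = np.zeros((N_KINDS, N_KINDS), dtype=np.bool_)
        for a in range(N_KINDS):
            for b in range(N_KINDS):
                p = self.pair(a, b)
                if not p.active:
                    continue
                eps[a, b] = p.epsilon
                sig[a, b] = p.sigma_lj
                rc2[a, b] = p.r_cut ** 2
                shift[a, b] = _vlj(p.r_cut, p.epsilon, p.sigma_lj)
                active[a, b] = True
        return eps, sig, rc2, shift, active

    def max_cutoff(self) -> float:
        return max((p.r_cut for p in self.pair_table.values() if p.active),
                   default=0.0)

    def with_pairs_inactive(self) -> "ForceFieldParams":
        """Copy with every soft-core pair switched off (bonded terms only)."""
        table = {k: replace(p, active=False) for k, p in self.pair_table.items()}
        return replace(self, pair_table=table)

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        pairs = {}
        for key, p in self.pair_table.items():
            name = "-".join(sorted(BeadKind(k).name for k in key))
            pairs[name] = {"epsilon": p.epsilon, "sigma_lj": p.sigma_lj,
                           "r_c_mult": p.r_c_mult, "active": p.active}
        return {"nu_fene": self.nu_fene, "r0": self.r0, "dr_m": self.dr_m,
                "nu_ba": self.nu_ba, "bond_style": self.bond_style,
                "harmonic_k": self.harmonic_k,
                "exclude_bonded": self.exclude_bonded, "pairs": pairs}

    @classmethod
    def from_dict(cls, d: dict) -> "ForceFieldParams":
        d = dict(d)
        pairs = d.pop("pairs", None)
        ff = cls(**d)
        if pairs:
            for name, pd in pairs.items():
                kinds = frozenset(BeadKind[k] for k in name.split("-"))
                ff.pair_table[kinds] = PairParams(**pd)
        return ff


# ----------------------------------------------------------------------
# scalar potentials
# ----------------------------------------------------------------------
def _vlj(r, eps, sigma):
    x = (sigma / r) ** 6
    return eps * (x * x - 2.0 * x)


def fene_energy(r: float, p: ForceFieldParams) -> float:
    """FENE bond energy at separation ``r``; raises outside the domain."""
    dr = r - p.r0
    if abs(dr) >= p.dr_m:
        raise FeneDomainError(r)
    x = dr / p.dr_m
    return -0.5 * p.nu_fene * p.dr_m ** 2 * math.log1p(-x * x)


def harmonic_bond_energy(r: float, p: ForceFieldParams) -> float:
    return 0.5 * p.harmonic_k * (r - p.r0) ** 2


def bond_energy(r: float, p: ForceFieldParams) -> float:
    if p.bond_style == "fene":
        return fene_energy(r, p)
    return harmonic_bond_energy(r, p)


def bond_angle_energy(theta: float, p: ForceFieldParams) -> float:
    """Bending energy nu_ba (1 - cos theta); theta = 0 is a straight chain."""
    c = min(1.0, max(-1.0, math.cos(theta)))
    return p.nu_ba * (1.0 - c)


def soft_core_energy(r: float, kind_a, kind_b, p: ForceFieldParams) -> float:
    """Truncated-shifted soft-core pair energy; 0 for r >= r_c.

    Inactive pairs (phantom solvent-solvent) return 0 by contract.
    """
    if r <= 0:
        raise ValueError("r must be positive")
    pp = p.pair(kind_a, kind_b)
    if not pp.active or r >= pp.r_cut:
        return 0.0
    return _vlj(r, pp.epsilon, pp.sigma_lj) - _vlj(pp.r_cut, pp.epsilon, pp.sigma_lj)


# ----------------------------------------------------------------------
# configuration energies (vectorised reference implementation)
# ----------------------------------------------------------------------
def _bond_lengths(config: Configuration, bonds: np.ndarray) -> np.ndarray:
    d = config.positions[bonds[:, 1]] - config.positions[bonds[:, 0]]
    d = config.minimum_image(d)
    return np.sqrt((d * d).sum(axis=1))


def _bonded_energy(config: Configuration, p: ForceFieldParams) -> float:
    bonds = config.bond_array()
    if len(bonds) == 0:
        return 0.0
    r = _bond_lengths(config, bonds)
    if p.bond_style == "fene":
        x = (r - p.r0) / p.dr_m
        bad = np.abs(x) >= 1.0
        if bad.any():
            i = int(np.argmax(bad))
            raise FeneDomainError(r[i], bonds[i])
        return float(-0.5 * p.nu_fene * p.dr_m ** 2 * np.log1p(-x * x).sum())
    return float(0.5 * p.harmonic_k * ((r - p.r0) ** 2).sum())


def _angle_energy(config: Configuration, p: ForceFieldParams) -> float:
    angles = config.angle_array()
    if len(angles) == 0 or p.nu_ba == 0.0:
        return 0.0
    u = config.minimum_image(config.positions[angles[:, 1]] - config.positions[angles[:, 0]])
    v = config.minimum_image(config.positions[angles[:, 2]] - config.positions[angles[:, 1]])
    c = (u * v).sum(axis=1) / (np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1))
    c = np.clip(c, -1.0, 1.0)
    return float(p.nu_ba * (1.0 - c).sum())


def _pair_energy_matrix(config, p, idx_a, idx_b):
    """Soft-core energy sum over the cartesian product idx_a x idx_b (i<j)."""
    eps, sig, rc2, shift, active = p.tables()
    pos = config.positions
    kinds = config.kinds
    d = pos[idx_b][None, :, :] - pos[idx_a][:, None, :]
    d = d - config.box * np.round(d / config.box)
    r2 = (d * d).sum(axis=-1)
    ka = kinds[idx_a][:, None]
    kb = kinds[idx_b][None, :]
    mask = active[ka, kb] & (r2 < rc2[ka, kb]) & (r2 > 0)
    if not mask.any():
        return 0.0
    s2 = sig[ka, kb][mask] ** 2 / r2[mask]
    s6 = s2 ** 3
    e = eps[ka, kb][mask] * (s6 * s6 - 2.0 * s6) - shift[ka, kb][mask]
    return float(e.sum())


def _nonbonded_energy(config: Configuration, p: ForceFieldParams) -> float:
    n = config.n_beads
    if n < 2:
        return 0.0
    eps, sig, rc2, shift, active = p.tables()
    pos = config.positions
    kinds = config.kinds
    total = 0.0
    # chunked upper-triangle pair sum under minimum image
    chunk = max(1, int(4e6 // max(n, 1)))
    excl = config.bond_array() if p.exclude_bonded else np.empty((0, 2), np.int64)
    for start in range(0, n, chunk):
        stop = min(n, start + chunk)
        i_idx = np.arange(start, stop)
        d = pos[None, :, :] - pos[i_idx, None, :]
        d = d - config.box * np.round(d / config.box)
        r2 = (d * d).sum(axis=-1)
        ki = kinds[i_idx][:, None]
        kj = kinds[None, :]
        j_idx = np.arange(n)[None, :]
        upper = j_idx > i_idx[:, None]
        mask = upper & active[ki, kj] & (r2 < rc2[ki, kj])
        for a, b in excl:
            if start <= a < stop:
                mask[a - start, b] = False
            if start <= b < stop:
                mask[b - start, a] = False
        if not mask.any():
            continue
        s2 = sig[ki, kj][mask] ** 2 / r2[mask]
        s6 = s2 ** 3
        e = eps[ki, kj][mask] * (s6 * s6 - 2.0 * s6) - shift[ki, kj][mask]
        total += float(e.sum())
    return total


def total_energy(config: Configuration, p: ForceFieldParams | None = None) -> float:
    """Total potential energy: bonds + angles + non-bonded soft core.

    Reference implementation (vectorised numpy, O(N^2) pairs under the
    minimum-image convention); the sampling engine uses an equivalent
    cell-list kernel validated against this function.
    """
    if p is None:
        p = ForceFieldParams()
    return _bonded_energy(config, p) + _angle_energy(config, p) + _nonbonded_energy(config, p)


# ----------------------------------------------------------------------
# proposed moves and incremental energies
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class BeadMove:
    """Single-bead trial displacement to an absolute position."""

    index: int
    new_position: np.ndarray


@dataclass(frozen=True)
class BoxScale:
    """Affine rescale of one box axis by ``factor`` (coordinates follow)."""

    axis: int
    factor: float


def _bead_local_energy(config: Configuration, i: int, p: ForceFieldParams) -> float:
    """Energy terms involving bead i (bonds, angles, pairs)."""
    pos = config.positions
    e = 0.0
    bonds = config.bond_array()
    if len(bonds):
        sel = bonds[(bonds[:, 0] == i) | (bonds[:, 1] == i)]
        for a, b in sel:
            d = config.minimum_image(pos[b] - pos[a])
            e += bond_energy(float(np.linalg.norm(d)), p)
    angles = config.angle_array()
    if len(angles) and p.nu_ba:
        sel = angles[(angles == i).any(axis=1)]
        for a, b, c in sel:
            u = config.minimum_image(pos[b] - pos[a])
            v = config.minimum_image(pos[c] - pos[b])
            cth = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
            e += p.nu_ba * (1.0 - min(1.0, max(-1.0, cth)))
    others = np.arange(config.n_beads)
    others = others[others != i]
    if p.exclude_bonded and len(bonds):
        nb = set(bonds[bonds[:, 0] == i, 1]) | set(bonds[bonds[:, 1] == i, 0])
        others = np.array([j for j in others if j not in nb], dtype=np.int64)
    if len(others):
        e += _pair_energy_matrix(config, p, np.array([i]), others)
    return e


def delta_energy(config: Configuration, move, p: ForceFieldParams | None = None) -> float:
    """Energy change of a proposed move, total_energy(after) - (before).

    Bead moves evaluate only the terms touching the moved bead; box
    rescales recompute the full energy at both box shapes.
    """
    if p is None:
        p = ForceFieldParams()
    if isinstance(move, BeadMove):
        before = _bead_local_energy(config, move.index, p)
        trial = config.copy()
        trial.positions[move.index] = np.asarray(move.new_position, dtype=float) % trial.box
        after = _bead_local_energy(trial, move.index, p)
        return after - before
    if isinstance(move, BoxScale):
        trial = config.copy()
        trial.positions[:, move.axis] *= move.factor
        trial.box[move.axis] *= move.factor
        return total_energy(trial, p) - total_energy(config, p)
    raise TypeError(f"unknown move type {type(move)!r}")
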