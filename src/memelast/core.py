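"""Core data structures: bead kinds and particle configurations.

All quantities are in reduced units: lengths in units of the tail-bead
Lennard-Jones diameter sigma_LJ, energies in units of epsilon, k_B = 1,
so temperature is epsilon/k_B and pressure epsilon/sigma_LJ^3.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np


class BeadKind(IntEnum):
    """Bead species of the coarse-grained amphiphile model.

    A lipid is one `head` bead followed by six `tail` beads; solvent
    beads are single-bead phantom particles (they interact with lipid
    beads but not with each other).
    """

    head = 0
    tail = 1
    solvent = 2


BEADS_PER_LIPID = 7


@dataclass
class Configuration:
    """A particle configuration in a periodic orthorhombic box.

    Parameters
    ----------
    positions : (N, 3) float array
        Bead coordinates in sigma_LJ.  Wrapped into [0, L) on periodic
        axes by :meth:`wrap`.
    kinds : (N,) int array
        ``BeadKind`` value per bead.
    molecules : list of lists of int
        Bead indices per molecule.  Lipids are chains head-first
        (1 head + 6 tails); solvent beads are singletons.
    box : (3,) float array
        Box lengths (L_x, L_y, L_z).
    periodic : tuple of bool
        Per-axis periodicity flags.  The engine treats all axes as
        periodic; the flags are metadata for analysis and I/O.
    bonds : (B, 2) int array, optional
        Explicit bond list.  If omitted, bonds are the consecutive
        pairs of every multi-bead molecule (the lipid chains).
        Explicit bonds are used by the toy spring networks.
    """

    positions: np.ndarray
    kinds: np.ndarray
    molecules: list = field(default_factory=list)
    box: np.ndarray = None
    periodic: tuple = (True, True, True)
    bonds: np.ndarray | None = None

    def __post_init__(self):
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.kinds = np.ascontiguousarray(self.kinds, dtype=np.int64)
        self.box = np.ascontiguousarray(self.box, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (N, 3)")
        if self.kinds.shape[0] != self.positions.shape[0]:
            raise ValueError("kinds length must match positions")
        if self.bonds is not None:
            self.bonds = np.ascontiguousarray(self.bonds, dtype=np.int64)

    # ------------------------------------------------------------------
    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    @property
    def lipids(self) -> list:
        """Molecules with more than one bead (the amphiphile chains)."""
        return [m for m in self.molecules if len(m) > 1]

    @property
    def n_lipids(self) -> int:
        return len(self.lipids)

    @property
    def volume(self) -> float:
        return float(np.prod(self.box))

    # ------------------------------------------------------------------
    def bond_array(self) -> np.ndarray:
        """(B, 2) bonded pairs: explicit list, else chain-consecutive."""
        if self.bonds is not None:
            return self.bonds
        pairs = []
        for mol in self.molecules:
            for a, b in zip(mol[:-1], mol[1:]):
                pairs.append((a, b))
        return np.asarray(pairs, dtype=np.int64).reshape(-1, 2)

    def angle_array(self) -> np.ndarray:
        """(A, 3) bond-angle triples along each chain.

        Only chain-derived angles exist; explicit-bond systems (spring
        networks) carry no angle terms.
        """
        if self.bonds is not None:
            return np.empty((0, 3), dtype=np.int64)
        triples = []
        for mol in self.molecules:
            for a, b, c in zip(mol[:-2], mol[1:-1], mol[2:]):
                triples.append((a, b, c))
        return np.asarray(triples, dtype=np.int64).reshape(-1, 3)

    # ------------------------------------------------------------------
    def minimum_image(self, d: np.ndarray) -> np.ndarray:
        """Apply the minimum-image convention to displacement vectors."""
        d = np.asarray(d, dtype=np.float64)
        return d - self.box * np.round(d / self.box)

    def wrap(self) -> "Configuration":
        """Wrap coordinates into the primary box (in place); returns self."""
        self.positions %= self.box
        return self

    def copy(self) -> "Configuration":
        return Configuration(
            positions=self.positions.copy(),
            kinds=self.kinds.copy(),
            molecules=[list(m) for m in self.molecules],
            box=self.box.copy(),
            periodic=tuple(self.periodic),
            bonds=None if self.bonds is None else self.bonds.copy(),
        )
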