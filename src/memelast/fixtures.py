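"""Synthetic systems that make every analysis stage testable cheaply.

* :func:`make_helfrich_ensemble` draws height-field frames exactly from
  the Helfrich mode-power distribution — the sampling oracle for the
  spectrum fit.
* :func:`make_triangular_network` builds a periodic 2-D triangular
  lattice of central-force harmonic springs, whose continuum Poisson's
  ratio is exactly 1/3 — the oracle for the rescaling protocol; it
  reuses the full MC machinery (springs instead of FENE chains, no
  angle terms, no pair interactions), demonstrating that the protocol
  is agnostic to the microscopic model.
* :func:`make_phantom_gas` builds a box of non-interacting solvent
  beads: an exact ideal gas whose NPT mean volume is N*T/P — the
  barostat oracle.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize

from .core import BeadKind, Configuration
from .forcefield import ForceFieldParams
from .spectrum import HeightField

__all__ = ["ToyNetwork", "make_helfrich_ensemble", "make_triangular_network",
           "make_phantom_gas", "static_poisson_ratio"]


# ----------------------------------------------------------------------
def make_helfrich_ensemble(k_c: float, sigma_tension: float, T: float,
                           L: float, grid_n: int, frames: int,
                           seed: int = 0) -> list:
    """i.i.d. height-field frames with exact Helfrich mode powers.

    Each Fourier mode's complex amplitude has independent Gaussian
    real/imaginary parts of total variance k_B T L^2/(k_c q^4 + sigma
    q^2), Hermitian-symmetrised so every frame is real.  Construction:
    white real-space Gaussian noise is Fourier-filtered by sqrt of the
    target power, which gives the Hermitian symmetry for free.
    """
    if grid_n < 4:
        raise ValueError("grid_n must be >= 4")
    if frames < 1:
        raise ValueError("frames must be >= 1")
    if k_c == 0 and sigma_tension == 0:
        raise ValueError("k_c and sigma cannot both vanish (amplitudes undefined)")
    rng = np.random.default_rng(seed)
    a = L / grid_n
    q1 = 2 * np.pi * np.fft.fftfreq(grid_n, d=a)
    QX, QY = np.meshgrid(q1, q1, indexing="ij")
    q2 = QX ** 2 + QY ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        S = T * L * L / (k_c * q2 ** 2 + sigma_tension * q2)
    S[0, 0] = 0.0  # mean-zero field
    if not np.isfinite(S).all():
        raise ValueError("non-finite mode power (check k_c, sigma signs)")
    amp = np.sqrt(S / grid_n ** 2)
    out = []
    for _ in range(frames):
        white = rng.standard_normal((grid_n, grid_n))
        h_hat = np.fft.fft2(white) * amp          # <|h_hat|^2> = S exactly
        h = np.fft.ifft2(h_hat / a ** 2)
        assert np.abs(h.imag).max() < 1e-10
        h = h.real
        h -= h.mean()
        out.append(HeightField(h=h, spacing=a, box=(L, L)))
    return out


# ----------------------------------------------------------------------
@dataclass
class ToyNetwork:
    """Periodic 2-D triangular lattice of identical harmonic springs."""

    positions: np.ndarray     # (N, 3); z = 0
    springs: np.ndarray       # (S, 2) node pairs
    rest_length: float
    stiffness: float
    box: np.ndarray           # (3,)
    periodic: tuple = (True, True, False)

    @property
    def n_nodes(self) -> int:
        return self.positions.shape[0]

    def to_configuration(self) -> Configuration:
        """As a Configuration of `solvent` beads (all pair terms inactive
        by the interaction table) with explicit harmonic bonds."""
        n = self.n_nodes
        return Configuration(
            positions=self.positions.copy(),
            kinds=np.full(n, int(BeadKind.solvent)),
            molecules=[[i] for i in range(n)],
            box=self.box.copy(),
            bonds=self.springs.copy(),
        )

    def forcefield(self) -> ForceFieldParams:
        return ForceFieldParams(bond_style="harmonic",
                                harmonic_k=self.stiffness,
                                r0=self.rest_length, nu_ba=0.0)


def make_triangular_network(n: int, spacing: float = 1.0,
                            stiffness: float = 100.0, seed: int = 0) -> ToyNetwork:
    """n x n periodic triangular lattice (n even for commensurability).

    Nodes sit at (i + 0.5*(j%2), j*sqrt(3)/2)*spacing; each node bonds
    to its six nearest neighbours (three stored per node), so the
    network percolates across both periodic lateral boundaries.
    ``seed`` is accepted for interface uniformity (the construction is
    deterministic).
    """
    if n < 4:
        raise ValueError("n must be >= 4")
    if n % 2:
        raise ValueError("n must be even for a commensurate periodic lattice")
    ry = np.sqrt(3.0) / 2.0 * spacing
    Lx, Ly = n * spacing, n * ry
    pos = np.zeros((n * n, 3))
    idx = lambda i, j: (i % n) * n + (j % n)
    for i in range(n):
        for j in range(n):
            pos[idx(i, j), 0] = (i + 0.5 * (j % 2)) * spacing
            pos[idx(i, j), 1] = j * ry
    springs = []
    for i in range(n):
        for j in range(n):
            a = idx(i, j)
            springs.append((a, idx(i + 1, j)))                    # right
            if j % 2 == 0:
                springs.append((a, idx(i, j + 1)))                # up-right
                springs.append((a, idx(i - 1, j + 1)))            # up-left
            else:
                springs.append((a, idx(i + 1, j + 1)))
                springs.append((a, idx(i, j + 1)))
    return ToyNetwork(positions=pos, springs=np.asarray(springs, dtype=np.int64),
                      rest_length=spacing, stiffness=stiffness,
                      box=np.array([Lx, Ly, 1.0]))


def _network_energy(sx, y, Lx, Ly, springs, k, L0):
    dx = sx[springs[:, 0]] - sx[springs[:, 1]]
    dx -= np.round(dx)
    dy = y[springs[:, 0]] - y[springs[:, 1]]
    dy -= Ly * np.round(dy / Ly)
    r = np.sqrt((Lx * dx) ** 2 + dy ** 2)
    return 0.5 * k * ((r - L0) ** 2).sum()


def static_poisson_ratio(network: ToyNetwork, eta: float = 0.02) -> float:
    """Zero-temperature oracle: impose strain eta on L_y, minimise the
    spring energy over all node positions and the transverse box length
    L_x, and return nu = -dL_x/(eta L_x0).

    Continuum elasticity of the central-force triangular lattice gives
    nu = 1/3 (Lame coefficients lambda = mu).
    """
    Lx0, Ly0 = float(network.box[0]), float(network.box[1])
    Ly = Ly0 * (1.0 + eta)
    pos = network.positions
    y0 = pos[:, 1] * (1.0 + eta)
    n = network.n_nodes
    springs = network.springs
    k, L0 = network.stiffness, network.rest_length

    def fun(v):
        sx = v[:n]
        y = v[n:2 * n]
        Lx = v[-1]
        return _network_energy(sx, y, Lx, Ly, springs, k, L0)

    v0 = np.concatenate([pos[:, 0] / Lx0, y0, [Lx0]])
    res = minimize(fun, v0, method="L-BFGS-B",
                   options={"maxiter": 5000, "ftol": 1e-14, "gtol": 1e-10})
    Lx = float(res.x[-1])
    return -(Lx - Lx0) / (eta * Lx0)


# ----------------------------------------------------------------------
def make_phantom_gas(n: int, box, seed: int = 0) -> Configuration:
    """n phantom (mutually non-interacting) solvent beads in a box."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    box = np.asarray(box, dtype=float)
    pos = rng.uniform(0.0, 1.0, size=(n, 3)) * box
    return Configuration(positions=pos, kinds=np.full(n, int(BeadKind.solvent)),
                         molecules=[[i] for i in range(n)], box=box.copy())
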