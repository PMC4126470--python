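"""NPT Metropolis Monte Carlo driver.

The Python layer packs a :class:`~memelast.core.Configuration` and
:class:`~memelast.forcefield.ForceFieldParams` into flat arrays, runs
the numba kernel in chunks (so temperature schedules and periodic
membrane-descriptor measurements are possible), and collects the
per-sweep observable series.

All randomness derives from ``MCSettings.seed`` through a numpy
``SeedSequence``: identical settings give a bit-identical trajectory.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _kernel
from .core import Configuration
from .forcefield import FeneDomainError, ForceFieldParams

__all__ = ["MCSettings", "ObservableSeries", "run_mc", "equilibrate_phase",
           "kernel_total_energy", "HarmonicWell"]


@dataclass(frozen=True)
class HarmonicWell:
    """External tether 0.5*k*|r - center|^2 applied to every bead.

    A test hook: with a single bead and all box axes fixed, the sampled
    position distribution must be the Boltzmann Gaussian of width
    sqrt(T/k) in each coordinate.
    """

    k: float
    center: tuple = (0.0, 0.0, 0.0)


@dataclass
class MCSettings:
    """Sampling-engine knobs.

    displacement_max is the half-width of the cubic trial-displacement
    window (sigma_LJ); box_move_max the half-width of the uniform step
    in ln L.  ``fixed_axes`` lists box axes whose length is never
    changed ('x', 'y', 'z'); ``move_dims`` masks which Cartesian
    components displacement moves touch (quasi-2D systems freeze z).
    Acceptance-rate adaptation (equilibration only — it breaks detailed
    balance) rescales both step sizes toward ``target_acceptance``
    between chunks.
    """

    sweeps: int = 1000
    displacement_max: float = 0.15
    box_move_max: float = 0.01
    fixed_axes: tuple = ()
    move_dims: tuple = (True, True, True)
    seed: int = 0
    sample_stride: int = 1
    chunk_sweeps: int = 1000
    adapt_acceptance: bool = False
    target_acceptance: float = 0.4
    well: HarmonicWell | None = None

    def __post_init__(self):
        if self.displacement_max <= 0:
            raise ValueError("displacement_max must be positive")
        if not 0 < self.target_acceptance < 1:
            raise ValueError("target acceptance must be in (0, 1)")
        bad = set(self.fixed_axes) - {"x", "y", "z"}
        if bad:
            raise ValueError(f"unknown fixed axes {bad}")


@dataclass
class ObservableSeries:
    """Per-sweep record of box lengths, energy, volume (+ optional
    membrane descriptors at a coarser stride)."""

    data: pd.DataFrame
    descriptors: pd.DataFrame | None = None
    acceptance_displacement: float = float("nan")
    acceptance_box: float = float("nan")

    def mean_box(self, last_fraction: float = 0.25) -> dict:
        """Mean box lengths over the trailing fraction of the series."""
        n = len(self.data)
        tail = self.data.iloc[int(np.floor(n * (1 - last_fraction))):]
        return {a: float(tail[f"L{a}"].mean()) for a in "xyz"}

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    def __len__(self):
        return len(self.data)


# ----------------------------------------------------------------------
def _csr(n_items: int, members) -> tuple:
    """Bead -> term-index CSR arrays from an iterable of index tuples."""
    counts = np.zeros(n_items + 1, dtype=np.int64)
    flat_members = list(members)
    for term_idx, beads in flat_members:
        for b in beads:
            counts[b + 1] += 1
    start = np.cumsum(counts)
    fill = start[:-1].copy()
    flat = np.zeros(start[-1], dtype=np.int64)
    for term_idx, beads in flat_members:
        for b in beads:
            flat[fill[b]] = term_idx
            fill[b] += 1
    return start, flat


def _pack_system(config: Configuration, ff: ForceFieldParams):
    n = config.n_beads
    bonds = config.bond_array()
    nb = len(bonds)
    bond_i = np.ascontiguousarray(bonds[:, 0]) if nb else np.empty(0, np.int64)
    bond_j = np.ascontiguousarray(bonds[:, 1]) if nb else np.empty(0, np.int64)
    style_code = 0 if ff.bond_style == "fene" else 1
    bond_style = np.full(nb, style_code, dtype=np.int64)
    k = ff.nu_fene if style_code == 0 else ff.harmonic_k
    bond_k = np.full(nb, float(k))
    bond_r0 = np.full(nb, float(ff.r0))
    bond_drm = np.full(nb, float(ff.dr_m))
    bead_bond_start, bead_bond_flat = _csr(
        n, ((t, (bonds[t, 0], bonds[t, 1])) for t in range(nb)))

    angles = config.angle_array()
    na = len(angles)
    ang_i = np.ascontiguousarray(angles[:, 0]) if na else np.empty(0, np.int64)
    ang_j = np.ascontiguousarray(angles[:, 1]) if na else np.empty(0, np.int64)
    ang_k = np.ascontiguousarray(angles[:, 2]) if na else np.empty(0, np.int64)
    bead_ang_start, bead_ang_flat = _csr(
        n, ((t, tuple(angles[t])) for t in range(na)))

    eps, sig, rc2, shift, active = ff.tables()
    if ff.exclude_bonded and nb:
        excl_start, excl_flat = _excl_csr(n, bonds)
    else:
        excl_start = np.zeros(n + 1, dtype=np.int64)
        excl_flat = np.empty(0, dtype=np.int64)
    return dict(
        bond_i=bond_i, bond_j=bond_j, bond_style=bond_style,
        bond_k=bond_k, bond_r0=bond_r0, bond_drm=bond_drm,
        bead_bond_start=bead_bond_start, bead_bond_flat=bead_bond_flat,
        ang_i=ang_i, ang_j=ang_j, ang_k=ang_k, nu_ba=float(ff.nu_ba),
        bead_ang_start=bead_ang_start, bead_ang_flat=bead_ang_flat,
        eps=eps, sig=sig, rc2=rc2, shift=shift, active=active,
        excl_start=excl_start, excl_flat=excl_flat,
    )


def _excl_csr(n, bonds):
    counts = np.zeros(n + 1, dtype=np.int64)
    for a, b in bonds:
        counts[a + 1] += 1
        counts[b + 1] += 1
    start = np.cumsum(counts)
    fill = start[:-1].copy()
    flat = np.zeros(start[-1], dtype=np.int64)
    for a, b in bonds:
        flat[fill[a]] = b
        fill[a] += 1
        flat[fill[b]] = a
        fill[b] += 1
    return start, flat


def kernel_total_energy(config: Configuration, ff: ForceFieldParams | None = None) -> float:
    """Total energy through the cell-list kernel (cross-check path)."""
    if ff is None:
        ff = ForceFieldParams()
    sys_ = _pack_system(config, ff)
    edge = max(ff.max_cutoff(), 1.0)
    e = _kernel.total_energy_kernel(
        config.positions.copy(), config.kinds, config.box.copy(),
        sys_["bond_i"], sys_["bond_j"], sys_["bond_style"],
        sys_["bond_k"], sys_["bond_r0"], sys_["bond_drm"],
        sys_["ang_i"], sys_["ang_j"], sys_["ang_k"], sys_["nu_ba"],
        sys_["eps"], sys_["sig"], sys_["rc2"], sys_["shift"], sys_["active"],
        sys_["excl_start"], sys_["excl_flat"], edge)
    if e >= _kernel.BIG:
        raise FeneDomainError(float("nan"))
    return float(e)


# ----------------------------------------------------------------------
def run_mc(config: Configuration, phase, settings: MCSettings,
           ff: ForceFieldParams | None = None, *,
           T: float | None = None, P: float | None = None,
           descriptor_stride: int | None = None):
    """Run NPT Metropolis MC; returns (final Configuration, ObservableSeries).

    ``phase`` supplies (T, P) unless overridden explicitly (pass
    ``phase=None`` with ``T=``/``P=`` for bare state points).  The input
    configuration is not modified.
    """
    if ff is None:
        ff = ForceFieldParams()
    if isinstance(phase, str):
        from .builder import PHASES
        phase = PHASES[phase]
    if T is None:
        T = phase.T
    if P is None:
        P = phase.P
    cfg = config.copy().wrap()
    if settings.sweeps == 0:
        empty = pd.DataFrame(columns=["sweep", "Lx", "Ly", "Lz", "energy", "volume"])
        return cfg, ObservableSeries(empty)

    sys_ = _pack_system(cfg, ff)
    well = settings.well
    well_k = 0.0 if well is None else float(well.k)
    wc = (0.0, 0.0, 0.0) if well is None else tuple(float(c) for c in well.center)
    free = tuple(a not in settings.fixed_axes for a in "xyz")
    move = tuple(bool(m) for m in settings.move_dims)

    chunk = max(1, min(settings.chunk_sweeps, settings.sweeps))
    if descriptor_stride is not None:
        chunk = min(chunk, descriptor_stride)
    n_chunks = int(np.ceil(settings.sweeps / chunk))
    seeds = np.random.SeedSequence(settings.seed).generate_state(n_chunks)
    disp_max = settings.displacement_max
    box_step = settings.box_move_max

    frames = []
    desc_rows = []
    acc_d = att_d = acc_b = att_b = 0
    done = 0
    for ic in range(n_chunks):
        this = min(chunk, settings.sweeps - done)
        obs, U, ad, td, ab, tb = _kernel.run_npt(
            cfg.positions, cfg.kinds, cfg.box,
            sys_["bond_i"], sys_["bond_j"], sys_["bond_style"],
            sys_["bond_k"], sys_["bond_r0"], sys_["bond_drm"],
            sys_["bead_bond_start"], sys_["bead_bond_flat"],
            sys_["ang_i"], sys_["ang_j"], sys_["ang_k"], sys_["nu_ba"],
            sys_["bead_ang_start"], sys_["bead_ang_flat"],
            sys_["eps"], sys_["sig"], sys_["rc2"], sys_["shift"], sys_["active"],
            sys_["excl_start"], sys_["excl_flat"],
            well_k, wc[0], wc[1], wc[2],
            float(T), float(P), disp_max, box_step,
            move[0], move[1], move[2],
            free[0], free[1], free[2],
            this, settings.sample_stride, int(seeds[ic] & 0x7FFFFFFF))
        sweeps_rec = done + (np.arange(1, obs.shape[0] + 1) * settings.sample_stride)
        frames.append(np.column_stack([sweeps_rec, obs]))
        acc_d += ad
        att_d += td
        acc_b += ab
        att_b += tb
        done += this
        if descriptor_stride is not None and done % descriptor_stride == 0:
            from .builder import membrane_descriptors
            try:
                md = membrane_descriptors(cfg)
                desc_rows.append((done, md.chain_length_mean, md.thickness,
                                  md.area_per_lipid, md.order_parameter))
            except Exception:
                desc_rows.append((done, np.nan, np.nan, np.nan, np.nan))
        if settings.adapt_acceptance and td:
            rate = ad / td
            disp_max = float(np.clip(disp_max * np.exp(0.5 * (rate - settings.target_acceptance)),
                                     1e-4, 2.0))
            if tb:
                brate = ab / tb
                box_step = float(np.clip(box_step * np.exp(0.5 * (brate - settings.target_acceptance)),
                                         1e-6, 0.2))

    data = pd.DataFrame(np.vstack(frames),
                        columns=["sweep", "Lx", "Ly", "Lz", "energy", "volume"])
    desc = None
    if desc_rows:
        desc = pd.DataFrame(desc_rows, columns=["sweep", "chain_length", "thickness",
                                                "area_per_lipid", "order_parameter"])
    series = ObservableSeries(
        data, desc,
        acceptance_displacement=acc_d / att_d if att_d else float("nan"),
        acceptance_box=acc_b / att_b if att_b else float("nan"))
    if att_d and acc_d / att_d < 0.01:
        warnings.warn("displacement acceptance below 1% — step size likely too large",
                      RuntimeWarning)
    return cfg, series


def equilibrate_phase(size, phase, sweeps, seed, *, ff=None,
                      settings: MCSettings | None = None,
                      descriptor_stride: int | None = 200, **build_kwargs):
    """Build a bilayer for ``phase`` and equilibrate it at (P, T).

    ``size`` is (nx, ny) lipids per leaflet.  Step-size adaptation is on
    by default here (equilibration only).
    """
    from .builder import build_bilayer
    nx, ny = size
    cfg = build_bilayer(nx, ny, phase, seed=seed, **build_kwargs)
    if sweeps == 0:
        empty = pd.DataFrame(columns=["sweep", "Lx", "Ly", "Lz", "energy", "volume"])
        return cfg, ObservableSeries(empty)
    if settings is None:
        settings = MCSettings(sweeps=sweeps, seed=seed, adapt_acceptance=True)
    else:
        settings = replace(settings, sweeps=sweeps, seed=seed)
    return run_mc(cfg, phase, settings, ff, descriptor_stride=descriptor_stride)
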