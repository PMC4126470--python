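"""Poisson's ratio by box rescaling under periodic boundary conditions.

The protocol: starting from an equilibrated configuration, all
inter-particle distances along one lateral axis j are rescaled by
(1 + eta) together with the box length; that axis is then held fixed
while the remaining axes keep fluctuating at constant pressure.  The
transverse relaxation traces

    nu_ij(t) = -(L_i(t) - L_i(0)) / (eta * L_i(0)),   i != j,

plateau at the Poisson's ratio nu_ij, with L_i(0) the pre-strain
equilibrium mean.  A brief temperature bump right after the rescale
accelerates re-thermalisation.  Rescaling along z is forbidden: it
would stretch intramolecular bonds and break them.

The z response is reported twice: from the box length L_z (which
includes the solvent slab) and from the membrane thickness d, when the
configuration contains a bilayer.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .builder import LeafletError, PhasePoint, membrane_descriptors
from .core import Configuration
from .forcefield import FeneDomainError, ForceFieldParams
from .mc import MCSettings, ObservableSeries, run_mc

__all__ = ["PoissonResult", "rescale_axial", "max_admissible_strain",
           "measure_poisson"]

_AXIS = {"x": 0, "y": 1, "z": 2}


@dataclass
class PoissonResult:
    """Relaxation traces and plateau-averaged Poisson's ratios.

    ``nu`` maps a response label to (estimate, stderr): ``"xy"`` is
    nu_xy (x response to a y strain) etc.; ``"zy_thickness"`` is the
    membrane-thickness-based z response.  ``converged`` flags whether
    the trace slope over the averaging window is below stderr/window.
    """

    eta: float
    axis: str
    traces: pd.DataFrame
    plateau_window: tuple
    nu: dict
    converged: dict
    baseline: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [f"Poisson protocol: strain eta={self.eta:g} along {self.axis}",
                 f"plateau window: sweeps {self.plateau_window[0]}..{self.plateau_window[1]}"]
        for key, (val, err) in self.nu.items():
            flag = "" if self.converged.get(key, True) else "  [NOT CONVERGED]"
            lines.append(f"  nu_{key} = {val:+.4f} +- {err:.4f}{flag}")
        return "\n".join(lines)

    def plot_traces(self, ax=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        for col in self.traces.columns:
            if col != "sweep":
                ax.plot(self.traces["sweep"], self.traces[col], label=f"nu_{col}")
        ax.axvspan(*self.plateau_window, alpha=0.15, color="grey")
        ax.set_xlabel("MC sweep")
        ax.set_ylabel(r"$-\Delta L_i/(\eta L_i)$")
        ax.legend()
        return ax


# ----------------------------------------------------------------------
def max_admissible_strain(config: Configuration, axis: str,
                          ff: ForceFieldParams | None = None) -> float:
    """Largest eta for which no bond leaves the FENE domain after rescale."""
    if ff is None:
        ff = ForceFieldParams()
    a = _AXIS[axis]
    bonds = config.bond_array()
    if len(bonds) == 0:
        return np.inf
    d = config.minimum_image(config.positions[bonds[:, 1]] - config.positions[bonds[:, 0]])
    r_max = ff.r0 + ff.dr_m
    perp2 = (d * d).sum(axis=1) - d[:, a] ** 2
    da2 = d[:, a] ** 2
    ok = da2 > 1e-30
    if not ok.any():
        return np.inf
    # per bond: (1+eta)^2 * da^2 + perp2 < r_max^2
    lim2 = (r_max ** 2 - perp2[ok]) / da2[ok]
    lim2 = np.maximum(lim2, 0.0)
    return float(np.sqrt(lim2.min()) - 1.0)


def rescale_axial(config: Configuration, eta: float, axis: str,
                  ff: ForceFieldParams | None = None) -> Configuration:
    """Affinely stretch one lateral axis by (1 + eta); guards FENE bonds.

    ``axis`` must be 'x' or 'y': an axial rescale along z would stretch
    the intra-lipid bonds themselves and break them.
    """
    if axis not in ("x", "y"):
        raise ValueError("rescaling is only defined along the lateral axes 'x'/'y'")
    if eta <= -1.0:
        raise ValueError("eta must exceed -1")
    if ff is None:
        ff = ForceFieldParams()
    out = config.copy()
    if eta == 0.0:
        return out
    if ff.bond_style == "fene" and len(config.bond_array()):
        eta_max = max_admissible_strain(config, axis, ff)
        if eta >= eta_max:
            err = FeneDomainError(ff.r0 + ff.dr_m)
            err.args = (f"rescale by eta={eta:g} would break a bond; max "
                        f"admissible eta for this configuration is {eta_max:.4g}",)
            raise err
    a = _AXIS[axis]
    out.positions[:, a] *= (1.0 + eta)
    out.box[a] *= (1.0 + eta)
    return out


def _block_stats(x: np.ndarray, n_blocks: int = 10):
    n = len(x)
    if n < n_blocks:
        return float(np.mean(x)), float(np.std(x) / max(np.sqrt(n), 1))
    usable = n - n % n_blocks
    blocks = x[:usable].reshape(n_blocks, -1).mean(axis=1)
    return float(blocks.mean()), float(blocks.std(ddof=1) / np.sqrt(n_blocks))


def measure_poisson(config: Configuration, phase: PhasePoint, eta: float,
                    axis: str, *,
                    relax_sweeps: int = 20000,
                    anneal_sweeps: int = 400,
                    burn_in: int = 5000,
                    pre_sweeps: int = 2000,
                    settings: MCSettings | None = None,
                    ff: ForceFieldParams | None = None,
                    baseline: dict | None = None,
                    thickness_stride: int | None = None) -> PoissonResult:
    """Run the full rescale-and-relax protocol; returns a PoissonResult.

    Parameters
    ----------
    config : Configuration
        Pre-equilibrated at the phase's (P, T).
    eta : float
        Axial strain; the strained box length is held at exactly
        (1+eta)*L_axis for the whole relaxation.
    axis : 'x' or 'y'
        Strained axis (z is forbidden — bonds would break).
    relax_sweeps : int
        Total sweeps after the rescale (the first ``anneal_sweeps`` of
        them at the bumped temperature ``phase.T_anneal``).
    burn_in : int
        Sweeps discarded before plateau averaging.
    pre_sweeps : int
        Unconstrained pre-run measuring the baseline means L_i(0)
        (average over its last quarter); skipped when ``baseline``
        supplies them directly ({'x': Lx0, ..., 'thickness': d0}).
    thickness_stride : int, optional
        Sample the membrane thickness every so many sweeps for the
        secondary z estimate (lipid systems only).
    """
    if axis not in ("x", "y"):
        raise ValueError("strain axis must be 'x' or 'y'")
    if isinstance(phase, str):
        from .builder import PHASES
        phase = PHASES[phase]
    if ff is None:
        ff = ForceFieldParams()
    if settings is None:
        settings = MCSettings()
    if burn_in >= relax_sweeps:
        raise ValueError("burn_in must be smaller than relax_sweeps")
    free_axes = [a for a in ("x", "y", "z") if a != axis and a not in settings.fixed_axes]

    cfg = config
    if baseline is None:
        pre_settings = replace(settings, sweeps=pre_sweeps, adapt_acceptance=False,
                               sample_stride=1, seed=settings.seed + 1)
        cfg, pre_obs = run_mc(cfg, phase, pre_settings, ff,
                              descriptor_stride=thickness_stride)
        baseline = pre_obs.mean_box(last_fraction=0.25)
        if thickness_stride is not None and pre_obs.descriptors is not None:
            dsc = pre_obs.descriptors
            tail = dsc.iloc[int(np.floor(len(dsc) * 0.75)):]
            baseline["thickness"] = float(tail["thickness"].mean())

    strained = rescale_axial(cfg, eta, axis, ff)

    fixed = tuple(sorted(set(settings.fixed_axes) | {axis}))
    obs_frames = []
    desc_frames = []
    cur = strained
    segments = []
    if anneal_sweeps > 0:
        segments.append((min(anneal_sweeps, relax_sweeps), phase.T_anneal, 2))
    remainder = relax_sweeps - (segments[0][0] if segments else 0)
    if remainder > 0:
        segments.append((remainder, phase.T, 3))
    done = 0
    for seg_sweeps, seg_T, seed_off in segments:
        seg_settings = replace(settings, sweeps=seg_sweeps, fixed_axes=fixed,
                               adapt_acceptance=False, sample_stride=1,
                               seed=settings.seed + seed_off)
        cur, obs = run_mc(cur, phase, seg_settings, ff, T=seg_T,
                          descriptor_stride=thickness_stride)
        df = obs.data.copy()
        df["sweep"] += done
        obs_frames.append(df)
        if obs.descriptors is not None:
            dd = obs.descriptors.copy()
            dd["sweep"] += done
            desc_frames.append(dd)
        done += seg_sweeps

    data = pd.concat(obs_frames, ignore_index=True)
    denom = eta if eta != 0.0 else 1.0

    traces = pd.DataFrame({"sweep": data["sweep"]})
    for a in free_axes:
        L0 = baseline[a]
        traces[f"{a}{axis}"] = -(data[f"L{a}"] - L0) / (denom * L0)

    nu = {}
    converged = {}
    sel = traces["sweep"] > burn_in
    window = (burn_in, int(traces["sweep"].max()))
    wlen = max(int(sel.sum()), 1)
    for a in free_axes:
        y = traces.loc[sel, f"{a}{axis}"].to_numpy()
        est, err = _block_stats(y)
        nu[f"{a}{axis}"] = (est, err)
        slope = np.polyfit(np.arange(len(y)), y, 1)[0] if len(y) > 2 else 0.0
        # drift across the averaging window must stay below one stderr
        converged[f"{a}{axis}"] = bool(abs(slope) * wlen < max(err, 1e-12))

    if desc_frames and "thickness" in baseline:
        dsc = pd.concat(desc_frames, ignore_index=True).dropna(subset=["thickness"])
        d0 = baseline["thickness"]
        th_trace = -(dsc["thickness"] - d0) / (denom * d0)
        traces_th = pd.DataFrame({"sweep": dsc["sweep"],
                                  f"z{axis}_thickness": th_trace})
        traces = traces.merge(traces_th, on="sweep", how="left")
        y = th_trace[dsc["sweep"] > burn_in].to_numpy()
        if len(y):
            est, err = _block_stats(y)
            nu[f"z{axis}_thickness"] = (est, err)
            converged[f"z{axis}_thickness"] = True

    return PoissonResult(eta=eta, axis=axis, traces=traces,
                         plateau_window=window, nu=nu, converged=converged,
                         baseline=dict(baseline))
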