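"""Membrane height field, undulation power spectrum, and Helfrich fit.

In Monge gauge the small-fluctuation Helfrich free energy

    H = int dx dy [ (k_c/2) (laplacian h)^2 + (sigma/2) (grad h)^2 ]

gives equipartition mode powers

    <|h_hat(q)|^2> = k_B T L^2 / (k_c q^4 + sigma q^2)

for a membrane of lateral area L^2, with h_hat the continuum Fourier
transform.  Numerically, h(x, y) is the mid-surface height — the mean
of the two leaflet head-bead heights per cell of a regular grid
(spacing 2 sigma_LJ by default), mean-subtracted — and h_hat(q) is its
discrete Fourier transform scaled by the cell area, so the continuum
convention (and Parseval's identity) holds exactly.

The fit linearises the spectrum: y(q) = k_B T L^2 / (<|h_hat|^2> q^2)
= k_c q^2 + sigma, an ordinary least-squares line in q^2 over a fit
window (default 0.5 <= q^2 <= 1, where neither the box size nor the
bead discreteness distorts the spectrum at feasible system sizes).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .builder import LeafletError, _circular_mean
from .core import Configuration

__all__ = ["HeightField", "SpectrumFit", "SpectrumError", "height_field",
           "power_spectrum", "average_power", "bin_radially", "fit_helfrich"]


class SpectrumError(ValueError):
    """Spectrum construction or fit failure (flagged, not silent)."""


@dataclass
class HeightField:
    """Mean-zero mid-surface height h(i, j) on a regular lateral grid."""

    h: np.ndarray          # (nx, ny), grid mean subtracted
    spacing: float         # sigma_LJ
    box: tuple             # (Lx, Ly)

    def __post_init__(self):
        self.h = np.asarray(self.h, dtype=np.float64)
        if self.h.ndim != 2:
            raise ValueError("h must be 2-D")

    @property
    def cell_area(self) -> float:
        lx, ly = self.box
        return (lx / self.h.shape[0]) * (ly / self.h.shape[1])


@dataclass
class SpectrumFit:
    """Result of the Helfrich-spectrum fit.

    k_c (bending rigidity, epsilon) is the slope and sigma_tension
    (epsilon/sigma_LJ^2) the intercept of y = k_c q^2 + sigma; modes
    carries the binned spectrum actually fitted.
    """

    modes: pd.DataFrame
    k_c: float
    k_c_stderr: float
    sigma_tension: float
    sigma_stderr: float
    fit_window: tuple
    residual: float
    n_frames: int
    ok: bool = True
    message: str = ""

    def summary(self) -> str:
        lines = [
            "Helfrich spectrum fit",
            f"  frames averaged : {self.n_frames}",
            f"  fit window      : {self.fit_window[0]:g} <= q^2 <= {self.fit_window[1]:g}"
            f"  ({len(self.modes)} q-bins)",
            f"  k_c             : {self.k_c:.4g} +- {self.k_c_stderr:.2g}  (epsilon)",
            f"  sigma           : {self.sigma_tension:.4g} +- {self.sigma_stderr:.2g}"
            "  (epsilon/sigma_LJ^2)",
            f"  rms residual    : {self.residual:.3g}",
        ]
        if not self.ok:
            lines.append(f"  FLAGGED: {self.message}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {"k_c": self.k_c, "k_c_stderr": self.k_c_stderr,
                "sigma_tension": self.sigma_tension,
                "sigma_stderr": self.sigma_stderr,
                "fit_window": list(self.fit_window),
                "residual": self.residual, "n_frames": self.n_frames,
                "ok": self.ok, "message": self.message}


# ----------------------------------------------------------------------
def height_field(config: Configuration, spacing: float = 2.0,
                 max_empty_fraction: float = 0.1) -> HeightField:
    """Grid the head beads into the mid-surface height field.

    Each cell's height is [z_+(i,j) + z_-(i,j)]/2, the mean of the
    upper- and lower-leaflet head heights; the grid mean is subtracted.
    Cells left empty by either leaflet are filled by iterated
    4-neighbour averaging; more than ``max_empty_fraction`` empty cells
    in either leaflet raises (ruptured membrane or too fine a grid).
    """
    lipids = config.lipids
    if not lipids:
        raise LeafletError("no lipid chains present")
    pos = config.positions
    Lx, Ly, Lz = config.box
    nx = max(int(round(Lx / spacing)), 1)
    ny = max(int(round(Ly / spacing)), 1)

    heads = np.array([m[0] for m in lipids])
    z_mid = _circular_mean(pos[np.concatenate(lipids), 2], Lz)
    zh = (pos[heads, 2] - z_mid + Lz / 2.0) % Lz
    upper = zh > Lz / 2.0
    if upper.all() or (~upper).all():
        raise LeafletError("cannot split leaflets for height field")

    ix = np.minimum((pos[heads, 0] % Lx) / Lx * nx, nx - 1).astype(int)
    iy = np.minimum((pos[heads, 1] % Ly) / Ly * ny, ny - 1).astype(int)

    planes = []
    for mask in (upper, ~upper):
        zsum = np.zeros((nx, ny))
        cnt = np.zeros((nx, ny))
        np.add.at(zsum, (ix[mask], iy[mask]), zh[mask])
        np.add.at(cnt, (ix[mask], iy[mask]), 1.0)
        empty = cnt == 0
        if empty.mean() > max_empty_fraction:
            raise SpectrumError(
                f"{empty.mean():.0%} empty cells in a leaflet "
                "(membrane ruptured or grid too fine)")
        plane = np.where(empty, np.nan, zsum / np.maximum(cnt, 1.0))
        planes.append(_fill_empty(plane))
    h = 0.5 * (planes[0] + planes[1])
    h -= h.mean()
    return HeightField(h=h, spacing=spacing, box=(float(Lx), float(Ly)))


def _fill_empty(plane: np.ndarray, max_iter: int = 1000) -> np.ndarray:
    """Fill NaN cells with the mean of their non-empty 4-neighbourhood."""
    p = plane.copy()
    for _ in range(max_iter):
        nan = np.isnan(p)
        if not nan.any():
            return p
        acc = np.zeros_like(p)
        cnt = np.zeros_like(p)
        for shift, ax in ((1, 0), (-1, 0), (1, 1), (-1, 1)):
            nb = np.roll(p, shift, axis=ax)
            good = ~np.isnan(nb)
            acc[good] += nb[good]
            cnt += good
        fill = nan & (cnt > 0)
        p[fill] = acc[fill] / cnt[fill]
    raise SpectrumError("empty-cell fill did not converge")


# ----------------------------------------------------------------------
def power_spectrum(field: HeightField) -> pd.DataFrame:
    """Per-mode power |h_hat(q)|^2 of one height field (zero mode excluded).

    h_hat carries the continuum normalisation (DFT times cell area), so
    sum_q |h_hat(q)|^2 / (Lx Ly) = cell_area * sum_ij h_ij^2 exactly
    (Parseval).  Columns: qx, qy, q, power.
    """
    nx, ny = field.h.shape
    if nx < 4 or ny < 4:
        raise SpectrumError("grid must be at least 4x4")
    Lx, Ly = field.box
    H = np.fft.fft2(field.h) * field.cell_area
    qx = 2 * np.pi * np.fft.fftfreq(nx, d=Lx / nx)
    qy = 2 * np.pi * np.fft.fftfreq(ny, d=Ly / ny)
    QX, QY = np.meshgrid(qx, qy, indexing="ij")
    q = np.sqrt(QX ** 2 + QY ** 2)
    df = pd.DataFrame({
        "qx": QX.ravel(), "qy": QY.ravel(), "q": q.ravel(),
        "power": np.abs(H.ravel()) ** 2,
    })
    return df[df["q"] > 0].reset_index(drop=True)


def average_power(fields) -> pd.DataFrame:
    """Mean per-mode power over an ensemble of height-field frames."""
    fields = list(fields)
    if not fields:
        raise SpectrumError("no frames supplied")
    acc = None
    for f in fields:
        df = power_spectrum(f)
        if acc is None:
            acc = df.copy()
        else:
            acc["power"] += df["power"].to_numpy()
    acc["power"] /= len(fields)
    acc.attrs["n_frames"] = len(fields)
    acc.attrs["box"] = fields[0].box
    return acc


def bin_radially(modes: pd.DataFrame, box=None) -> pd.DataFrame:
    """Radially bin per-mode powers by |q|, bin width 2*pi/max(Lx, Ly)."""
    if box is None:
        box = modes.attrs.get("box")
    if box is None:
        raise ValueError("box lengths required for radial binning")
    width = 2 * np.pi / max(box)
    b = np.round(modes["q"] / width).astype(int)
    g = modes.groupby(b).agg(q=("q", "mean"), power=("power", "mean"),
                             n_modes=("power", "size"))
    g["qsq"] = g["q"] ** 2
    g.attrs.update(modes.attrs)
    return g.reset_index(drop=True)


def fit_helfrich(modes: pd.DataFrame, T: float, L=None,
                 window: tuple = (0.5, 1.0), *,
                 binned: bool = True) -> SpectrumFit:
    """Least-squares fit of k_B T L^2/(<|h_hat|^2> q^2) = k_c q^2 + sigma.

    ``modes`` is an averaged per-mode table (from :func:`average_power`)
    or an already-binned table with a ``qsq`` column.  ``L`` may be a
    scalar (square membrane) or (Lx, Ly); defaults to the box recorded
    on the table.
    """
    box = modes.attrs.get("box")
    if L is None:
        if box is None:
            raise ValueError("membrane size L required")
        Lx, Ly = box
    elif np.isscalar(L):
        Lx = Ly = float(L)
    else:
        Lx, Ly = L
    if binned and "qsq" not in modes.columns:
        modes = bin_radially(modes, box=(Lx, Ly))
    qsq = modes["qsq"] if "qsq" in modes.columns else modes["q"] ** 2
    sel = (qsq >= window[0]) & (qsq <= window[1])
    sub = modes[sel]
    if len(sub) < 3:
        raise SpectrumError(f"only {len(sub)} q-bins inside the fit window {window}")
    if (sub["power"] <= 0).any():
        return SpectrumFit(modes=sub, k_c=np.nan, k_c_stderr=np.nan,
                           sigma_tension=np.nan, sigma_stderr=np.nan,
                           fit_window=window, residual=np.nan,
                           n_frames=modes.attrs.get("n_frames", 1),
                           ok=False, message="zero-power modes in fit window")
    x = qsq[sel].to_numpy()
    y = T * Lx * Ly / (sub["power"].to_numpy() * x)
    res = stats.linregress(x, y)
    resid = float(np.sqrt(np.mean((y - (res.slope * x + res.intercept)) ** 2)))
    fit = SpectrumFit(modes=sub.reset_index(drop=True),
                      k_c=float(res.slope), k_c_stderr=float(res.stderr),
                      sigma_tension=float(res.intercept),
                      sigma_stderr=float(res.intercept_stderr),
                      fit_window=tuple(window), residual=resid,
                      n_frames=int(modes.attrs.get("n_frames", 1)))
    if modes.attrs.get("n_frames", 1) < 10:
        fit.ok = False
        fit.message = "under-sampled: fewer than 10 frames averaged"
    if not np.isfinite(fit.k_c) or fit.k_c <= 0:
        fit.ok = False
        fit.message = (fit.message + "; " if fit.message else "") + "fitted k_c <= 0"
    return fit
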