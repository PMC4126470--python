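"""Thin-plate elasticity: Young's modulus from (k_c, nu, d).

For a thin isotropic plate the bending rigidity, Young's modulus,
Poisson's ratio and thickness are related by

    k_c = E d^3 / [12 (1 - nu^2)]   <=>   E = 12 k_c (1 - nu^2) / d^3.

The relation only applies to in-plane-isotropic membranes; the phase
report checks isotropy (nu_xy vs nu_yx within combined error bars)
and withholds E otherwise.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .builder import MembraneDescriptors
from .poisson import PoissonResult
from .spectrum import SpectrumFit

__all__ = ["ElasticModuli", "young_modulus", "phase_report"]


def young_modulus(k_c: float, nu: float, d: float) -> float:
    """E = 12 k_c (1 - nu^2) / d^3 (epsilon/sigma_LJ^3).

    k_c in epsilon, d in sigma_LJ, nu dimensionless with |nu| < 1.
    """
    if d <= 0:
        raise ValueError("thickness d must be positive")
    if abs(nu) >= 1:
        raise ValueError("|nu| must be below 1")
    return 12.0 * k_c * (1.0 - nu * nu) / d ** 3


@dataclass
class ElasticModuli:
    """Per-phase elastic-constant report.

    ``E`` is populated only for in-plane-isotropic membranes (within
    the anisotropy test); ``nu`` is then the mean of nu_xy and nu_yx.
    """

    k_c: float
    nu: float | None
    d: float
    E: float | None
    isotropic: bool
    nu_components: dict | None = None

    def __post_init__(self):
        if self.nu is not None and not -1.0 < self.nu < 0.5 + 0.1:
            raise ValueError("Poisson's ratio outside the physical range")

    def summary(self) -> str:
        lines = [f"k_c = {self.k_c:.4g} epsilon, d = {self.d:.4g} sigma"]
        if self.nu_components:
            for k, (v, e) in self.nu_components.items():
                lines.append(f"nu_{k} = {v:.3f} +- {e:.3f}")
        if self.isotropic and self.E is not None:
            lines.append(f"isotropic; nu = {self.nu:.3f}; "
                         f"E = {self.E:.3g} epsilon/sigma^3")
        else:
            lines.append("anisotropic in plane: E withheld "
                         "(thin-plate relation requires isotropy)")
        return "\n".join(lines)


def _gather_nus(poisson) -> dict:
    if isinstance(poisson, PoissonResult):
        poisson = [poisson]
    if isinstance(poisson, dict):   # synthetic {'xy': (value, stderr), ...}
        return dict(poisson)
    out = {}
    for res in poisson:
        if isinstance(res, PoissonResult):
            out.update(res.nu)
        else:
            out.update(dict(res))
    return out


def phase_report(spectrum: SpectrumFit, poisson, descriptors: MembraneDescriptors,
                 *, isotropy_sigma: float = 2.0, d: float | None = None) -> ElasticModuli:
    """Assemble elastic constants for one phase.

    ``poisson`` is a PoissonResult (or a pair of them, one per strain
    axis, or a plain {'xy': (value, stderr), ...} mapping).  Isotropy
    holds when |nu_xy - nu_yx| <= isotropy_sigma * combined stderr;
    E is computed only then, with nu the mean of the two.  ``d``
    defaults to the descriptors' mean thickness.
    """
    missing = [name for name, v in (("spectrum", spectrum), ("poisson", poisson),
                                    ("descriptors", descriptors)) if v is None]
    if missing:
        raise ValueError(f"missing inputs: {', '.join(missing)}")
    nus = _gather_nus(poisson)
    if d is None:
        d = descriptors.thickness
    have_pair = "xy" in nus and "yx" in nus
    if have_pair:
        (vxy, exy), (vyx, eyx) = nus["xy"], nus["yx"]
        comb = float(np.hypot(exy, eyx))
        isotropic = abs(vxy - vyx) <= isotropy_sigma * max(comb, 1e-12)
        nu_mean = 0.5 * (vxy + vyx)
    elif "xy" in nus or "yx" in nus:
        raise ValueError("both nu_xy and nu_yx are required to test isotropy")
    else:
        raise ValueError("no in-plane Poisson's ratios supplied")
    E = young_modulus(spectrum.k_c, nu_mean, d) if isotropic else None
    return ElasticModuli(k_c=spectrum.k_c, nu=nu_mean if isotropic else None,
                         d=d, E=E, isotropic=isotropic, nu_components=nus)
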