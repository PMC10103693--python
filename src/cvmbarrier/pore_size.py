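"""Effective mucus pore size from hindered nanoparticle diffusion.

Densely PEG-coated mucus-penetrating particles (MPPs) interact with the
mucin mesh only sterically, so the ratio of their effective diffusivity
in mucus to their free diffusivity in water reports the mesh (pore)
size.  The forward obstruction-scaling model used here is

    D_eff / D0 = exp[ -(pi/4) * ((d + d_f) / (xi + d_f))^2 ]

with probe diameter d, mesh fiber diameter d_f, and pore size xi, which
inverts in closed form.  D0 comes from Stokes-Einstein; D_eff from the
ensemble-average MSD at tau = 1 s (2-D tracking: D = MSD / 4 tau).
The model is pluggable: any callable mapping (xi, d, d_f) -> hindrance
may replace the default form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PoreModelConditions", "PoreSizeEstimate",
           "stokes_einstein_d0", "effective_diffusivity",
           "obstruction_hindrance", "invert_obstruction_model",
           "sample_pore_size", "UNBOUNDED"]

KB = 1.380649e-23  # J/K

#: Sentinel for probes diffusing at (or above) their free-water rate.
UNBOUNDED = "unbounded"


@dataclass(frozen=True)
class PoreModelConditions:
    """Physical constants of the pore-size inversion.

    Room-temperature aqueous conditions by default; ``d_fiber`` is the
    effective mucin fiber diameter in nm.
    """

    temperature: float = 298.15   # K
    viscosity: float = 8.9e-4     # Pa s
    d_fiber: float = 7.0          # nm
    tau: float = 1.0              # s, MSD lag


@dataclass
class PoreSizeEstimate:
    sample_id: str
    per_probe_xi: dict            # diameter nm -> xi nm | "unbounded"
    xi_mean: float                # nm; NaN when all probes unbounded
    d_fiber: float
    temperature: float
    viscosity: float
    flags: list = field(default_factory=list)

    @property
    def defined(self) -> bool:
        return not math.isnan(self.xi_mean)


def stokes_einstein_d0(diameter_nm: float, temperature: float = 298.15,
                       viscosity: float = 8.9e-4) -> float:
    """Free diffusivity D0 = kB*T / (3 pi eta d), returned in um^2/s."""
    if diameter_nm <= 0 or temperature <= 0 or viscosity <= 0:
        raise ValueError("diameter, temperature and viscosity must be > 0")
    d_m = diameter_nm * 1e-9
    d0_m2s = KB * temperature / (3.0 * math.pi * viscosity * d_m)
    return d0_m2s * 1e12  # m^2/s -> um^2/s


def effective_diffusivity(msd_um2: float, tau: float) -> float:
    """D_eff = MSD / (4 tau) for 2-D tracking, in um^2/s."""
    if msd_um2 < 0:
        raise ValueError(f"msd must be >= 0, got {msd_um2}")
    if tau <= 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    return msd_um2 / (4.0 * tau)


def obstruction_hindrance(xi_nm: float, diameter_nm: float,
                          d_fiber_nm: float = 7.0) -> float:
    """Forward model: hindrance ratio D_eff/D0 for pore size xi."""
    ratio = (diameter_nm + d_fiber_nm) / (xi_nm + d_fiber_nm)
    return math.exp(-(math.pi / 4.0) * ratio ** 2)


def invert_obstruction_model(hindrance: float, diameter_nm: float,
                             d_fiber_nm: float = 7.0):
    """Invert the obstruction model to a pore size in nm.

    Returns ``"unbounded"`` when hindrance >= 1 (free diffusion implies
    no measurable confinement).  A mathematically negative pore size
    (extreme hindrance) is clamped to 0.
    """
    if not np.isfinite(hindrance) or hindrance <= 0:
        raise ValueError(f"hindrance must be finite and > 0, got {hindrance}")
    if hindrance >= 1.0:
        return UNBOUNDED
    xi = ((diameter_nm + d_fiber_nm)
          * math.sqrt(math.pi / (4.0 * math.log(1.0 / hindrance)))
          - d_fiber_nm)
    return max(xi, 0.0)


def sample_pore_size(msd_by_probe: dict, sample_id: str = "sample",
                     conditions: PoreModelConditions | None = None,
                     ) -> PoreSizeEstimate:
    """Average pore size of one sample from per-probe ensemble MSDs.

    ``msd_by_probe`` maps MPP diameter (nm) to the sample's ensemble
    average MSD (um^2) at ``conditions.tau``.  Per-probe pore sizes are
    computed through D_eff -> hindrance -> inversion; the sample
    estimate is the arithmetic mean of the defined (bounded) per-probe
    values.
    """
    if not msd_by_probe:
        raise ValueError("at least one MPP probe is required")
    cond = conditions or PoreModelConditions()
    per_probe: dict = {}
    flags: list[str] = []
    values: list[float] = []
    for diameter_nm, msd in msd_by_probe.items():
        d0 = stokes_einstein_d0(diameter_nm, cond.temperature, cond.viscosity)
        deff = effective_diffusivity(msd, cond.tau)
        if deff <= 0:
            per_probe[diameter_nm] = 0.0
            values.append(0.0)
            flags.append(f"zero_mobility_{int(diameter_nm)}nm")
            continue
        xi = invert_obstruction_model(deff / d0, diameter_nm, cond.d_fiber)
        per_probe[diameter_nm] = xi
        if xi == UNBOUNDED:
            flags.append(f"unbounded_{int(diameter_nm)}nm")
        else:
            if xi == 0.0:
                flags.append(f"clamped_{int(diameter_nm)}nm")
            values.append(xi)
    xi_mean = float(np.mean(values)) if values else float("nan")
    if not values:
        flags.append("undefined")
    return PoreSizeEstimate(
        sample_id=sample_id, per_probe_xi=per_probe, xi_mean=xi_mean,
        d_fiber=cond.d_fiber, temperature=cond.temperature,
        viscosity=cond.viscosity, flags=flags)


def pore_size_table(estimates: list[PoreSizeEstimate]) -> pd.DataFrame:
    """Estimates as the shared per-sample pore-size CSV schema."""
    rows = []
    for e in estimates:
        def cell(d):
            v = e.per_probe_xi.get(d)
            return np.nan if v in (None, UNBOUNDED) else v
        rows.append((e.sample_id, cell(100), cell(200), cell(500),
                     e.xi_mean, ";".join(e.flags)))
    return pd.DataFrame(rows, columns=[
        "sample_id", "xi_100", "xi_200", "xi_500", "xi_mean_nm", "flags"])
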