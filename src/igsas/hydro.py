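"""Sedimentation-coefficient standardization and hull-based prediction.

Observed sedimentation coefficients are standardized to water at 20 degC,

    s20,w = s_T,B (eta_T,B / eta_20,w) (1 - vbar rho)_20,w / (1 - vbar rho)_T,B,

and theoretical values for bead models come from a simplified convex-hull
method: the hull of the bead centres gives an equivalent-sphere radius,
augmented by a fixed hydration increment, and a Perrin-type shape factor
from the model's principal axes corrects the friction for asymmetry.  The
hull captures solvent entrained by extended shapes, which is what makes an
elongated antibody sediment slower than a compact one of equal mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull

from .constants import AVOGADRO, ETA_20W, RHO_20W, VBAR_IGG
from .models import BeadModel

#: hydration increment added to the equivalent-sphere radius (nm)
HYDRATION_INCREMENT_NM = 0.28


@dataclass
class SolventConditions:
    """Buffer conditions at the measurement temperature."""

    temperature: float = 20.0       # degC
    density: float = RHO_20W        # g/ml
    viscosity: float = ETA_20W      # poise
    vbar: float = VBAR_IGG          # ml/g

    def __post_init__(self):
        if min(self.density, self.viscosity, self.vbar) <= 0:
            raise ValueError("solvent parameters must be positive")


#: standard water at 20 degC
STANDARD_WATER = SolventConditions()


@dataclass
class HydroResult:
    s: float                 # Svedberg, in the given buffer
    s20w: float              # Svedberg, standardized
    stokes_radius: float     # nm
    frictional_ratio: float  # f/f0 vs the anhydrous equivalent sphere
    hull_volume: float       # nm^3
    shape_factor: float = 1.0


def s20w_standardize(s_obs: float, cond: SolventConditions) -> float:
    """Correct an observed s value to standard water at 20 degC."""
    buoy_tb = 1.0 - cond.vbar * cond.density
    if buoy_tb <= 0:
        raise ValueError("(1 - vbar rho) <= 0: particle would float")
    buoy_w = 1.0 - cond.vbar * RHO_20W
    return s_obs * (cond.viscosity / ETA_20W) * (buoy_w / buoy_tb)


def perrin_factor(axial_ratio: float) -> float:
    """Perrin translational friction factor for a spheroid of axial ratio p.

    p > 1 is prolate, p < 1 oblate; F >= 1 and F(1) = 1.  The reference is
    the sphere of equal volume.
    """
    p = float(axial_ratio)
    if abs(p - 1.0) < 1e-6:
        return 1.0
    if p > 1.0:
        xi = np.sqrt(p * p - 1.0)
        return xi / (p ** (1.0 / 3.0) * np.log(p + xi))
    xi = np.sqrt(1.0 - p * p)
    return xi / (p ** (1.0 / 3.0) * np.arctan2(xi, p))


def _axial_ratio(points: np.ndarray) -> float:
    """Prolate-equivalent axial ratio from the coordinate covariance."""
    ev = np.sort(np.linalg.eigvalsh(np.cov(points.T)))[::-1]
    ev = np.clip(ev, 1e-12, None)
    return float(np.sqrt(ev[0] / np.sqrt(ev[1] * ev[2])))


def hull_s_estimate(model: BeadModel, mass: float | None = None,
                    vbar: float = VBAR_IGG,
                    cond: SolventConditions = STANDARD_WATER,
                    hydration: float = HYDRATION_INCREMENT_NM) -> HydroResult:
    """Sedimentation coefficient of a bead model by the convex-hull method.

    s = M (1 - vbar rho) / (N_A 6 pi eta R_s F) with R_s the hydrated
    equivalent-sphere radius of the hull and F the Perrin shape factor.
    GLYCAN beads participate in the hull.  Raises on degenerate hulls
    (fewer than 4 non-coplanar sites).
    """
    pts = model.positions
    if len(pts) < 4:
        raise ValueError("need at least 4 sites for a hull")
    try:
        hull = ConvexHull(pts)
    except Exception as exc:  # qhull raises its own error type on flat input
        raise ValueError(f"degenerate hull: {exc}") from None
    if hull.volume <= 0:
        raise ValueError("degenerate (zero-volume) hull")
    if mass is None:
        mass = model.total_mass()

    r_eq = (3.0 * hull.volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    r_s = r_eq + hydration
    shape = perrin_factor(_axial_ratio(pts))

    buoy = 1.0 - vbar * cond.density
    if buoy <= 0:
        raise ValueError("(1 - vbar rho) <= 0: particle would float")
    # cgs: eta in poise, R_s in cm; s in seconds -> Svedberg (1e-13 s)
    f_trans = 6.0 * np.pi * cond.viscosity * (r_s * 1e-7) * shape
    s_seconds = mass * buoy / (AVOGADRO * f_trans)
    s_svedberg = s_seconds / 1e-13

    r_anh = (3.0 * mass * vbar / (4.0 * np.pi * AVOGADRO)) ** (1.0 / 3.0) * 1e7  # nm
    ffr = (r_s * shape) / r_anh
    s20w = s20w_standardize(s_svedberg, cond) if cond is not STANDARD_WATER \
        else s_svedberg
    return HydroResult(s_svedberg, s20w, float(r_s), float(ffr),
                       float(hull.volume), float(shape))
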