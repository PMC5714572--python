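"""Implant-level dosimetry: lifetime dose, apparent activity, isodose
contours and multi-seed superposition.

A permanently implanted seed with initial dose rate D0 and decay constant
lambda delivers D0 (1 - e^(-lambda T)) / lambda by time T; the infinite-time
dose is D0 times the mean lifetime T_half / ln 2. Self-absorption links the
activity contained in the glass to the apparent activity inferred from the
external dose field: contained / apparent = 1 / (1 - f_self).

Superposition treats seeds as transparent to each other's radiation
(no interseed attenuation) -- a documented limitation, acceptable at the
~1 cm spacings considered here because the dose a seed contributes at a
neighbour's far side is already down by orders of magnitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .engine import DoseGrid
from .nuclides import NuclideRecord
from .tg60 import TG60ParameterSet, dose_rate_tg60

LN2 = math.log(2.0)


def permanent_implant_dose(dose_rate_cGy_h: float, half_life_h: float,
                           duration_h: float = math.inf) -> float:
    """Cumulated dose in Gy from an exponentially decaying dose rate."""
    if dose_rate_cGy_h < 0 or half_life_h <= 0 or duration_h < 0:
        raise ValueError("inputs must be nonnegative (half-life positive)")
    lam = LN2 / half_life_h
    factor = 1.0 / lam if math.isinf(duration_h) else (
        1.0 - math.exp(-lam * duration_h)) / lam
    return dose_rate_cGy_h * factor / 100.0


def contained_to_apparent(f_self: float) -> float:
    """Contained-to-apparent activity ratio 1 / (1 - f_self)."""
    if not 0.0 <= f_self < 1.0:
        raise ValueError("self-absorption fraction must lie in [0, 1)")
    return 1.0 / (1.0 - f_self)


def isodose_contours(grid: DoseGrid, levels, resolution_mm: float = 0.05
                     ) -> dict[float, list[np.ndarray]]:
    """Isodose polylines in the (y, z) plane through the seed axis.

    The polar dose map is resampled onto a Cartesian half-plane, mirrored
    across the axis (cylindrical symmetry), and contoured; each returned
    polyline is an (n, 2) array of (y_mm, z_mm) vertices. Levels outside the
    grid's dynamic range come back as empty lists with a warning.
    """
    import warnings

    from scipy.interpolate import RegularGridInterpolator

    gs = grid.grid
    interp = RegularGridInterpolator(
        (gs.r_centers_mm, gs.theta_centers_deg),
        np.nan_to_num(grid.dose, nan=np.nan),
        bounds_error=False, fill_value=np.nan)
    extent = gs.r_max_mm
    y = np.arange(-extent, extent + resolution_mm, resolution_mm)
    z = y.copy()
    Y, Z = np.meshgrid(y, z)
    R = np.hypot(Y, Z)
    TH = np.degrees(np.arccos(np.clip(Z / np.maximum(R, 1e-12), -1, 1)))
    D = interp(np.column_stack([R.ravel(), TH.ravel()])).reshape(R.shape)

    finite = D[np.isfinite(D)]
    out: dict[float, list[np.ndarray]] = {}
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    try:
        for lev in levels:
            if lev <= np.nanmin(finite) or lev >= np.nanmax(finite):
                warnings.warn(f"isodose level {lev} outside grid dynamic range")
                out[lev] = []
                continue
            cs = ax.contour(Y, Z, D, levels=[lev])
            segs = [np.asarray(s) for s in cs.allsegs[0] if len(s) >= 3]
            out[lev] = segs
    finally:
        plt.close(fig)
    return out


@dataclass(frozen=True)
class PlannedSeed:
    position_mm: tuple[float, float, float]
    orientation: tuple[float, float, float] = (0.0, 0.0, 1.0)
    activity_mCi: float = 5.0

    def __post_init__(self):
        if self.activity_mCi < 0:
            raise ValueError("activity must be >= 0")
        n = math.sqrt(sum(c * c for c in self.orientation))
        if abs(n - 1.0) > 1e-6:
            raise ValueError("orientation must be a unit vector")


@dataclass(frozen=True)
class ImplantPlan:
    """A set of seeds sharing one parameter set and nuclide."""

    seeds: tuple[PlannedSeed, ...]
    params: TG60ParameterSet
    nuclide: NuclideRecord
    seed_length_mm: float = 4.5
    seed_radius_mm: float = 0.4


def _seed_frame_coords(seed: PlannedSeed, point_mm) -> tuple[float, float]:
    v = np.asarray(point_mm, dtype=float) - np.asarray(seed.position_mm)
    r = float(np.linalg.norm(v))
    if r == 0.0:
        return 0.0, 0.0
    ct = float(np.dot(v, seed.orientation) / r)
    return r, math.degrees(math.acos(max(-1.0, min(1.0, ct))))


def multi_seed_dose(plan: ImplantPlan, point_mm, duration_h: float = math.inf
                    ) -> float:
    """Cumulative dose in Gy at a point from every seed in the plan.

    Each seed's dose rate is evaluated in its own frame through the TG-60
    reconstruction (per uCi of contained activity, scaled by the seed's
    activity), then integrated through decay to ``duration_h``. Seeds whose
    distance to the point exceeds the tabulated radial range contribute
    zero: that range ends at the beta maximum range, beyond which the seed
    deposits no primary dose.
    """
    from .tg60 import ExtrapolationError

    total = 0.0
    for s in plan.seeds:
        r, th = _seed_frame_coords(s, point_mm)
        z = r * math.cos(math.radians(th))
        rho = r * math.sin(math.radians(th))
        if abs(z) < plan.seed_length_mm / 2 and rho < plan.seed_radius_mm:
            raise ValueError(f"point {point_mm} lies inside the seed at "
                             f"{s.position_mm}")
        try:
            rate = dose_rate_tg60(plan.params, r, th) * s.activity_mCi * 1e3
        except ExtrapolationError:
            continue
        total += permanent_implant_dose(rate, plan.nuclide.half_life_h, duration_h)
    return total
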