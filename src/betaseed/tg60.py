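"""TG-60/TG-149 dosimetric parameters and dose reconstruction.

The beta-seed dose formalism factorizes the dose rate around a cylindrical
source as

    D(r, theta) = D(r0, theta0) * [GL(r, theta) / GL(r0, theta0)]
                  * gL(r) * F(r, theta)

with the line-source geometry function GL(r, theta) = beta / (L r sin theta)
(beta the angle the source line subtends at the field point), the radial
dose function gL(r) normalized to 1 at the reference radius r0 = 2 mm, the
2D anisotropy function F(r, theta) normalized to 1 on the transverse plane
(theta0 = 90 deg), and the reference dose rate taken at (2 mm, 90 deg).

:class:`TG60Model` extracts the full parameter set from either a simulated
:class:`~betaseed.engine.DoseGrid` or a transverse-axis dose-rate table (the
packaged published tables, for instance) and returns a :class:`TG60Results`
that reconstructs dose, fits the customary fifth-order polynomial to gL and
prints a summary.

Polar convention: theta = 0 along the seed's long axis, 90 deg transverse,
symmetric about the transverse plane.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import DoseGrid, transverse_profile

R0_MM = 2.0
THETA0_DEG = 90.0


class ExtrapolationError(ValueError):
    """Requested point lies outside the tabulated parameter range."""


def geometry_function_line(r_mm, theta_deg, L_mm: float = 4.5):
    """Line-source geometry function GL(r, theta) in 1/mm^2.

    beta / (L r sin theta) off-axis; the 1 / (r^2 - L^2/4) limit on the
    axis. Points on the source segment itself (sin theta = 0, r <= L/2)
    raise a domain error.
    """
    r = np.asarray(r_mm, dtype=float)
    th = np.radians(np.asarray(theta_deg, dtype=float))
    r, th = np.broadcast_arrays(r, th)
    z = r * np.cos(th)
    y = r * np.sin(th)
    on_axis = np.abs(y) < 1e-12
    if np.any(on_axis & (r <= L_mm / 2)):
        raise ValueError("point on the source line with r <= L/2")
    beta = np.arctan2(y, z - L_mm / 2) - np.arctan2(y, z + L_mm / 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        gl = np.where(on_axis, 1.0 / (r**2 - L_mm**2 / 4.0),
                      np.abs(beta) / (L_mm * r * np.abs(y) / r))
    out = gl.reshape(r.shape)
    return float(out) if out.ndim == 0 else out


def radial_dose_function(transverse: pd.DataFrame, L_mm: float = 4.5,
                         r0_mm: float = R0_MM,
                         dose_col: str | None = None) -> pd.Series:
    """gL(r) from a transverse-axis dose table.

    gL(r) = [D(r) / D(r0)] * [GL(r0, 90) / GL(r, 90)]. The table needs a
    row at the reference radius.
    """
    if dose_col is None:
        dose_col = [c for c in transverse.columns if c != "r_mm"][0]
    r = transverse["r_mm"].to_numpy(dtype=float)
    d = transverse[dose_col].to_numpy(dtype=float)
    at_r0 = np.isclose(r, r0_mm)
    if not at_r0.any():
        raise ValueError(f"transverse table lacks the reference radius {r0_mm} mm")
    d0 = float(d[at_r0][0])
    gl0 = geometry_function_line(r0_mm, THETA0_DEG, L_mm)
    gl = geometry_function_line(r, np.full_like(r, THETA0_DEG), L_mm)
    return pd.Series(d / d0 * gl0 / gl, index=pd.Index(r, name="r_mm"), name="gL")


def anisotropy_2d(grid: DoseGrid, L_mm: float = 4.5, radii_mm=None,
                  angles_deg=None, theta_band_deg: float = 4.0) -> pd.DataFrame:
    """2D anisotropy function F(r, theta) from a scored dose grid.

    F(r, theta) = [D(r, theta) / D(r, 90)] * [GL(r, 90) / GL(r, theta)].
    Cell doses are volume-weighted over a +-1 shell, +-band/2 polar window,
    mirror-averaged about the transverse plane. Points whose window falls
    entirely inside the seed come back NaN (undefined, as in the published
    table), never zero.
    """
    if radii_mm is None:
        radii_mm = np.arange(1.0, 10.01, 0.5)
    if angles_deg is None:
        angles_deg = np.arange(0.0, 90.01, 10.0)
    gs = grid.grid
    vol = gs.cell_volumes_mm3()
    out = pd.DataFrame(index=pd.Index(angles_deg, name="theta_deg"),
                       columns=pd.Index(radii_mm, name="r_mm"), dtype=float)
    for r in radii_mm:
        ir = np.abs(gs.r_centers_mm - r) <= gs.shell_mm
        d_t = _window_dose(grid, vol, ir, THETA0_DEG, theta_band_deg)
        if not np.isfinite(d_t) or d_t <= 0:
            continue
        for th in angles_deg:
            d = _window_dose(grid, vol, ir, th, theta_band_deg)
            if not np.isfinite(d):
                continue
            th_eval = max(th, 1e-3)  # GL is taken at the nominal angle
            f = (d / d_t) * (
                geometry_function_line(r, THETA0_DEG, L_mm)
                / geometry_function_line(r, th_eval, L_mm)
            )
            out.loc[th, r] = f
    return out


def _window_dose(grid: DoseGrid, vol, ir_mask, theta_deg, band_deg):
    """Volume-weighted mean dose in a (r-window, theta-window), mirrored."""
    gs = grid.grid
    tc = gs.theta_centers_deg
    sel = (np.abs(tc - theta_deg) <= band_deg / 2 + 1e-9) | (
        np.abs(tc - (180.0 - theta_deg)) <= band_deg / 2 + 1e-9)
    cells = np.ix_(ir_mask, sel)
    d, v = grid.dose[cells], vol[cells]
    ok = np.isfinite(d)
    if not ok.any():
        return float("nan")
    return float(np.nansum(d * v * ok) / (v * ok).sum())


def anisotropy_1d(grid: DoseGrid, radii_mm=None) -> pd.Series:
    """1D anisotropy factor phi_an(r): solid-angle-weighted mean dose over
    4 pi divided by the transverse dose, by trapezoidal quadrature over the
    grid's polar bins.

    At radii where part of the polar range lies inside the seed (undefined
    dose), the mean is taken over the defined solid angle only.
    """
    if radii_mm is None:
        radii_mm = np.arange(1.0, 10.01, 0.5)
    gs = grid.grid
    vol = gs.cell_volumes_mm3()
    th = np.radians(gs.theta_centers_deg)
    dth = math.radians(gs.aperture_deg)
    out = {}
    for r in radii_mm:
        ir = np.abs(gs.r_centers_mm - r) <= gs.shell_mm
        if not ir.any():
            raise ValueError(f"radius {r} mm outside the grid")
        w = vol[ir].sum(axis=0)
        d = np.nansum(grid.dose[ir] * vol[ir], axis=0) / w
        defined = np.isfinite(d) & np.any(np.isfinite(grid.dose[ir]), axis=0)
        if not defined[np.abs(gs.theta_centers_deg - 90.0) < gs.aperture_deg].any():
            raise ValueError(f"no transverse coverage at r = {r} mm")
        num = np.sum(d[defined] * np.sin(th[defined]) * dth)
        den = np.sum(np.sin(th[defined]) * dth)
        d_t = _window_dose(grid, vol, ir, THETA0_DEG, 4.0)
        out[r] = (num / den) / d_t if np.isfinite(d_t) and d_t > 0 else np.nan
    return pd.Series(out, name="phi_an").rename_axis("r_mm")


def phi_an_from_F(F_row: pd.Series, r_mm: float, L_mm: float = 4.5,
                  n_theta: int = None) -> float:
    """phi_an(r) reconstructed from an F(r, theta) table row by quadrature.

    D(r, theta) ~ GL(r, theta) F(r, theta); trapezoid over the tabulated
    angles (mirrored about 90 deg), normalized by the transverse value.
    """
    row = F_row.dropna()
    th = row.index.to_numpy(dtype=float)
    f = row.to_numpy(dtype=float)
    th_eval = np.maximum(th, 1e-3)
    gl = np.array([geometry_function_line(r_mm, t, L_mm) for t in th_eval])
    d = f * gl
    s = np.sin(np.radians(th))
    num = np.trapezoid(d * s, np.radians(th))
    den = np.trapezoid(s, np.radians(th))
    d_t = d[np.isclose(th, 90.0)][0]
    return float((num / den) / d_t)


@dataclass(frozen=True)
class PolynomialFit:
    """Quintic fit gL(r) = a0 + a1 r + ... + a5 r^5 (r in mm)."""

    coefficients: tuple  # (a0 .. a5)
    correlation_R: float

    def __call__(self, r_mm):
        return np.polynomial.polynomial.polyval(np.asarray(r_mm, float),
                                                self.coefficients)


def fit_radial_polynomial(gL: pd.Series, order: int = 5) -> PolynomialFit:
    """Unweighted least-squares polynomial fit of a gL table.

    R is the Pearson correlation between fitted and tabulated values.
    """
    r = gL.index.to_numpy(dtype=float)
    y = gL.to_numpy(dtype=float)
    if len(r) < order + 2:
        raise ValueError(f"need at least {order + 2} points for order {order}")
    coef = np.polynomial.polynomial.polyfit(r, y, order)
    fitted = np.polynomial.polynomial.polyval(r, coef)
    R = float(np.corrcoef(fitted, y)[0, 1])
    return PolynomialFit(coefficients=tuple(coef), correlation_R=R)


@dataclass
class TG60ParameterSet:
    """Complete extracted parameter set for one seed."""

    reference_dose_rate: float        # cGy / h / uCi at (2 mm, 90 deg)
    gL_table: pd.Series               # index r_mm
    F_table: pd.DataFrame | None      # index theta_deg, columns r_mm
    phi_an_table: pd.Series | None    # index r_mm
    L_mm: float
    fit: PolynomialFit | None = None
    reference_dose_rate_unc: float = float("nan")

    def __post_init__(self):
        g = self.gL_table
        at_r0 = np.isclose(g.index.to_numpy(dtype=float), R0_MM)
        if not at_r0.any() or abs(g.to_numpy()[at_r0][0] - 1.0) > 1e-9:
            raise ValueError("gL table must equal 1 at the reference radius")

    def to_json(self, path) -> None:
        payload = {
            "reference_dose_rate": self.reference_dose_rate,
            "reference_dose_rate_unc": self.reference_dose_rate_unc,
            "L_mm": self.L_mm,
            "gL": {"r_mm": list(map(float, self.gL_table.index)),
                   "gL": list(map(float, self.gL_table))},
            "F": None if self.F_table is None else {
                "theta_deg": list(map(float, self.F_table.index)),
                "r_mm": list(map(float, self.F_table.columns)),
                "values": self.F_table.where(pd.notna(self.F_table), None)
                              .values.tolist()},
            "phi_an": None if self.phi_an_table is None else {
                "r_mm": list(map(float, self.phi_an_table.index)),
                "phi_an": list(map(float, self.phi_an_table))},
            "fit": None if self.fit is None else {
                "coefficients": list(self.fit.coefficients),
                "correlation_R": self.fit.correlation_R},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TG60ParameterSet":
        with open(path) as fh:
            p = json.load(fh)
        F = None
        if p["F"] is not None:
            F = pd.DataFrame(p["F"]["values"],
                             index=pd.Index(p["F"]["theta_deg"], name="theta_deg"),
                             columns=pd.Index(p["F"]["r_mm"], name="r_mm"),
                             dtype=float)
        phi = None
        if p["phi_an"] is not None:
            phi = pd.Series(p["phi_an"]["phi_an"],
                            index=pd.Index(p["phi_an"]["r_mm"], name="r_mm"))
        fit = None
        if p["fit"] is not None:
            fit = PolynomialFit(tuple(p["fit"]["coefficients"]),
                                p["fit"]["correlation_R"])
        return cls(reference_dose_rate=p["reference_dose_rate"],
                   reference_dose_rate_unc=p.get("reference_dose_rate_unc",
                                                 float("nan")),
                   gL_table=pd.Series(p["gL"]["gL"],
                                      index=pd.Index(p["gL"]["r_mm"],
                                                     name="r_mm"), name="gL"),
                   F_table=F, phi_an_table=phi, L_mm=p["L_mm"], fit=fit)


def dose_rate_tg60(params: TG60ParameterSet, r_mm: float,
                   theta_deg: float) -> float:
    """Reconstruct D(r, theta) in cGy/h/uCi from an extracted parameter set.

    gL is interpolated log-linearly in r (the falloff spans nearly four
    decades over the table); F bilinearly in (r, theta), folded about the
    transverse plane. Requests beyond the tabulated radial range raise
    :class:`ExtrapolationError`.
    """
    g = params.gL_table
    r_tab = g.index.to_numpy(dtype=float)
    if r_mm < r_tab.min() - 1e-9 or r_mm > r_tab.max() + 1e-9:
        raise ExtrapolationError(
            f"r = {r_mm} mm outside tabulated range "
            f"[{r_tab.min()}, {r_tab.max()}] mm")
    gl_val = float(np.exp(np.interp(r_mm, r_tab, np.log(g.to_numpy(dtype=float)))))
    th = 180.0 - theta_deg if theta_deg > 90.0 else theta_deg
    if params.F_table is not None:
        F_val = _bilinear_F(params.F_table, r_mm, th)
    else:
        F_val = 1.0 if abs(th - THETA0_DEG) < 1e-9 else float("nan")
    th_eval = max(th, 1e-3)
    gl_geom = geometry_function_line(r_mm, th_eval, params.L_mm)
    gl_geom0 = geometry_function_line(R0_MM, THETA0_DEG, params.L_mm)
    return params.reference_dose_rate * (gl_geom / gl_geom0) * gl_val * F_val


def _bilinear_F(F: pd.DataFrame, r_mm: float, theta_deg: float) -> float:
    th_tab = F.index.to_numpy(dtype=float)
    r_tab = F.columns.to_numpy(dtype=float)
    r_mm = min(max(r_mm, r_tab.min()), r_tab.max())
    theta_deg = min(max(theta_deg, th_tab.min()), th_tab.max())
    i = np.clip(np.searchsorted(th_tab, theta_deg) - 1, 0, len(th_tab) - 2)
    j = np.clip(np.searchsorted(r_tab, r_mm) - 1, 0, len(r_tab) - 2)
    t = (theta_deg - th_tab[i]) / (th_tab[i + 1] - th_tab[i])
    u = (r_mm - r_tab[j]) / (r_tab[j + 1] - r_tab[j])
    q = F.iloc[i : i + 2, j : j + 2].to_numpy(dtype=float)
    return float((1 - t) * (1 - u) * q[0, 0] + (1 - t) * u * q[0, 1]
                 + t * (1 - u) * q[1, 0] + t * u * q[1, 1])


def reference_dose_rate_from_table(transverse: pd.DataFrame,
                                   dose_col: str | None = None) -> float:
    """Dose rate at the reference radius from a transverse-axis table."""
    if dose_col is None:
        dose_col = [c for c in transverse.columns if c != "r_mm"][0]
    at = transverse[np.isclose(transverse["r_mm"], R0_MM)]
    if at.empty:
        raise ValueError("table lacks the 2 mm reference radius")
    return float(at[dose_col].iloc[0])


class TG60Model:
    """Extracts the TG-60 parameter set from a dose map.

    Built either from a scored :class:`DoseGrid` (full 2D extraction) or
    from a transverse-axis dose-rate table (gL, reference rate and quintic
    fit only).
    """

    def __init__(self, grid: DoseGrid | None = None,
                 transverse: pd.DataFrame | None = None,
                 L_mm: float = 4.5, dose_col: str | None = None):
        if (grid is None) == (transverse is None):
            raise ValueError("provide exactly one of grid / transverse")
        self.dose_grid = grid
        self.transverse = transverse
        self.L_mm = L_mm
        self.dose_col = dose_col

    @classmethod
    def from_grid(cls, grid: DoseGrid, L_mm: float = 4.5) -> "TG60Model":
        return cls(grid=grid, L_mm=L_mm)

    @classmethod
    def from_transverse_table(cls, table: pd.DataFrame, L_mm: float = 4.5,
                              dose_col: str | None = None) -> "TG60Model":
        return cls(transverse=table, L_mm=L_mm, dose_col=dose_col)

    def fit(self, radii_mm=None, angles_deg=None,
            poly_order: int = 5) -> "TG60Results":
        if radii_mm is None:
            # beyond ~9 mm the kernel engine is outside its validity domain
            # (no bremsstrahlung tail), so grid extraction stops there
            radii_mm = (np.arange(1.0, 9.01, 0.5) if self.dose_grid is not None
                        else np.arange(1.0, 10.01, 0.5))
        if self.dose_grid is not None:
            prof = transverse_profile(self.dose_grid, radii_mm)
            prof = prof.rename(columns={"dose_cGy_per_uCi_h": "dose"})
            ref = prof.loc[np.isclose(prof["r_mm"], R0_MM), "dose"].iloc[0]
            ref_unc = ref * prof.loc[np.isclose(prof["r_mm"], R0_MM),
                                     "rel_unc"].iloc[0]
            gL = radial_dose_function(prof[["r_mm", "dose"]], self.L_mm)
            F = anisotropy_2d(self.dose_grid, self.L_mm, radii_mm, angles_deg)
            phi = anisotropy_1d(self.dose_grid, radii_mm)
        else:
            gL = radial_dose_function(self.transverse, self.L_mm,
                                      dose_col=self.dose_col)
            ref = reference_dose_rate_from_table(self.transverse, self.dose_col)
            ref_unc = float("nan")
            F, phi = None, None
        fit = fit_radial_polynomial(gL, poly_order)
        params = TG60ParameterSet(reference_dose_rate=float(ref),
                                  reference_dose_rate_unc=float(ref_unc),
                                  gL_table=gL.round(12), F_table=F,
                                  phi_an_table=phi, L_mm=self.L_mm, fit=fit)
        return TG60Results(model=self, params=params)


@dataclass
class TG60Results:
    """Extracted parameter set plus reconstruction and reporting helpers."""

    model: TG60Model
    params: TG60ParameterSet

    def dose_rate(self, r_mm: float, theta_deg: float = THETA0_DEG) -> float:
        return dose_rate_tg60(self.params, r_mm, theta_deg)

    def summary(self) -> str:
        p = self.params
        lines = [
            "TG-60/TG-149 parameter extraction",
            "=" * 52,
            f"effective length L       {p.L_mm:.2f} mm",
            f"reference dose rate      {p.reference_dose_rate:.4f} cGy/h/uCi "
            f"at ({R0_MM:.0f} mm, {THETA0_DEG:.0f} deg)",
        ]
        if np.isfinite(p.reference_dose_rate_unc):
            lines[-1] += f" +- {p.reference_dose_rate_unc:.4f}"
        if p.fit is not None:
            a = ", ".join(f"a{i}={c:.5g}" for i, c in
                          enumerate(p.fit.coefficients))
            lines += [f"quintic gL fit           {a}",
                      f"fit correlation R        {p.fit.correlation_R:.5f}"]
        lines += ["", "radial dose function gL(r):",
                  p.gL_table.round(3).to_string()]
        if p.phi_an_table is not None:
            lines += ["", "1D anisotropy factor phi_an(r):",
                      p.phi_an_table.round(3).to_string()]
        return "\n".join(lines)

    def plot_radial(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        g = self.params.gL_table
        ax.semilogy(g.index, g.values, "o", label="extracted gL(r)")
        if self.params.fit is not None:
            rr = np.linspace(g.index.min(), g.index.max(), 200)
            ax.semilogy(rr, np.maximum(self.params.fit(rr), 1e-6), "-",
                        label="quintic fit")
        ax.set_xlabel("r (mm)")
        ax.set_ylabel("gL(r)")
        ax.legend()
        return ax
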