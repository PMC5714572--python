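import numpy as np
import pandas as pd
import pytest

import betaseed as bs
from betaseed.reference import anisotropy_table
from betaseed.tg60 import (
    ExtrapolationError,
    fit_radial_polynomial,
    phi_an_from_F,
    radial_dose_function,
)
from tests_oracles import brute_force_geometry_function


class TestGeometryFunction:
    def test_reference_point_value(self):
        # beta = 2 arctan(L / 2 r) on the transverse axis
        assert bs.geometry_function_line(2.0, 90.0) == pytest.approx(
            2 * np.arctan(1.125) / (4.5 * 2.0), rel=1e-12
        )
        assert bs.geometry_function_line(2.0, 90.0) == pytest.approx(0.187590,
                                                                     abs=1e-6)

    def test_on_axis_closed_form(self):
        assert bs.geometry_function_line(5.0, 0.0) == pytest.approx(
            1.0 / (25.0 - 5.0625), rel=1e-12
        )

    def test_agrees_with_line_integral_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            r = rng.uniform(2.4, 10.0)
            th = rng.uniform(5.0, 175.0)
            got = bs.geometry_function_line(r, th)
            want = brute_force_geometry_function(r, th, 4.5)
            assert got == pytest.approx(want, rel=1e-6)

    def test_point_source_limit(self):
        r = 500.0
        assert bs.geometry_function_line(r, 63.0) * r**2 == pytest.approx(
            1.0, rel=1e-4
        )

    def test_point_on_source_rejected(self):
        with pytest.raises(ValueError):
            bs.geometry_function_line(1.0, 0.0)


class TestRadialDoseFunction:
    def test_published_table_consistency(self, table4, table6):
        """gL recomputed from the published MCNP5 transverse dose rates
        matches the published gL column to one unit in the last printed
        digit at every radius except 1.5 mm, where the two printed tables
        are mutually inconsistent (all three code columns disagree with
        their printed gL there in the same direction)."""
        gl = radial_dose_function(table4[["r_mm", "mcnp5"]])
        ref = pd.Series(table6["mcnp5"].values, index=table6["r_mm"].values)
        dev = (gl - ref).abs().drop(1.5)
        assert dev.max() <= 0.001
        assert (gl - ref).abs().loc[1.5] == pytest.approx(0.0037, abs=0.0005)

    def test_normalized_at_reference_radius(self, table4):
        gl = radial_dose_function(table4[["r_mm", "mcnp5"]])
        assert gl.loc[2.0] == 1.0

    @pytest.mark.parametrize("r,expected", [(1.0, 1.100), (5.0, 0.374)])
    def test_spot_values(self, table4, r, expected):
        gl = radial_dose_function(table4[["r_mm", "mcnp5"]])
        assert round(float(gl.loc[r]), 3) == expected

    def test_missing_reference_radius_rejected(self, table4):
        trimmed = table4[table4["r_mm"] != 2.0]
        with pytest.raises(ValueError, match="reference"):
            radial_dose_function(trimmed[["r_mm", "mcnp5"]])


class TestPolynomialFit:
    def test_exact_quintic_recovered(self):
        coef = (1.0, -0.3, 0.05, 0.01, -2e-3, 1e-4)
        r = np.arange(1.0, 10.01, 0.5)
        y = np.polynomial.polynomial.polyval(r, coef)
        fit = fit_radial_polynomial(pd.Series(y, index=r))
        np.testing.assert_allclose(fit.coefficients, coef, atol=1e-8)
        assert fit.correlation_R == pytest.approx(1.0, abs=1e-12)

    def test_published_gl_fits_tightly(self, table6):
        gl = pd.Series(table6["mcnp5"].values, index=table6["r_mm"].values)
        fit = fit_radial_polynomial(gl)
        assert fit.correlation_R >= 0.999

    def test_published_coefficients_near_unity_at_reference(self):
        eq1 = bs.load_reference_table("eq1_coefficients").data
        coefs = tuple(eq1.set_index("coefficient")["value"][f"a{i}"]
                      for i in range(6))
        val = np.polynomial.polynomial.polyval(2.0, coefs)
        assert val == pytest.approx(1.002, abs=0.001)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_radial_polynomial(pd.Series([1.0, 0.9], index=[1.0, 2.0]))


class TestAnisotropyTables:
    def test_packaged_maximum(self):
        F, _ = anisotropy_table()
        assert F.max().max() == 6.785

    def test_transverse_row_is_unity(self):
        F, _ = anisotropy_table()
        assert (F.loc[90.0] == 1.0).all()

    def test_blank_cells_stay_missing(self):
        F, _ = anisotropy_table()
        assert F.loc[0.0].isna().sum() == 3
        assert F.loc[20.0].isna().sum() == 1
        assert F.notna().sum().sum() == 10 * 19 - 7

    def test_phi_an_reconstructed_by_quadrature(self):
        """Integrating GL x F over the tabulated angles reproduces the
        printed 1D anisotropy factor at the fully-covered radii."""
        F, phi = anisotropy_table()
        got = phi_an_from_F(F[3.0], 3.0)
        assert got == pytest.approx(phi[3.0], rel=0.05)

    def test_phi_an_between_dose_ratio_extremes(self):
        """phi_an is a solid-angle mean of D(r,theta)/D(r,90), so it must
        lie between the extremes of F x GL/GL(90) over theta (not of F
        alone: the geometry factor amplifies the near-axis dose)."""
        F, phi = anisotropy_table()
        for r in (3.0, 5.0, 10.0):
            row = F[r].dropna()
            gl90 = bs.geometry_function_line(r, 90.0)
            ratio = np.array([
                f * bs.geometry_function_line(r, max(th, 1e-3)) / gl90
                for th, f in row.items()
            ])
            assert ratio.min() <= phi[r] <= ratio.max()


@pytest.fixture(scope="module")
def fitted(table4):
    return bs.TG60Model.from_transverse_table(table4, dose_col="mcnp5").fit()


@pytest.fixture(scope="module")
def fitted_grid(small_sim):
    return bs.TG60Model.from_grid(small_sim.dose_grid).fit()


class TestModelOnPublishedTable:
    def test_reference_dose_rate(self, fitted):
        assert fitted.params.reference_dose_rate == 5.0542

    def test_reconstruction_identity_at_reference(self, fitted):
        assert fitted.dose_rate(2.0, 90.0) == pytest.approx(5.0542, rel=1e-9)

    @pytest.mark.parametrize("r,expected", [(1.0, 15.18), (5.0, 0.3784)])
    def test_reconstruction_at_table_nodes(self, fitted, r, expected):
        assert fitted.dose_rate(r, 90.0) == pytest.approx(expected, rel=0.005)

    def test_extrapolation_refused(self, fitted):
        with pytest.raises(ExtrapolationError):
            fitted.dose_rate(10.5, 90.0)

    def test_serialization_roundtrip(self, fitted, tmp_path):
        p = tmp_path / "params.json"
        fitted.params.to_json(p)
        back = bs.TG60ParameterSet.from_json(p)
        assert back.reference_dose_rate == fitted.params.reference_dose_rate
        pd.testing.assert_series_equal(back.gL_table, fitted.params.gL_table,
                                       check_names=False)
        np.testing.assert_allclose(back.fit.coefficients,
                                   fitted.params.fit.coefficients)

    def test_summary_prints_fit(self, fitted):
        s = fitted.summary()
        assert "reference dose rate" in s and "correlation R" in s


class TestModelOnSimulatedGrid:
    def test_transverse_anisotropy_is_unity(self, fitted_grid):
        F = fitted_grid.params.F_table
        np.testing.assert_allclose(F.loc[90.0].dropna().values, 1.0, rtol=1e-9)

    def test_cells_inside_seed_stay_undefined(self, fitted_grid):
        F = fitted_grid.params.F_table
        assert np.isnan(F.loc[0.0, 1.0])  # on-axis 1 mm is inside the glass
        assert np.isfinite(F.loc[0.0, 3.0])

    def test_isotropic_grid_has_unit_phi_an(self, small_sim):
        """phi_an == 1 identically for a synthetic angle-independent grid."""
        import copy

        iso = copy.deepcopy(small_sim.dose_grid)
        r = iso.grid.r_centers_mm[:, None]
        iso.dose = np.broadcast_to(1.0 / r**2, iso.dose.shape).copy()
        iso.rel_unc = np.full_like(iso.dose, 0.001)
        iso.inside_seed = np.zeros_like(iso.dose, dtype=bool)
        phi = bs.anisotropy_1d(iso, radii_mm=[2.0, 5.0])
        np.testing.assert_allclose(phi.values, 1.0, rtol=1e-9)

    def test_gl_normalized(self, fitted_grid):
        assert fitted_grid.params.gL_table.loc[2.0] == pytest.approx(1.0, abs=1e-12)
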