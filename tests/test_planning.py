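import math

import numpy as np
import pytest

import betaseed as bs
from betaseed.engine import DoseGrid, GridSpec
from betaseed.planning import (
    ImplantPlan,
    PlannedSeed,
    contained_to_apparent,
    isodose_contours,
    multi_seed_dose,
    permanent_implant_dose,
)

LN2 = math.log(2)


class TestPermanentImplantDose:
    def test_lifetime_dose_at_1cm(self):
        """5 mCi decaying to extinction with the published 0.0003
        cGy/h/uCi transverse dose rate at 10 mm delivers ~1.38 Gy."""
        rate = 0.0003 * 5000.0  # 5 mCi = 5000 uCi
        assert permanent_implant_dose(rate, 64.0) == pytest.approx(1.38, abs=0.01)

    def test_unit_rate_full_decay(self):
        assert permanent_implant_dose(1.0, 64.0) == pytest.approx(0.9233,
                                                                  abs=0.0001)

    def test_linear_in_rate_and_monotone_in_time(self):
        assert permanent_implant_dose(3.0, 64.0, 10.0) == pytest.approx(
            3 * permanent_implant_dose(1.0, 64.0, 10.0)
        )
        d = [permanent_implant_dose(1.0, 64.0, t) for t in (10, 50, 200, np.inf)]
        assert np.all(np.diff(d) > 0)

    def test_one_half_life_delivers_half(self):
        assert permanent_implant_dose(1.0, 64.0, 64.0) == pytest.approx(
            0.5 * permanent_implant_dose(1.0, 64.0)
        )

    def test_90pct_at_time_to_dose_fraction(self):
        """Cross-module consistency: the 8.86-day mark delivers 90% of the
        infinite-time dose."""
        t90 = bs.time_to_dose_fraction(LN2 / 64.0, 0.9)
        frac = permanent_implant_dose(1.0, 64.0, t90) / permanent_implant_dose(
            1.0, 64.0
        )
        assert frac == pytest.approx(0.9, rel=1e-9)


class TestContainedToApparent:
    def test_published_self_absorption_gives_1p4(self):
        assert contained_to_apparent(0.3051) == pytest.approx(1.4, abs=0.05)

    @pytest.mark.parametrize("f,expected", [(0.0, 1.0), (0.5, 2.0)])
    def test_limits(self, f, expected):
        assert contained_to_apparent(f) == expected

    @pytest.mark.parametrize("f", [1.0, 1.5, -0.1])
    def test_domain(self, f):
        with pytest.raises(ValueError):
            contained_to_apparent(f)


def _synthetic_radial_grid(dose_of_r):
    gs = GridSpec()
    r = gs.r_centers_mm[:, None]
    dose = np.broadcast_to(dose_of_r(r), (gs.n_r, gs.n_theta)).copy()
    return DoseGrid(grid=gs, dose=dose, rel_unc=np.full_like(dose, 1e-3),
                    inside_seed=np.zeros_like(dose, dtype=bool),
                    n_histories=0, rng_seed=0)


class TestIsodoseContours:
    def test_nested_ordering(self, small_sim):
        cont = isodose_contours(small_sim.dose_grid, [5.0, 1.0],
                                resolution_mm=0.1)
        hi = np.vstack(cont[5.0])
        lo = np.vstack(cont[1.0])
        assert np.hypot(*hi.T).max() < np.hypot(*lo.T).min() + 0.5
        assert np.hypot(*hi.T).mean() < np.hypot(*lo.T).mean()

    def test_contour_crosses_transverse_axis_consistently(self, small_sim):
        """The contour drawn at the transverse dose of r = 3 mm crosses the
        transverse axis at 3.0 +- 0.1 mm."""
        level = float(
            small_sim.transverse_profile([3.0])["dose_cGy_per_uCi_h"].iloc[0]
        )
        cont = isodose_contours(small_sim.dose_grid, [level], resolution_mm=0.05)
        pts = np.vstack(cont[level])
        near_axis = pts[np.abs(pts[:, 1]) < 0.05]
        assert np.abs(near_axis[:, 0]).min() == pytest.approx(3.0, abs=0.1)

    def test_spherical_grid_gives_circles(self):
        grid = _synthetic_radial_grid(lambda r: np.exp(-r))
        cont = isodose_contours(grid, [float(np.exp(-4.0))], resolution_mm=0.1)
        pts = np.vstack(cont[float(np.exp(-4.0))])
        rad = np.hypot(pts[:, 0], pts[:, 1])
        # eccentricity proxy: radial spread relative to mean radius
        assert rad.std() / rad.mean() < 0.02
        assert rad.mean() == pytest.approx(4.0, abs=0.1)

    def test_out_of_range_level_warns_and_returns_empty(self, small_sim):
        with pytest.warns(UserWarning, match="dynamic range"):
            cont = isodose_contours(small_sim.dose_grid, [1e9])
        assert cont[1e9] == []


@pytest.fixture(scope="module")
def params(table4):
    from betaseed.reference import anisotropy_table

    res = bs.TG60Model.from_transverse_table(table4, dose_col="mcnp5").fit()
    p = res.params
    p.F_table, p.phi_an_table = anisotropy_table()
    return p


@pytest.fixture(scope="module")
def nuclide():
    return bs.get_nuclide("90Y")


class TestMultiSeedDose:
    def test_single_seed_reduces_to_permanent_dose(self, params, nuclide):
        plan = ImplantPlan(seeds=(PlannedSeed((0, 0, 0), activity_mCi=5.0),),
                           params=params, nuclide=nuclide)
        got = multi_seed_dose(plan, (0, 6.0, 0))
        want = permanent_implant_dose(
            bs.dose_rate_tg60(params, 6.0, 90.0) * 5000.0, 64.0
        )
        assert got == pytest.approx(want, rel=1e-12)

    def test_two_seeds_midpoint_doubles(self, params, nuclide):
        plan = ImplantPlan(
            seeds=(PlannedSeed((0, 0, 0)), PlannedSeed((0, 10.0, 0))),
            params=params, nuclide=nuclide)
        single = ImplantPlan(seeds=(PlannedSeed((0, 0, 0)),), params=params,
                             nuclide=nuclide)
        assert multi_seed_dose(plan, (0, 5.0, 0)) == pytest.approx(
            2.0 * multi_seed_dose(single, (0, 5.0, 0)), rel=1e-12
        )

    def test_three_collinear_seeds_match_brute_force(self, params, nuclide):
        """Three seeds 1 cm apart along y (the phantom layout): superposed
        dose at a probe equals an independent seed-by-seed summation, with
        seeds beyond the beta range contributing nothing."""
        positions = [(0, -10.0, 0), (0, 0, 0), (0, 10.0, 0)]
        plan = ImplantPlan(
            seeds=tuple(PlannedSeed(p, activity_mCi=5.0) for p in positions),
            params=params, nuclide=nuclide)
        probe = np.array([0.0, 4.0, 2.0])
        r_max = float(params.gL_table.index.max())
        brute = 0.0
        for p in positions:
            v = probe - np.array(p)
            r = np.linalg.norm(v)
            if r > r_max:  # beyond the tabulated (and beta) range
                continue
            th = math.degrees(math.acos(v[2] / r))
            brute += permanent_implant_dose(
                bs.dose_rate_tg60(params, r, th) * 5000.0, 64.0)
        assert brute > 0
        assert multi_seed_dose(plan, probe) == pytest.approx(brute, rel=1e-12)

    def test_point_inside_seed_rejected(self, params, nuclide):
        plan = ImplantPlan(seeds=(PlannedSeed((0, 0, 0)),), params=params,
                           nuclide=nuclide)
        with pytest.raises(ValueError, match="inside"):
            multi_seed_dose(plan, (0.1, 0.0, 0.5))

    def test_orientation_must_be_unit(self):
        with pytest.raises(ValueError):
            PlannedSeed((0, 0, 0), orientation=(0, 0, 2.0))
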