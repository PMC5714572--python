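import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

import betaseed as bs
from betaseed.activation import ActivationScenario, activation_activity

LN2 = math.log(2)


class TestActivationActivity:
    def test_sm152_nominal_scenario(self):
        """152Sm(n,gamma)153Sm: thermal-only activation of the seed's 0.02 mg
        of enriched samarium at the nominal flux reproduces ~0.95 mCi."""
        n = bs.atom_inventory(bs.yas_composition(), "152Sm")
        lam = LN2 / 46.7
        a = activation_activity(n, 206.0, 3e13, lam, 5.0)
        assert a == pytest.approx(0.95, abs=0.005)

    def test_saturation_limit(self):
        n, sigma, flux = 1e18, 100.0, 1e13
        lam = LN2 / 10.0
        sat = n * sigma * 1e-24 * flux / 3.7e7
        assert activation_activity(n, sigma, flux, lam, 1e6) == pytest.approx(sat)
        assert activation_activity(n, sigma, flux, lam, 0.0) == 0.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            activation_activity(-1.0, 1.0, 1.0, 1.0, 1.0)

    @given(
        scale=st.floats(min_value=1.1, max_value=10.0),
        t=st.floats(min_value=0.1, max_value=100.0),
    )
    def test_monotone_in_each_argument(self, scale, t):
        base = activation_activity(1e18, 10.0, 1e13, LN2 / 50.0, t)
        assert activation_activity(1e18 * scale, 10.0, 1e13, LN2 / 50.0, t) > base
        assert activation_activity(1e18, 10.0 * scale, 1e13, LN2 / 50.0, t) > base
        assert activation_activity(1e18, 10.0, 1e13 * scale, LN2 / 50.0, t) > base
        assert activation_activity(1e18, 10.0, 1e13, LN2 / 50.0, t * scale) > base

    def test_eob_ratio_is_flux_independent(self):
        """The EOB activity ratio of two products cancels the flux exactly."""
        def ratio(flux):
            a = activation_activity(1e18, 10.0, flux, LN2 / 50.0, 5.0)
            b = activation_activity(2e17, 200.0, flux, LN2 / 40.0, 5.0)
            return a / b

        assert ratio(1e12) == pytest.approx(ratio(5e14), rel=1e-12)


class TestDecay:
    def test_y90_cooling_to_5mci(self):
        assert bs.decay(5.750, LN2 / 64.1, 13.0) == pytest.approx(5.0, abs=0.05)

    def test_sm153_cooling_to_0p8mci(self):
        assert bs.decay(0.95, LN2 / 46.7, 13.0) == pytest.approx(0.8, abs=0.025)

    def test_half_life_halves_exactly(self):
        assert bs.decay(2.0, LN2 / 64.0, 64.0) == pytest.approx(1.0, rel=1e-12)

    def test_zero_cooling_is_identity(self):
        a = activation_activity(1e18, 10.0, 1e13, LN2 / 50.0, 5.0)
        assert bs.decay(a, LN2 / 50.0, 0.0) == a


class TestCumulatedDose:
    def test_90pct_dose_in_8p86_days(self):
        t = bs.time_to_dose_fraction(LN2 / 64.0, 0.9)
        assert t == pytest.approx(212.6, abs=0.05)
        assert t / 24.0 == pytest.approx(8.86, abs=0.005)

    def test_half_fraction_gives_half_life(self):
        assert bs.time_to_dose_fraction(LN2 / 64.0, 0.5) == pytest.approx(64.0)

    def test_99pct_fraction(self):
        assert bs.time_to_dose_fraction(LN2 / 64.0, 0.99) == pytest.approx(
            425.2, abs=0.1
        )

    @pytest.mark.parametrize("f", [0.0, 1.0, -0.5, 1.5])
    def test_fraction_domain(self, f):
        with pytest.raises(ValueError):
            bs.time_to_dose_fraction(LN2 / 64.0, f)

    def test_infinite_cumulated_decays(self):
        assert bs.cumulated_decays(1.0, LN2 / 64.0) == pytest.approx(
            64.0 / LN2, rel=1e-12
        )

    def test_one_half_life_accumulates_half(self):
        lam = LN2 / 64.0
        assert bs.cumulated_decays(1.0, lam, 64.0) == pytest.approx(
            0.5 * bs.cumulated_decays(1.0, lam)
        )
        assert bs.cumulated_decays(1.0, lam, 0.0) == 0.0


@pytest.fixture(scope="module")
def plan():
    return bs.irradiation_plan(ActivationScenario(seed=bs.yas_seed()))


class TestIrradiationPlan:
    def _get(self, plan, isotope, epoch):
        return next(r for r in plan if r.isotope == isotope and r.epoch == epoch)

    def test_sm153_eob_and_cooled(self, plan):
        assert self._get(plan, "153Sm", "end-of-bombardment").activity_mCi == (
            pytest.approx(0.95, abs=0.005)
        )
        assert self._get(plan, "153Sm", "post-cooling").activity_mCi == (
            pytest.approx(0.8, abs=0.025)
        )

    def test_short_lived_products_flagged_negligible(self, plan):
        """After 13 h of cooling (~5 half-lives of 31Si) the short-lived
        products carry a negligible share of the seed's activity."""
        assert self._get(plan, "31Si", "post-cooling").negligible
        assert self._get(plan, "28Al", "post-cooling").negligible
        assert not self._get(plan, "90Y", "post-cooling").negligible

    def test_zero_flux_gives_zero_activities(self):
        plan = bs.irradiation_plan(
            ActivationScenario(flux_cm2_s=0.0, seed=bs.yas_seed())
        )
        assert all(r.activity_mCi == 0.0 for r in plan)

    def test_missing_composition_rejected(self):
        with pytest.raises(ValueError):
            bs.irradiation_plan(ActivationScenario(seed=None))

    def test_cooling_composes_with_activation(self, plan):
        eob = self._get(plan, "90Y", "end-of-bombardment").activity_mCi
        cooled = self._get(plan, "90Y", "post-cooling").activity_mCi
        assert cooled == pytest.approx(eob * math.exp(-LN2 / 64.1 * 13.0))
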