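"""Neutron activation, cooling and cumulated-decay arithmetic.

Thermal-only (2200 m/s) activation of a thin target: the end-of-bombardment
activity of a product with decay constant lambda after irradiating N parent
atoms of capture cross section sigma in a flux phi for time t is

    A(t) = N sigma phi (1 - exp(-lambda t))

which saturates at N sigma phi. No epithermal/resonance term, no parent
burn-up, no flux depression or self-shielding. For the YAS seed in the
nominal scenario (phi = 3e13 cm^-2 s^-1, 5 h irradiation, 13 h cooling) the
model reproduces the published 153Sm activity; the published 90Y/31Si/28Al
values are each ~4.2x the thermal-only analytic result (an unexplained
scoring-convention difference in the original activation calculation) and
are deliberately not reproduced here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .nuclides import MaterialComposition, SeedSpec, atom_inventory, get_nuclide

BARN_CM2 = 1e-24
BQ_PER_MCI = 3.7e7
LN2 = math.log(2.0)


@dataclass(frozen=True)
class ActivationScenario:
    """Irradiation/cooling conditions for one seed."""

    flux_cm2_s: float = 3e13
    irradiation_time_h: float = 5.0
    cooling_time_h: float = 13.0
    seed: SeedSpec | None = None

    def __post_init__(self):
        if min(self.flux_cm2_s, self.irradiation_time_h, self.cooling_time_h) < 0:
            raise ValueError("scenario values must be nonnegative")


@dataclass(frozen=True)
class ActivityRecord:
    isotope: str
    activity_mCi: float
    epoch: str  # "end-of-bombardment" | "post-cooling"
    negligible: bool = False

    def __post_init__(self):
        if self.activity_mCi < 0:
            raise ValueError("activity must be >= 0")


def activation_activity(
    n_atoms: float, sigma_b: float, flux_cm2_s: float, lam_per_h: float, t_h: float
) -> float:
    """End-of-bombardment activity in mCi; saturates at N*sigma*phi."""
    if min(n_atoms, sigma_b, flux_cm2_s, lam_per_h, t_h) < 0:
        raise ValueError("all activation inputs must be nonnegative")
    saturation_bq = n_atoms * sigma_b * BARN_CM2 * flux_cm2_s
    return saturation_bq * (1.0 - math.exp(-lam_per_h * t_h)) / BQ_PER_MCI


def decay(activity_mCi: float, lam_per_h: float, t_h: float) -> float:
    """Activity after decaying for ``t_h`` hours."""
    if t_h < 0:
        raise ValueError("cooling time must be >= 0")
    return activity_mCi * math.exp(-lam_per_h * t_h)


def time_to_dose_fraction(lam_per_h: float, fraction: float) -> float:
    """Hours for a permanently implanted source to deliver ``fraction`` of
    its total cumulated dose: t = -ln(1 - f) / lambda."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    return -math.log(1.0 - fraction) / lam_per_h


def cumulated_decays(
    activity0_mCi: float, lam_per_h: float, duration_h: float = math.inf
) -> float:
    """Time-integrated activity (mCi*h) over ``duration_h``; inf gives A0/lambda."""
    if duration_h < 0:
        raise ValueError("duration must be >= 0")
    if math.isinf(duration_h):
        return activity0_mCi / lam_per_h
    return activity0_mCi * (1.0 - math.exp(-lam_per_h * duration_h)) / lam_per_h


#: a cooled product contributing less than this fraction of the seed's total
#: post-cooling activity is flagged negligible (the nominal 13 h cooling --
#: about five 31Si half-lives -- pushes 31Si and 28Al far below it)
NEGLIGIBLE_FRACTION = 0.01


def irradiation_plan(scenario: ActivationScenario) -> list[ActivityRecord]:
    """Per-isotope activities at end of bombardment and after cooling.

    Walks every activatable parent in the seed composition (89Y, 30Si, 27Al,
    152Sm by default), computes EOB activities from the thermal-only model
    and decays them through the cooling interval. Products whose cooled
    activity has fallen below 1% of the seed's total are flagged negligible.
    """
    if scenario.seed is None or scenario.seed.composition is None:
        raise ValueError("scenario needs a seed with a composition")
    comp: MaterialComposition = scenario.seed.composition
    per_isotope: list[tuple[str, float, float]] = []
    for element, info in comp.elements.items():
        product = info["product"]
        nuc = get_nuclide(product, source="table2")
        if nuc.parent_capture_xs_b is None:
            continue
        n = atom_inventory(comp, element)
        lam = nuc.decay_constant_per_h
        a_eob = activation_activity(
            n, nuc.parent_capture_xs_b, scenario.flux_cm2_s, lam,
            scenario.irradiation_time_h,
        )
        per_isotope.append((product, a_eob, decay(a_eob, lam,
                                                  scenario.cooling_time_h)))
    eob_total = sum(a for _, a, _ in per_isotope)
    cooled_total = sum(a for _, _, a in per_isotope)
    records: list[ActivityRecord] = []
    for product, a_eob, a_cool in per_isotope:
        negligible = cooled_total > 0 and a_cool < NEGLIGIBLE_FRACTION * cooled_total
        records.append(ActivityRecord(product, a_eob, "end-of-bombardment"))
        records.append(ActivityRecord(product, a_cool, "post-cooling", negligible))
    records.append(ActivityRecord("total", eob_total, "end-of-bombardment"))
    records.append(ActivityRecord("total", cooled_total, "post-cooling"))
    return records
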