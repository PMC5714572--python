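"""Nuclide registry, seed geometry and glass composition.

Physical constants and per-isotope data used throughout the package: decay
properties of the beta emitters, thermal-neutron capture cross sections of
the activatable parents, the cylindrical seed geometry, and the elemental
composition of the yttrium-aluminosilicate (YAS) glass.

Two half-life values for 90Y circulate in the source data (64.0 h in the
emitter-property table, 64.1 h in the activation table); both are kept, with
``source`` tags, so that decay arithmetic and activation arithmetic can each
use the value its reference table carries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .reference import load_reference_table

AVOGADRO = 6.02214076e23
LN2 = math.log(2.0)

_HOURS = {"h": 1.0, "d": 24.0, "y": 8766.0, "m": 1.0 / 60.0, "s": 1.0 / 3600.0}

#: charge and mass number of the *daughter* nucleus, needed by the Coulomb
#: correction of the beta spectrum.
DAUGHTER_ZA = {
    "90Y": (40, 90),     # -> 90Zr
    "153Sm": (63, 153),  # -> 153Eu
    "90Sr": (39, 90),
    "32P": (16, 32),
    "31Si": (15, 31),
    "28Al": (14, 28),
    "19O": (9, 19),
    "186Re": (76, 186),
    "188Re": (76, 188),
    "142Pr": (60, 142),
    "177Lu": (72, 177),
    "166Ho": (68, 166),
}

#: beta transitions with a unique first-forbidden shape (DeltaJ=2, parity flip)
_UNIQUE_FF = {"90Y", "90Sr"}


class UnknownNuclideError(KeyError):
    """Lookup of an isotope absent from the packaged registry."""


@dataclass(frozen=True)
class NuclideRecord:
    """Decay and activation properties of one isotope.

    Attributes
    ----------
    name : str
        Isotope label, e.g. ``"90Y"``.
    half_life_h : float
        Half-life in hours.
    emax_MeV, emean_MeV : float or None
        Beta endpoint and mean energy (main branch) in MeV.
    transition_type : str
        ``"allowed"`` or ``"first-forbidden-unique"``.
    parent_capture_xs_b : float or None
        Thermal (2200 m/s) neutron capture cross section of the activatable
        parent, barns.
    gamma_lines : tuple of (float, float)
        Photon lines as (energy keV, yield fraction).
    source : str
        Which packaged table the numbers came from.
    """

    name: str
    half_life_h: float
    emax_MeV: float | None = None
    emean_MeV: float | None = None
    transition_type: str = "allowed"
    parent_capture_xs_b: float | None = None
    gamma_lines: tuple[tuple[float, float], ...] = ()
    source: str = "table1"

    def __post_init__(self):
        if self.half_life_h <= 0:
            raise ValueError(f"{self.name}: half-life must be positive")
        if self.emax_MeV is not None and self.emean_MeV is not None:
            if not (self.emax_MeV > self.emean_MeV > 0):
                raise ValueError(f"{self.name}: need Emax > Emean > 0")
        if self.parent_capture_xs_b is not None and self.parent_capture_xs_b < 0:
            raise ValueError(f"{self.name}: cross section must be >= 0")

    @property
    def decay_constant_per_h(self) -> float:
        """lambda = ln2 / T_half, in 1/h."""
        return LN2 / self.half_life_h

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "half_life_h": self.half_life_h,
            "decay_constant_per_h": self.decay_constant_per_h,
            "emax_MeV": self.emax_MeV,
            "emean_MeV": self.emean_MeV,
            "transition_type": self.transition_type,
            "parent_capture_xs_b": self.parent_capture_xs_b,
            "gamma_lines": list(self.gamma_lines),
            "source": self.source,
        }


def _parse_gamma(text) -> tuple[tuple[float, float], ...]:
    if not isinstance(text, str) or text.strip() in ("", "Brems"):
        return ()
    lines = []
    for part in text.split(";"):
        part = part.strip()
        if "(" in part:
            e, y = part.split("(")
            lines.append((float(e), float(y.strip("%) ")) / 100.0))
    return tuple(lines)


def _build_registry() -> dict[str, NuclideRecord]:
    reg: dict[str, NuclideRecord] = {}
    t1 = load_reference_table("table1_nuclides").data
    for _, row in t1.iterrows():
        name = row["radionuclide"]
        xs = row["parent_xs_b"]
        reg[name] = NuclideRecord(
            name=name,
            half_life_h=float(row["half_life"]) * _HOURS[row["half_life_unit"]],
            emax_MeV=float(row["emax_MeV"]),
            emean_MeV=float(row["emean_MeV"]),
            transition_type=(
                "first-forbidden-unique" if name in _UNIQUE_FF else "allowed"
            ),
            parent_capture_xs_b=None if np.isnan(xs) else float(xs),
            gamma_lines=_parse_gamma(row["gamma_emissions"]),
            source="table1",
        )
    t2 = load_reference_table("table2_activation").data
    for _, row in t2.iterrows():
        name = row["radionuclide"]
        rec = NuclideRecord(
            name=name,
            half_life_h=float(row["half_life"]) * _HOURS[row["half_life_unit"]],
            emax_MeV=reg[name].emax_MeV if name in reg else None,
            emean_MeV=reg[name].emean_MeV if name in reg else None,
            transition_type=(
                "first-forbidden-unique" if name in _UNIQUE_FF else "allowed"
            ),
            parent_capture_xs_b=float(row["parent_xs_b"]),
            gamma_lines=reg[name].gamma_lines if name in reg else (),
            source="table2",
        )
        # Table 2 owns the activation entries; keep Table 1's record for the
        # isotopes it covers and file the activation variant under a suffix.
        if name in reg:
            reg[name + "/activation"] = rec
        else:
            reg[name] = rec
    return reg


_REGISTRY: dict[str, NuclideRecord] | None = None


def registry() -> dict[str, NuclideRecord]:
    global _REGISTRY
    if _REGISTRY is None:
        _REGISTRY = _build_registry()
    return _REGISTRY


def get_nuclide(name: str, source: str | None = None) -> NuclideRecord:
    """Look up an isotope in the packaged registry.

    Parameters
    ----------
    name : str
        Isotope label, e.g. ``"90Y"``.
    source : {"table1", "table2", None}
        Which provenance variant to return when an isotope appears in both
        packaged tables (90Y: 64.0 h vs 64.1 h). Default: the emitter-property
        (table1) variant when it exists.
    """
    reg = registry()
    key = name
    if source == "table2" and name + "/activation" in reg:
        key = name + "/activation"
    if key not in reg:
        known = sorted(k for k in reg if "/" not in k)
        raise UnknownNuclideError(
            f"unknown isotope {name!r}; packaged registry has: {', '.join(known)}"
        )
    rec = reg[key]
    if source == "table1" and rec.source != "table1":
        raise UnknownNuclideError(f"{name!r} has no table1 (emitter) entry")
    return rec


@dataclass(frozen=True)
class MaterialComposition:
    """Elemental make-up of the seed glass.

    ``elements`` maps element label -> dict with keys ``weight_pct``,
    ``mass_mg``, ``molar_mass_g_mol``, ``parent_abundance`` (isotopic
    abundance of the neutron-activatable parent, as a fraction) and
    ``product`` (the activation product label).
    """

    elements: dict[str, dict] = field(default_factory=dict)
    total_mass_mg: float = 0.0

    def __post_init__(self):
        wsum = sum(e["weight_pct"] for e in self.elements.values())
        if self.elements and abs(wsum - 100.0) > 0.01:
            raise ValueError(f"weight fractions sum to {wsum}, expected 100 +- 0.01")

    @property
    def element_mass_sum_mg(self) -> float:
        return sum(e["mass_mg"] for e in self.elements.values())


@dataclass(frozen=True)
class SeedSpec:
    """Cylindrical seed: length and diameter in mm, density in g/cm3."""

    length_mm: float = 4.5
    diameter_mm: float = 0.8
    density_g_cm3: float = 3.8
    composition: MaterialComposition | None = None

    def __post_init__(self):
        if self.length_mm <= 0 or self.diameter_mm <= 0 or self.density_g_cm3 <= 0:
            raise ValueError("seed dimensions and density must be positive")

    @property
    def radius_mm(self) -> float:
        return self.diameter_mm / 2.0

    @property
    def volume_mm3(self) -> float:
        return math.pi * self.radius_mm**2 * self.length_mm


def yas_composition(natural_abundance: bool = False) -> MaterialComposition:
    """The packaged YAS glass composition (43.2% Y, 8.618 mg total).

    With ``natural_abundance=True`` the samarium entry is treated as natural
    samarium (26.7% 152Sm) instead of the enriched, isotopically-pure default.
    """
    t3 = load_reference_table("table3_composition").data
    ed = load_reference_table("element_data").data.set_index("element")
    elements = {}
    total = 0.0
    for _, row in t3.iterrows():
        if row["element"] == "Total":
            total = float(row["mass_mg"])
            continue
        el = row["element"]
        info = ed.loc[el]
        abundance = float(info["parent_natural_abundance"])
        if el == "152Sm" and not natural_abundance:
            abundance = 1.0  # enriched 98.7% ~ 1 for the activation arithmetic
        elif el == "152Sm" and natural_abundance:
            abundance = 0.267
        elements[el] = {
            "weight_pct": float(row["weight_pct"]),
            "mass_mg": float(row["mass_mg"]),
            "molar_mass_g_mol": float(info["molar_mass_g_mol"]),
            "parent_abundance": abundance,
            "product": str(info["product"]),
        }
    return MaterialComposition(elements=elements, total_mass_mg=total)


def yas_seed(natural_abundance: bool = False) -> SeedSpec:
    """The 4.5 mm x 0.8 mm, 3.8 g/cm3 YAS glass seed."""
    return SeedSpec(composition=yas_composition(natural_abundance))


def atom_inventory(composition: MaterialComposition, element: str) -> float:
    """Number of activatable parent atoms of ``element`` in the seed.

    N = m / M * N_A * (parent isotopic abundance).
    """
    if element not in composition.elements:
        raise KeyError(f"element {element!r} not in composition")
    e = composition.elements[element]
    if e.get("molar_mass_g_mol") is None or e.get("parent_abundance") is None:
        raise ValueError(f"element {element!r} lacks molar mass or abundance")
    return (
        e["mass_mg"] * 1e-3 / e["molar_mass_g_mol"] * AVOGADRO * e["parent_abundance"]
    )
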