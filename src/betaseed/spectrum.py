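"""Beta emission spectra from Fermi theory.

The shape of an allowed beta spectrum is

    N(E) dE ~ p W (W0 - W)^2 F(Z, W) dE

with W the total electron energy and p its momentum (electron-mass units),
W0 the endpoint, and F the Fermi Coulomb correction for the daughter charge
Z. The 90Y -> 90Zr ground-state transition is unique first forbidden
(DeltaJ = 2, parity change), which multiplies the shape by the standard
(p^2 + q^2) factor, q = W0 - W being the neutrino momentum.

The Coulomb correction used here is the relativistic point-charge Fermi
function

    F(Z, W) = 2 (1 + gamma) (2 p R)^(2 gamma - 2) e^(pi eta)
              |Gamma(gamma + i eta)|^2 / Gamma(2 gamma + 1)^2

with gamma = sqrt(1 - (alpha Z)^2), eta = alpha Z W / p and R the nuclear
radius (1.2 fm A^(1/3)); screening is neglected. At Z ~ 40 the
nonrelativistic 2*pi*eta/(1-exp(-2*pi*eta)) approximation overweights the
low-energy end enough to push the 90Y mean ~4% above the tabulated
0.934 MeV, while the relativistic form lands within 2%, which is the
accuracy the downstream dosimetry needs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import loggamma

from .nuclides import DAUGHTER_ZA, NuclideRecord

ELECTRON_MASS_MEV = 0.51099895
ALPHA = 7.2973525693e-3
_COMPTON_FM = 386.1593  # reduced electron Compton wavelength, fm


@dataclass(frozen=True)
class BetaSpectrum:
    """Binned beta spectrum: probability density over kinetic energy.

    ``energy_MeV`` are bin centers of a uniform grid on [0, Emax];
    ``density_per_MeV`` integrates to 1 over the support.
    """

    nuclide: str
    energy_MeV: np.ndarray
    density_per_MeV: np.ndarray

    @property
    def emax_MeV(self) -> float:
        de = self.energy_MeV[1] - self.energy_MeV[0]
        return float(self.energy_MeV[-1] + de / 2)

    @property
    def mean_MeV(self) -> float:
        de = self.energy_MeV[1] - self.energy_MeV[0]
        return float(np.sum(self.energy_MeV * self.density_per_MeV) * de)

    def cdf(self) -> np.ndarray:
        """Cumulative probability at the upper edge of each bin."""
        de = self.energy_MeV[1] - self.energy_MeV[0]
        c = np.cumsum(self.density_per_MeV) * de
        return c / c[-1]

    def to_csv(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.energy_MeV, self.density_per_MeV]),
            delimiter=",",
            header="E_MeV,density_per_MeV",
            comments="",
        )

    @classmethod
    def from_csv(cls, path, nuclide: str = "custom") -> "BetaSpectrum":
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(nuclide=nuclide, energy_MeV=arr[:, 0], density_per_MeV=arr[:, 1])


def fermi_function(Z: int, A: int, E_MeV: np.ndarray) -> np.ndarray:
    """Relativistic point-charge Fermi function F(Z, W) for a beta-minus decay."""
    W = 1.0 + np.asarray(E_MeV, dtype=float) / ELECTRON_MASS_MEV
    p = np.sqrt(np.maximum(W**2 - 1.0, 1e-300))
    gamma = np.sqrt(1.0 - (ALPHA * Z) ** 2)
    R = 1.2 * A ** (1.0 / 3.0) / _COMPTON_FM
    eta = ALPHA * Z * W / p
    log_f = (
        np.log(2.0 * (1.0 + gamma))
        + (2.0 * gamma - 2.0) * np.log(2.0 * p * R)
        + np.pi * eta
        + 2.0 * np.real(loggamma(gamma + 1j * eta))
        - 2.0 * np.real(loggamma(2.0 * gamma + 1.0))
    )
    return np.exp(log_f)


def build_spectrum(nuclide: NuclideRecord, n_bins: int = 500) -> BetaSpectrum:
    """Construct the binned beta spectrum of a nuclide from Fermi theory.

    Uses the main (endpoint) branch only; for 153Sm the tabulated 0.228 MeV
    average folds in the weaker 0.705/0.635 MeV branches, so the single-branch
    mean here sits above it (see the methods note).
    """
    if nuclide.emax_MeV is None:
        raise ValueError(f"{nuclide.name}: no beta endpoint configured")
    if n_bins < 100:
        raise ValueError("n_bins must be >= 100")
    if nuclide.name not in DAUGHTER_ZA:
        raise ValueError(f"no daughter Z/A known for {nuclide.name}")
    Z, A = DAUGHTER_ZA[nuclide.name]
    emax = nuclide.emax_MeV
    de = emax / n_bins
    E = (np.arange(n_bins) + 0.5) * de
    W = 1.0 + E / ELECTRON_MASS_MEV
    W0 = 1.0 + emax / ELECTRON_MASS_MEV
    p = np.sqrt(W**2 - 1.0)
    q = W0 - W
    density = p * W * q**2 * fermi_function(Z, A, E)
    if nuclide.transition_type == "first-forbidden-unique":
        density = density * (p**2 + q**2)
    density /= np.sum(density) * de
    return BetaSpectrum(nuclide=nuclide.name, energy_MeV=E, density_per_MeV=density)


def sample_energies(
    spectrum: BetaSpectrum, n: int, rng: np.random.Generator | int
) -> np.ndarray:
    """Draw ``n`` i.i.d. kinetic energies (MeV) by inverse CDF over the bins.

    Sampling is continuous within bins (linear interpolation of the CDF), so
    the draws follow the piecewise-constant density exactly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    de = spectrum.energy_MeV[1] - spectrum.energy_MeV[0] if len(spectrum.energy_MeV) > 1 else (
        2 * spectrum.energy_MeV[0]
    )
    edges = np.concatenate([[0.0], spectrum.energy_MeV + de / 2])
    cdf_edges = np.concatenate([[0.0], spectrum.cdf()])
    return np.interp(rng.random(n), cdf_edges, edges)
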