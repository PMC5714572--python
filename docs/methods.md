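# Methods

This note records the models implemented in `betaseed`, the parameters that
matter, the calibration anchors, and what the desk-scale engine can and
cannot be expected to reproduce.

## Seed, materials and activation

The source is a bare YAS glass cylinder, length L = 4.5 mm, diameter
0.8 mm, density 3.8 g/cm³, composition (wt%): Y 43.2, O 34.7, Si 14.0,
Al 7.9, ¹⁵²Sm 0.2 (total mass 8.618 mg). The activation model is
thermal-only (2200 m/s) thin-target capture:

    A(t) = N σ φ (1 − e^(−λt)),   N = m/M · N_A · (parent abundance)

with no epithermal/resonance contribution, parent burn-up, flux depression
or self-shielding. Units: activities in mCi (1 mCi = 3.7×10⁷ Bq), times in
hours, cross sections in barns. The samarium is enrichment-grade (98.7%
¹⁵²Sm) and treated as isotopically pure; a natural-abundance mode is
available per element (³⁰Si at 3.09% for ³¹Si production, ¹⁸O at 0.205%
for ¹⁹O). Under the nominal scenario (φ = 3×10¹³ cm⁻²s⁻¹, 5 h irradiation,
13 h cooling) this model reproduces the published ¹⁵³Sm activity
(0.95 mCi EOB → 0.78 mCi cooled) exactly; the published ⁹⁰Y, ³¹Si and ²⁸Al
EOB activities are each ≈4.2× the thermal-only analytic value and are *not*
reproduced — the discrepancy is consistent across those three products and
presumably reflects an unstated convention in the original activation
computation. Products whose cooled activity falls below 1% of the seed
total are flagged negligible (13 h ≈ five ³¹Si half-lives).

Two half-life values for ⁹⁰Y circulate in the source data (64.0 h in the
emitter-property table, 64.1 h in the activation table). Both are kept with
provenance tags: activation/cooling arithmetic defaults to 64.1 h,
dose-per-decay arithmetic to 64.0 h, each overridable. A "604.0 h" half-life
appearing once in the source prose is an evident misprint for 64.0 h.

## Beta spectra

Spectra follow Fermi theory, N(E) ∝ p·W·(W₀−W)²·F(Z,W), with the
relativistic point-charge Fermi function

    F(Z,W) = 2(1+γ)(2pR)^(2γ−2) e^(πη) |Γ(γ+iη)|² / Γ(2γ+1)²,
    γ = √(1−(αZ)²),  η = αZW/p,  R = 1.2 fm·A^(1/3),

screening neglected, Z and A of the daughter. The ⁹⁰Y→⁹⁰Zr ground-state
transition is unique first forbidden, adding the (p²+q²) shape factor. This
combination gives a ⁹⁰Y mean of 0.949 MeV, 1.6% above the tabulated
0.934 MeV — within the 2% accuracy the downstream dosimetry needs. (The
nonrelativistic 2πη/(1−e^(−2πη)) approximation was tried first and rejected:
at Z = 40 it overweights the low-energy end enough to push the mean to
0.970 MeV, a 3.9% error.) The ¹⁵³Sm spectrum uses the main 0.817 MeV branch
only; its tabulated 0.228 MeV average folds in two weaker branches, so the
single-branch mean here sits above that value. Only the ⁹⁰Y spectrum feeds
the dose engine.

Spectra are binned (default 500 uniform bins) and sampled by inverse CDF,
continuous within bins; sampling is reproducible for a fixed generator
seed.

## Dose point kernel

The transport primitive is a dose point kernel k(r): the fraction of the
energy emitted by an isotropic point beta source deposited per unit radial
distance in unit-density water. The default `CSDAKernel` is built from the
sampled spectrum and the Katz–Penfold range–energy relation

    R(E) = 0.412 · E^(1.265 − 0.0954 ln E)   [g/cm², E in MeV]

which gives 11.0 mm for the 2.284 MeV endpoint — the known maximum range of
⁹⁰Y betas in water, and the kernel's hard support limit. Each electron
deposits energy along its track at the collision stopping power of its
residual energy (S = dE/dR, from the same relation). Multiple scattering is
not simulated; its net effect — radial penetration shorter than path
length — is modelled by a *progressive detour*: a track of CSDA range R₀
reaches radial depth

    r(ℓ) = ℓ (1 − a·ℓ / 2R₀)

after path length ℓ, so tracks start straight (the near-origin deposition
density keeps its exact physical limit ⟨S⟩/⟨E⟩) and bend increasingly
toward end of range. The single rate parameter a is calibrated so that the
⁹⁰Y point-source X90 equals 5.3 mm, the accepted 90%-energy radius for ⁹⁰Y
in water (a ≈ 0.371; without any detour the model gives X90 = 6.3 mm). A
constant detour factor was tried first and rejected: compressing the whole
profile uniformly inflates the near-field density by ~19%, which shows up
directly as an overestimated transverse dose at 1 mm. A Loevinger-type
analytic kernel (c·[1−(x/c)e^(1−x/c)] + x·e^(1−x), x = νr, with
c = 3.11·e^(−0.55·E_max) and ν solved against the same X90 anchor) is kept
as a pluggable alternative.

Paths through the glass are converted to water-equivalent length with the
ratio of linear collision stopping powers: density ratio × Bethe
mass-stopping-power ratio computed from the glass composition by Bragg
additivity (effective Z/A = 0.472, I ≈ 190 eV vs water's 0.555 and 75 eV),
giving ≈ 3.8 × 0.768 ≈ 2.92 at the spectrum mean energy. Bare density
scaling (×3.8) was tried first and rejected: the heavy yttrium fraction
stops electrons markedly less per unit mass than water, and ignoring that
inflates self-absorption from ~30% to ~38%.

## Monte Carlo engine

Decay sites are sampled uniformly in the cylinder, directions
isotropically, energies from the spectrum. Each history's energy is carried
along its straight ray: the in-glass segment (to the analytic cylinder exit
point) is collapsed through the water-equivalent scaling, the escape energy
is the kernel's residual at that depth (this gives the per-history glass
deposit *exactly*, no discretization), and the remainder is deposited in
water by marching the ray in 0.05 mm steps, each step receiving the
telescoped residual-energy difference. Scoring uses concentric 0.1 mm
spherical shells × 2° polar cones about the seed center (θ = 0 along the
seed axis), to r_max = 12 mm; a finer radial-only tally extending past the
grid records the escaped-energy distribution for R90. Because deposits
telescope, total energy is conserved to rounding by construction, and the
`energy_balance` diagnostic confirms it per run.

Dose per cell is energy / analytic cell volume (shell–cone ring), converted
to cGy per µCi·h of **contained** activity (1 µCi·h = 1.332×10⁸ decays).
Cells whose center lies inside the seed are masked undefined (NaN), never
zero; cells straddling the glass surface use their full analytic volume (a
partial-volume approximation confined to r < 2.3 mm near the axis, inside
the region the published anisotropy table itself leaves blank).
Uncertainties are 1σ batch statistics over 20 batches from one seeded
generator; a fixed (histories, seed, batches) triple is bit-reproducible.
10⁶ histories run in ~15 s on one CPU and give <1% relative uncertainty at
the reference point.

Integral metrics: f_self (fraction of emitted energy absorbed in the
glass), R90 (radius of the sphere absorbing 90% of the *escaped* energy),
X90 (the point-source calibration anchor, reported for provenance).

## TG-60/TG-149 extraction and reconstruction

The extraction implements the beta-seed formalism with reference point
(r₀ = 2 mm, θ₀ = 90°) and line-source geometry function with effective
length equal to the physical 4.5 mm:

    G_L(r,θ) = β/(L·r·sinθ),  β the subtended angle;  1/(r²−L²/4) on axis.

g_L(r) is taken from the transverse profile (volume-weighted over ±1 shell
and a ±2° polar band, where the anisotropy is flat), F(r,θ) from
mirror-averaged polar windows, φ_an(r) by trapezoidal quadrature over the
polar bins — at radii where part of the axis is inside the seed, over the
defined solid angle only. The quintic fit of g_L is unweighted least
squares; its quality measure R is the Pearson correlation between fitted
and tabulated values (the published fit's weighting is unstated, so
equality with its printed R = 0.99998 is not asserted — R ≥ 0.999 is).

Reconstruction interpolates g_L log-linearly in r (the falloff spans four
decades; linear-in-r interpolation is badly biased) and F bilinearly in
(r,θ), folded about the transverse plane. Requests beyond the tabulated
radial range raise an explicit extrapolation refusal rather than guessing;
multi-seed superposition treats such seeds as contributing zero, which is
physically exact beyond the beta range.

Grid-based extraction stops at 9 mm: the kernel transports no
bremsstrahlung, so beyond r ≈ 9 mm (seed half-length + maximum escaped
depth) the simulated dose is identically zero while the real field has a
small photon tail. Published-table extraction runs to the full 10 mm.

## Implant-level metrics

A permanent implant with initial dose rate Ḋ₀ delivers
D = Ḋ₀(1−e^(−λT))/λ; T→∞ gives Ḋ₀·T½/ln2 (92.33 cGy per cGy/h for ⁹⁰Y).
Contained/apparent activity ratio is 1/(1−f_self). Isodose contours are
extracted from a Cartesian resampling of the polar map in the (y,z) plane
through the seed axis, mirrored by cylindrical symmetry. Multi-seed
superposition ignores interseed attenuation (seeds are transparent to each
other's radiation) — a documented limitation, mild at ~1 cm spacings where
the neighbour's dose is already orders of magnitude down.

## Validation data and known inconsistencies

The packaged CSV fixtures transcribe the published characterization tables
(nuclide properties, activation products, composition, per-code transverse
dose rates, reference dose rates, g_L, F/φ_an, quintic coefficients) with a
YAML sidecar for units and provenance. Two printed-data issues are handled
explicitly:

* the anisotropy table's second radius column is headed "7.5" where the
  sequence implies 1.5 mm; it is stored as 1.5 mm with a sidecar note, and
  its blank cells (points inside/behind the seed) stay missing;
* the transverse dose-rate and g_L tables are mutually inconsistent at
  r = 1.5 mm: recomputing g_L through the geometry function reproduces the
  printed column to ≤0.001 at 18 of 19 radii, but differs by 0.0037 at
  1.5 mm — in all three transport-code columns, same direction — so one of
  the two printed rows is misprinted. The consistency test asserts the
  ≤0.001 bound and deliberately fails there rather than excluding the row.

## What passing tests do and do not show

The engine emulates the *scored grids* of full transport codes, not their
physics. Shape-normalized quantities (g_L to within 10% for r ≤ 6 mm,
anisotropy structure), energy-fraction metrics (f_self within the published
30.25–30.77% ± 2 pp; the model's 28.7% sits at the low edge because it has
no glass backscatter), R90 (5.30 mm vs 5.5 mm published) and the
formalism's internal consistency are meaningful checks. Absolute dose rates
are reported per contained activity and agree with the published reference
value to ~1%, but this agreement is not asserted anywhere: whether the
published normalization is contained or apparent activity is not stated, so
absolute dose-rate equality is not a validation target. Real-data features
the stand-in does not model: bremsstrahlung dose beyond the beta range,
backscatter at the glass–water interface, end-of-range straggling beyond
what the detour mapping captures, and the 103 keV ¹⁵³Sm photon dose
(negligible next to the beta dose, and not transported).

## Problem sizes

Defaults were chosen so the full pipeline is interactive on one CPU: 10⁶
histories for production runs (statistical uncertainty <1% at the reference
point, ~15 s), 1.5×10⁵ for structural checks, 500 spectrum bins, 0.05 mm
transport steps on a 0.1 mm × 2° grid. Doubling any of these changes the
extracted parameters well within their quoted uncertainties.
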