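# Units and provenance for the packaged reference tables.
table1_nuclides:
  provenance: "Properties of several beta-emitting radionuclides (published seed-characterization study, Table 1)"
  units: {half_life: "per half_life_unit column (h/d/y)", emax_MeV: MeV, emean_MeV: MeV,
          parent_abundance_pct: "%", parent_xs_b: barn}
table2_activation:
  provenance: "Radionuclides from neutron activation of YAS glass (Table 2)"
  units: {parent_xs_b: barn, half_life: "per half_life_unit column (h/m/s)"}
table3_composition:
  provenance: "Composition of the YAS glass seed (Table 3); total mass 8.618 mg as printed"
  units: {weight_pct: "wt %", mass_mg: mg}
table4_radial_dose_rate:
  provenance: "Monte Carlo-calculated radial dose rate on the transverse axis (Table 4)"
  units: {r_mm: mm, mcnp5: "cGy/h/uCi", egsnrc: "cGy/h/uCi", fluka: "cGy/h/uCi"}
table5_reference_dose_rate:
  provenance: "Absorbed dose rate at the reference point (2 mm, 90 deg) in water (Table 5)"
  units: {dose_rate: "cGy/h/uCi", uncertainty: "cGy/h/uCi (1 sigma)"}
table6_gL:
  provenance: "Radial dose function gL(r) (Table 6)"
  units: {r_mm: mm, mcnp5: dimensionless, egsnrc: dimensionless, fluka: dimensionless}
table7_F:
  provenance: >-
    2D anisotropy function F(r,theta) and 1D anisotropy factor phi_an(r) (Table 7).
    The printed header of the second radius column reads "7.5"; the radius sequence
    (1.0, ?, 2.0, 2.5, ...) implies 1.5 mm and it is stored as 1.5 mm here. Blank
    cells at small r and small theta (points inside/behind the physical seed) are
    kept as missing values, never imputed.
  units: {theta_deg: degree, columns: "radius in mm", values: dimensionless}
eq1_coefficients:
  provenance: "Fifth-order polynomial fit of the MCNP5 radial dose function (printed coefficients; r in mm); R is the printed correlation coefficient"
  units: {value: "dimensionless (powers of mm absorbed into coefficients)"}
element_data:
  provenance: "Molar masses: IUPAC standard atomic weights; isotopic abundances: IUPAC representative values. 152Sm enriched to 98.7 pct in the seed, treated as isotopically pure."
  units: {molar_mass_g_mol: g/mol, parent_natural_abundance: fraction}
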