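# Thermophysical properties of human blood and carbon nanotubes.
#
# Values are the ones commonly tabulated in the CNT-nanofluid literature
# (blood as base fluid; single- and multi-walled carbon nanotubes).  Units:
# rho [kg/m^3], cp [J/kg/K], k [W/m/K], beta [1/K], sigma [S/m].  Only the
# ratios derived from these enter the dimensionless model; the "neutral"
# preset (all ratios equal to 1) reproduces the pure base fluid.

SWCNT-blood:
  rho_f: 1053.0
  cp_f: 3594.0
  k_f: 0.492
  beta_f: 0.18e-3
  sigma_f: 0.8
  rho_c: 2600.0
  cp_c: 425.0
  k_c: 6600.0
  beta_c: 2.7e-5
  sigma_c: 1.0e+6

MWCNT-blood:
  rho_f: 1053.0
  cp_f: 3594.0
  k_f: 0.492
  beta_f: 0.18e-3
  sigma_f: 0.8
  rho_c: 1600.0
  cp_c: 796.0
  k_c: 3000.0
  beta_c: 4.4e-5
  sigma_c: 1.0e+6

neutral:
  rho_f: 1.0
  cp_f: 1.0
  k_f: 1.0
  beta_f: 1.0
  sigma_f: 1.0
  rho_c: 1.0
  cp_c: 1.0
  k_c: 1.0
  beta_c: 1.0
  sigma_c: 1.0
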