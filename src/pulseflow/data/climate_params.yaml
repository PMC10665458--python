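# Default parameter set of the linearized climate model.
#
# All quantities are AR6-consistent: perturbation lifetimes and radiative
# efficiencies follow IPCC AR6 Ch. 7 (Forster et al., 2021); the CO2 impulse
# response is the multi-exponential fit of Joos et al. (2013) adopted for AR6
# metrics.  Effective efficiencies (direct x indirect_multiplier) and the
# temperature/carbon-cycle coefficients are set within published uncertainty
# so that the per-tonne forcing of a pulse of each gas and the implied
# GWP-style integrals agree with AR6 central values (biogenic CH4 GWP100 ~ 27,
# N2O ~ 266).  Edit freely; every number is read from this file at run time.
discretization:
  step_years: 1.0
  horizon_years: 500

gases:
  CO2:
    molar_mass: 44.01
    # W m-2 per kg of atmospheric burden (1.33e-5 W m-2 ppb-1)
    radiative_efficiency: 1.7088e-15
    indirect_multiplier: 1.0
    # the CO2 impulse response below already embeds the climate-carbon feedback
    carbon_cycle_feedback: 0.0
    biogenic: false
  CH4:
    molar_mass: 16.043
    perturbation_lifetime_years: 11.8
    radiative_efficiency: 1.364e-13
    # tropospheric ozone + stratospheric water vapour enhancement
    indirect_multiplier: 1.503
    # W m-2 per K of induced warming (temperature-driven CO2 outgassing)
    carbon_cycle_feedback: 0.15
    # ruminant CH4 is biogenic: no oxidation-to-fossil-CO2 term
    biogenic: true
  N2O:
    molar_mass: 44.013
    perturbation_lifetime_years: 109.0
    radiative_efficiency: 4.09e-13
    # net of the induced reduction in CH4 lifetime
    indirect_multiplier: 0.88
    carbon_cycle_feedback: 0.15
    biogenic: false

co2_irf:
  # fraction remaining = a0 + sum a_i * exp(-t / tau_i);  a0 + sum a_i = 1
  a0: 0.2173
  terms:
    - [0.2240, 394.4]
    - [0.2824, 36.54]
    - [0.2763, 4.304]

temperature_response:
  # two-box surface/deep-ocean kernel: sum_j (c_j / d_j) exp(-t / d_j)
  # c_j in K (W m-2)-1, d_j in years; sum c_j = 0.763 -> ECS 3.0 K at 2xCO2
  terms:
    - [0.454, 8.4]
    - [0.309, 409.0]
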