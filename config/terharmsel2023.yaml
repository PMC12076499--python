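# Parameter template for the experimentally fitted flow-reactor oscillator.
#
# The rate constants, reactor dilution rate and inflow composition of the
# original study are NOT distributed with this repository; fill in every null
# below from the published source to enable the external period-prediction
# targets (tests/test_acceptance.py::test_criterion_8_reference_period_predictions
# and scripts/acceptance.py --params).
#
# Units: molar concentrations; time in hours (second-order rate constants in
# 1/(M h), dilution rate in 1/h).  Species indices: 1 piperidine,
# 2 Fmoc-piperidine, 3 p-nitrophenyl acetate, 4 phenyl acetate,
# 5 N-methylpiperidine (held constant), 6 dibenzofulvene, 7 N-acetylpiperidine.
time_unit: h
kappa:
  k_tr: null    # trigger deprotection, 1/(M h)
  k_ac: null    # autocatalytic deprotection, 1/(M h)
  k_inh1: null  # fast inhibition (activated ester), 1/(M h)
  k_inh2: null  # slow inhibition (phenyl acetate), 1/(M h)
nmp_conc: null  # constant N-methylpiperidine concentration, M
flow:
  dilution_rate: null  # 1/h
  inflow: {}           # species index -> inflow concentration, M (fuel and
                       # slow-inhibitor entries are overridden per setting)
y0: {}                 # initial reactor composition, species index -> M
horizon: 240.0         # solve horizon for period estimation, h
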