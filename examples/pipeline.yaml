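# Demo pipeline configuration: synthetic recordings at four voltages with
# 0.5 mM blocker, hidden-rate extraction, koff(V) pooling, release-model fit
# and asymmetric (500 mM external KCl) prediction.
# Units: mV, pA, s, s^-1, mol/L-derived activities, mM concentrations.
seed: 11
scheme: "builtin:kcv-like"
kcl_mM: 100.0
voltages_mV: [-120.0, -80.0, 80.0, 120.0]
tpra_mM: [0.5]
duration_s: 10.0
conductance_pS: 55.0
konO_per_M_s: 2.0e+8
noise_sd_pA: 0.8
release_a_per_s: 31400.0
release_b_per_s: 378600.0
asymmetric_external_kcl_mM: 500.0
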