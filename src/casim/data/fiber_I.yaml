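# Type I (slow-oxidative) fiber preset.  All maximum-capacity values refer
# to 22 C; transport V values act on the concentration of their home
# compartment (SERCA/NCX/SOCE: sarcoplasm; MCU/NCE: mitochondrial matrix).
fiber_type: I
temperature_C: 22.0
tn_scheme: single_site
volumes: # fractions of total fiber volume; v_sarc derived as the remainder
  v_SR: 0.029
  v_ttub: 0.002
  v_mito: 0.154
  v_MS: 0.81
resting:
  Ca_sarc_rest: {value: 106.0, unit: nM}
  Ca_SR_rest: {value: 1.14, unit: mM}
  Mg_free_rest: {value: 0.78, unit: mM}
  Mg_total: {value: 3300.0, unit: uM}
  Na_sarc: {value: 10.0, unit: mM}
  Na_mito: {value: 5.0, unit: mM}
  Na_extra: {value: 140.0, unit: mM}
  Ca_extra: {value: 1.0, unit: mM}
buffer_totals: # referenced to the water volume of the home compartment
  Tn_T: {value: 120.0, unit: uM}    # one regulatory Ca site per molecule
  TNS_T: {value: 240.0, unit: uM}
  PV_T: {value: 6.0, unit: uM}
  ATP_T: {value: 5.0, unit: mM}
  CSQ_T: {value: 23.0, unit: mM}
  B_T: {value: 20.0, unit: uM}
  Dye_T: {value: 229.1, unit: uM}
serca:
  V_SERCA: {value: 0.6, unit: uM/ms}
  K_SERCA: {value: 0.38, unit: uM}
  h_SERCA: 2.2
mcu:
  V_MCU: {value: 74.3, unit: uM/s}
  K_MCU: {value: 1.97, unit: uM}
  h_MCU: 3.5
nce:
  V_NCE: {value: 9.19, unit: uM/s}
  K_NCE_Ca: {value: 1.1, unit: mM}
  K_NCE_Na: {value: 8.2, unit: mM}
  dPsi_mito: {value: 190.0, unit: mV}
ncx:
  V_NCX: {value: 93.2, unit: uM/s}  # s^-1 reading adopted; see unit note in docs
  K_NCX_Ca: {value: 130.0, unit: uM}
  K_NCX_Na: {value: 11.0, unit: mM}
  dPsi_m: {value: 80.0, unit: mV}
soce:
  V_SOCE: {value: 15.0, unit: uM/s}
  K_SOCE: {value: 0.35, unit: mM}
  h_SOCE: 4.7
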