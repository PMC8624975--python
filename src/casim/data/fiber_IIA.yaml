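# Type IIA (fast-oxidative) fiber preset; 22 C reference.
fiber_type: IIA
temperature_C: 22.0
tn_scheme: two_site_sequential
volumes:
  v_SR: 0.055
  v_ttub: 0.004
  v_mito: 0.085
  v_MS: 0.75
resting:
  Ca_sarc_rest: {value: 106.0, unit: nM}
  Ca_SR_rest: {value: 1.01, unit: mM}
  Mg_free_rest: {value: 0.78, unit: mM}
  Mg_total: {value: 3300.0, unit: uM}
  Na_sarc: {value: 10.0, unit: mM}
  Na_mito: {value: 5.0, unit: mM}
  Na_extra: {value: 140.0, unit: mM}
  Ca_extra: {value: 1.0, unit: mM}
buffer_totals:
  Tn_T: {value: 240.0, unit: uM}    # two cooperative Ca sites per molecule
  TNS_T: {value: 240.0, unit: uM}
  PV_T: {value: 60.0, unit: uM}
  ATP_T: {value: 8.0, unit: mM}
  CSQ_T: {value: 46.0, unit: mM}
  B_T: {value: 20.0, unit: uM}
  Dye_T: {value: 229.1, unit: uM}
serca:
  V_SERCA: {value: 1.4, unit: uM/ms}
  K_SERCA: {value: 0.44, unit: uM}
  h_SERCA: 2.1
mcu:
  V_MCU: {value: 18.2, unit: uM/s}
  K_MCU: {value: 1.2, unit: uM}
  h_MCU: 2.0
nce:
  V_NCE: {value: 2.25, unit: uM/s}
  K_NCE_Ca: {value: 1.1, unit: mM}
  K_NCE_Na: {value: 8.2, unit: mM}
  dPsi_mito: {value: 190.0, unit: mV}
ncx:
  V_NCX: {value: 120.1, unit: uM/s}
  K_NCX_Ca: {value: 140.0, unit: uM}
  K_NCX_Na: {value: 14.0, unit: mM}
  dPsi_m: {value: 80.0, unit: mV}
soce:
  V_SOCE: {value: 19.0, unit: uM/s}
  K_SOCE: {value: 0.35, unit: mM}
  h_SOCE: 4.7
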