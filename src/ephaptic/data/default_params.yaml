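# Two-ORN sensillum circuit parameters (schema v1).
# common: shared circuit constants; sensilla: per-neuron morphometry (um^2)
# and log10-dilution odorant sensitivities. A_d_is_measured marks dendrite
# surfaces obtained from morphometric reconstruction rather than fitting.
schema: 1
common:
  E_A: 77.0
  V_0: -60.0
  rho_s: 30.0
  rho_d0: 17.0
  n: 0.7
  g_max: 10.0
sensilla:
  ab3:
    A: {A_s: 98.0, A_d: 46.0, k_od: -4.8, A_d_is_measured: false}
    B: {A_s: 91.0, A_d: 16.0, k_od: -5.1, A_d_is_measured: false}
  ab4:
    A: {A_s: 137.0, A_d: 38.0, k_od: -5.9, A_d_is_measured: false}
    B: {A_s: 75.0, A_d: 25.0, k_od: -2.5, A_d_is_measured: false}
  ab5:
    A: {A_s: 65.0, A_d: 20.0, k_od: -1.0, A_d_is_measured: true}
    B: {A_s: 67.0, A_d: 20.0, k_od: -2.0, A_d_is_measured: true}
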