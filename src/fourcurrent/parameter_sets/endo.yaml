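tau_h_plus: 10.8
tau_h_minus: 10.8
tau_f_plus: 355.0
tau_f_minus: 52.3
tau_r_plus: 7.54
tau_r_minus: 6.07
tau_s_plus: 29.1
tau_s_minus: 10.4
g_fi: 1.72
V_fi: 1.24
g_so: 0.00891
g_si: 0.414
beta_1: 22.8
beta_2: 2.95
V_1: 0.522
V_2: 0.596
g_to: 0.3
V_c: 0.13
V_s: 0.6
V_r: 0.6
V_to: 0.0
s_gate_threshold: Vs
label: endo
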