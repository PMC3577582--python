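tau_h_plus: 90.5
tau_h_minus: 6.61
tau_f_plus: 43.1
tau_f_minus: 181.0
tau_r_plus: 13.5
tau_r_minus: 2.2
tau_s_plus: 99.9
tau_s_minus: 4.34
g_fi: 14.0
V_fi: 1.18
g_so: 0.0498
g_si: 0.138
beta_1: 11.8
beta_2: 8.05
V_1: 0.2
V_2: 1.02
g_to: 9.82
V_c: 0.35
V_s: 0.6
V_r: 0.6
V_to: 0.0
s_gate_threshold: Vs
label: tnnp
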