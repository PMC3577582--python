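tau_h_plus: 17.9
tau_h_minus: 11.4
tau_f_plus: 123.0
tau_f_minus: 183.0
tau_r_plus: 2.51
tau_r_minus: 2.0
tau_s_plus: 57.0
tau_s_minus: 10.6
g_fi: 4.0
V_fi: 1.46
g_so: 0.0161
g_si: 0.176
beta_1: 3.99
beta_2: 1.56
V_1: 0.529
V_2: 0.386
g_to: 2.1
V_c: 0.13
V_s: 0.3
V_r: 0.6
V_to: 0.0
s_gate_threshold: Vs
label: epi
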