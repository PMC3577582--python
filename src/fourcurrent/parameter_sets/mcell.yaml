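tau_h_plus: 11.3
tau_h_minus: 1.88
tau_f_plus: 101.0
tau_f_minus: 228.0
tau_r_plus: 2.15
tau_r_minus: 0.371
tau_s_plus: 4.67
tau_s_minus: 1.75
g_fi: 2.62
V_fi: 1.6
g_so: 0.0278
g_si: 0.103
beta_1: 27.1
beta_2: 6.12
V_1: 0.668
V_2: 1.08
g_to: 1.36
V_c: 0.13
V_s: 0.3
V_r: 0.6
V_to: 0.0
s_gate_threshold: Vs
label: mcell
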