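tau_h_plus: 25.8
tau_h_minus: 0.95
tau_f_plus: 488.0
tau_f_minus: 25.4
tau_r_plus: 5.1
tau_r_minus: 13.1
tau_s_plus: 300.0
tau_s_minus: 7.11
g_fi: 10.0
V_fi: 1.2
g_so: 0.0316
g_si: 2.32
beta_1: 6.9
beta_2: 6.36
V_1: 0.453
V_2: 0.828
g_to: 2.5
V_c: 0.38
V_s: 0.6
V_r: 0.6
V_to: 0.0
s_gate_threshold: Vs
label: lrd
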