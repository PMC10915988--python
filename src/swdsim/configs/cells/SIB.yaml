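# strongly intrinsically bursting variant substituted into L5/L6
membrane_capacitance: 1.0
g_Na: 50.0
g_K: 5.0
g_leak: 0.04
E_leak: -78.0
g_T: 2.6
g_NaP: 0.03
g_M: 0.22
tau_M_max: 120.0
VT: -56.2
E_GABAA: -70.0
step_amplitude: 0.8
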