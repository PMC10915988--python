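# network-driver neuron: excitable repetitive burster with persistent Na+
membrane_capacitance: 1.0
g_Na: 50.0
g_K: 5.0
g_leak: 0.04
E_leak: -78.0
g_T: 1.8
g_NaP: 0.02
g_M: 0.22
tau_M_max: 120.0
VT: -56.2
E_GABAA: -70.0
step_amplitude: 0.7
g_KL: 0.015
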