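# intrinsically bursting pyramidal neuron: onset burst via T current
membrane_capacitance: 1.0
g_Na: 50.0
g_K: 5.0
g_leak: 0.04
E_leak: -78.0
g_T: 1.2
g_M: 0.03
tau_M_max: 1000.0
VT: -56.2
E_GABAA: -70.0
step_amplitude: 0.6
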