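# regular-spiking cortical pyramidal neuron
membrane_capacitance: 1.0
g_Na: 56.0
g_K: 6.0
g_leak: 0.0205
E_leak: -70.3
g_M: 0.075
tau_M_max: 608.0
VT: -56.2
E_GABAA: -70.0
step_amplitude: 0.75
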