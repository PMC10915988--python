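# fast-spiking cortical interneuron
membrane_capacitance: 1.0
g_Na: 56.0
g_K: 8.0
g_leak: 0.07
E_leak: -70.0
VT: -57.0
E_GABAA: -70.0
step_amplitude: 2.0
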