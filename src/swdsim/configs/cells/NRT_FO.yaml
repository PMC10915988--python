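# first-order reticular thalamic neuron
membrane_capacitance: 1.0
g_Na: 100.0
g_K: 10.0
g_leak: 0.05
E_leak: -75.0
g_KL: 0.03
g_T: 2.5
g_NaP: 0.005
g_CAN: 0.08
tau_Ca: 2500.0
ca_gain: 5.0e-05
kd_CAN: 0.01
tau_CAN: 300.0
VT: -52.0
E_GABAA: -75.0
step_amplitude: 0.5
hyper_amplitude: -1.5
g_M: 0.25
tau_M_max: 150.0
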