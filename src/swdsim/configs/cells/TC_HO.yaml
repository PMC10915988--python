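# higher-order thalamocortical relay neuron (more depolarised K+ leak set-point)
membrane_capacitance: 1.0
g_Na: 90.0
g_K: 12.0
g_leak: 0.05
E_leak: -55.0
g_KL: 0.045
g_T: 1.6
g_h: 0.02
g_CAN: 0.03
tau_Ca: 150.0
ca_gain: 0.0002
kd_CAN: 0.0015
tau_CAN: 200.0
VT: -52.0
E_GABAA: -85.0
E_Cl: -80.0
step_amplitude: 0.5
hyper_amplitude: -2.0
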