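# Default corticothalamic network: 900 neurons, six sectors.
# Each cortical layer contributes a 100-cell excitatory subsector (mixed
# RS/IB/EF/RIB/ND composition) and a 50-cell FS inhibitory subsector; the
# first- and higher-order thalamic sectors hold 100 TC relay neurons
# reciprocally coupled to 50 NRT neurons each.  Ionotropic weights are
# peak conductance densities (mS/cm^2) added per presynaptic spike at the
# postsynaptic membrane; GABAB weights instead drive the transmitter
# stage of the G-protein cascade, whose maximal conductance is the
# per-population override g_GABAB_max.  radius_P counts topographic
# neighbours on each side at full scale and shrinks with the network.
populations:
- name: L23_E
  layer: L23
  composition:
    RS: 70
    IB: 15
    EF: 10
    RIB: 5
- name: L23_I
  layer: L23
  composition:
    FS: 50
- name: L4_E
  layer: L4
  composition:
    RS: 80
    IB: 10
    EF: 10
- name: L4_I
  layer: L4
  composition:
    FS: 50
- name: L5_E
  layer: L5
  composition:
    RS: 40
    IB: 40
    EF: 5
    RIB: 10
    ND: 5
- name: L5_I
  layer: L5
  composition:
    FS: 50
- name: L6_E
  layer: L6
  composition:
    RS: 55
    IB: 30
    EF: 5
    RIB: 5
    ND: 5
- name: L6_I
  layer: L6
  composition:
    FS: 50
- name: TC_FO
  composition:
    TC_FO: 100
- name: NRT_FO
  composition:
    NRT_FO: 50
- name: TC_HO
  composition:
    TC_HO: 100
- name: NRT_HO
  composition:
    NRT_HO: 50
projections:
- source: L23_E
  target: L23_E
  radius_P: 10
  receptors:
    AMPA: 0.018
  latency_range:
  - 1.0
  - 3.0
- source: L23_E
  target: L23_I
  radius_P: 10
  receptors:
    AMPA: 0.0288
  latency_range:
  - 1.0
  - 2.0
- source: L23_I
  target: L23_E
  radius_P: 10
  receptors:
    GABAA: 0.025
    GABAB: 0.1
  latency_range:
  - 1.0
  - 2.0
- source: L23_I
  target: L23_I
  radius_P: 10
  receptors:
    GABAA: 0.01
  latency_range:
  - 1.0
  - 2.0
- source: L4_E
  target: L4_E
  radius_P: 10
  receptors:
    AMPA: 0.065
  latency_range:
  - 1.0
  - 3.0
- source: L4_E
  target: L4_I
  radius_P: 10
  receptors:
    AMPA: 0.0288
  latency_range:
  - 1.0
  - 2.0
- source: L4_I
  target: L4_E
  radius_P: 10
  receptors:
    GABAA: 0.03
    GABAB: 0.15
  latency_range:
  - 1.0
  - 2.0
- source: L4_I
  target: L4_I
  radius_P: 10
  receptors:
    GABAA: 0.01
  latency_range:
  - 1.0
  - 2.0
- source: L5_E
  target: L5_E
  radius_P: 10
  receptors:
    AMPA: 0.018
  latency_range:
  - 1.0
  - 3.0
- source: L5_E
  target: L5_I
  radius_P: 10
  receptors:
    AMPA: 0.0288
  latency_range:
  - 1.0
  - 2.0
- source: L5_I
  target: L5_E
  radius_P: 10
  receptors:
    GABAA: 0.025
    GABAB: 0.1
  latency_range:
  - 1.0
  - 2.0
- source: L5_I
  target: L5_I
  radius_P: 10
  receptors:
    GABAA: 0.01
  latency_range:
  - 1.0
  - 2.0
- source: L6_E
  target: L6_E
  radius_P: 10
  receptors:
    AMPA: 0.018
  latency_range:
  - 1.0
  - 3.0
- source: L6_E
  target: L6_I
  radius_P: 10
  receptors:
    AMPA: 0.0288
  latency_range:
  - 1.0
  - 2.0
- source: L6_I
  target: L6_E
  radius_P: 10
  receptors:
    GABAA: 0.025
    GABAB: 0.1
  latency_range:
  - 1.0
  - 2.0
- source: L6_I
  target: L6_I
  radius_P: 10
  receptors:
    GABAA: 0.01
  latency_range:
  - 1.0
  - 2.0
- source: L4_E
  target: L23_E
  radius_P: 10
  receptors:
    AMPA: 0.015
  latency_range:
  - 1.0
  - 3.0
- source: L23_E
  target: L5_E
  radius_P: 10
  receptors:
    AMPA: 0.015
  latency_range:
  - 1.0
  - 3.0
- source: L5_E
  target: L6_E
  radius_P: 10
  receptors:
    AMPA: 0.015
  latency_range:
  - 1.0
  - 3.0
- source: L6_E
  target: L4_E
  radius_P: 10
  receptors:
    AMPA: 0.01
  latency_range:
  - 1.0
  - 3.0
- source: L6_E
  target: TC_FO
  radius_P: 10
  receptors:
    AMPA: 0.005
  latency_range:
  - 4.0
  - 7.0
- source: L6_E
  target: NRT_FO
  radius_P: 5
  receptors:
    AMPA: 0.04
  latency_range:
  - 3.0
  - 5.0
- source: L5_E
  target: TC_HO
  radius_P: 10
  receptors:
    AMPA: 0.005
  latency_range:
  - 4.0
  - 7.0
- source: L5_E
  target: NRT_HO
  radius_P: 5
  receptors:
    AMPA: 0.04
  latency_range:
  - 3.0
  - 5.0
- source: TC_FO
  target: L4_E
  radius_P: 5
  receptors:
    AMPA: 0.012
  latency_range:
  - 6.0
  - 9.0
- source: TC_FO
  target: L4_I
  radius_P: 5
  receptors:
    AMPA: 0.08
  latency_range:
  - 6.0
  - 9.0
- source: TC_HO
  target: L23_E
  radius_P: 5
  receptors:
    AMPA: 0.012
  latency_range:
  - 4.0
  - 7.0
- source: TC_HO
  target: L5_E
  radius_P: 5
  receptors:
    AMPA: 0.015
  latency_range:
  - 4.0
  - 7.0
- source: TC_FO
  target: NRT_FO
  radius_P: 3
  receptors:
    AMPA: 0.012
  latency_range:
  - 1.0
  - 2.0
- source: TC_HO
  target: NRT_HO
  radius_P: 3
  receptors:
    AMPA: 0.012
  latency_range:
  - 1.0
  - 2.0
- source: NRT_FO
  target: TC_FO
  radius_P: 5
  receptors:
    GABAA: 0.04
    GABAB: 0.06
  latency_range:
  - 1.0
  - 2.0
- source: NRT_HO
  target: TC_HO
  radius_P: 5
  receptors:
    GABAA: 0.025
    GABAB: 0.04
  latency_range:
  - 1.0
  - 2.0
- source: NRT_FO
  target: NRT_FO
  radius_P: 3
  receptors:
    GABAA: 0.02
  latency_range:
  - 1.0
  - 2.0
- source: NRT_HO
  target: NRT_HO
  radius_P: 3
  receptors:
    GABAA: 0.02
  latency_range:
  - 1.0
  - 2.0
overrides:
  TC_FO:
    g_tonic: 0.01
    g_GABAB_max: 0.3
  TC_HO:
    g_tonic: 0.01
    g_GABAB_max: 0.15
  L23_E:
    g_GABAB_max: 0.03
  L4_E:
    g_GABAB_max: 0.05
  L5_E:
    g_GABAB_max: 0.03
  L6_E:
    g_GABAB_max: 0.03
  L23_I:
    g_GABAB_max: 0.0
  L4_I:
    g_GABAB_max: 0.0
  L5_I:
    g_GABAB_max: 0.0
  L6_I:
    g_GABAB_max: 0.0
background:
  cortex_E:
    rate: 120.0
    weight: 0.008
  cortex_I:
    rate: 200.0
    weight: 0.012
  TC:
    rate: 300.0
    weight: 0.02
  NRT:
    rate: 50.0
    weight: 0.004
states:
  wake:
    g_KL_factor: 0.8
    drive_factor: 1.3
  sleep_wake_transition:
    g_KL_factor: 1.0
    drive_factor: 1.0
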