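# Connection-class synaptic parameters.
# Receptor entries: reversal (mV), tau_rise/tau_decay (ms), g_max (nS),
# strength given as (mean, spread) of the per-connection weight w.  By
# default `spread` is read as a standard deviation of a normal distribution
# truncated at 0.05*mean ("sd" mode); set weight_spread_mode to "var" to
# read it as a variance instead.
weight_spread_mode: sd
weight_distribution: normal
transmitter_pulse_ms: 1.0
classes:
  PN_PN:
    ampa: {reversal: 0.0, tau_rise: 0.3, tau_decay: 6.9, g_max: 1.0,
           strength: [5.0, 3.0]}
    nmda: {reversal: 0.0, tau_rise: 3.7, tau_decay: 125.0, g_max: 0.5,
           strength: [2.0, 1.0]}
    stp: {kind: depression, d_min: 0.5, d1: 0.9, d2: 0.95,
          tau_d1: 40.0, tau_d2: 70.0}
  PN_FSI:
    ampa: {reversal: 0.0, tau_rise: 0.1, tau_decay: 2.4, g_max: 1.0,
           strength: [7.0, 2.0]}
    nmda: {reversal: 0.0, tau_rise: 3.7, tau_decay: 125.0, g_max: 0.5,
           strength: [7.0, 2.0]}
    stp: {kind: depression, d_min: 0.7, d1: 0.9, d2: 0.95,
          tau_d1: 40.0, tau_d2: 70.0}
  FSI_PN:
    gaba: {reversal: -75.0, tau_rise: 0.5, tau_decay: 6.8, g_max: 0.6,
           strength: [12.0, 2.0]}
    stp: {kind: depression, d_min: 0.6, d1: 0.9, d2: 0.95,
          tau_d1: 40.0, tau_d2: 70.0}
  FSI_FSI:
    gaba: {reversal: -75.0, tau_rise: 0.5, tau_decay: 6.8, g_max: 0.2,
           strength: [20.0, 10.0]}
    stp: {kind: depression, d_min: 0.6, d1: 0.9, d2: 0.95,
          tau_d1: 40.0, tau_d2: 70.0}
  # Extrinsic glutamatergic afferents: receptor kinetics are not separately
  # specified, so the intrinsic excitatory classes are reused.
  AFF_PN:
    ampa: {reversal: 0.0, tau_rise: 0.3, tau_decay: 6.9, g_max: 1.0,
           strength: [5.0, 3.0]}
    nmda: {reversal: 0.0, tau_rise: 3.7, tau_decay: 125.0, g_max: 0.5,
           strength: [2.0, 1.0]}
    stp: {kind: depression, d_min: 0.5, d1: 0.9, d2: 0.95,
          tau_d1: 40.0, tau_d2: 70.0}
  AFF_FSI:
    ampa: {reversal: 0.0, tau_rise: 0.1, tau_decay: 2.4, g_max: 1.0,
           strength: [7.0, 2.0]}
    nmda: {reversal: 0.0, tau_rise: 3.7, tau_decay: 125.0, g_max: 0.5,
           strength: [7.0, 2.0]}
    stp: {kind: depression, d_min: 0.7, d1: 0.9, d2: 0.95,
          tau_d1: 40.0, tau_d2: 70.0}
gap_junction:
  coupling_coefficient: 0.05
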