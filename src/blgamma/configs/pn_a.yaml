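# Adapting principal neuron (PN_A): three sections (soma, apical dendrite,
# passive-matching dendrite); each dendrite is electrically split into a
# proximal and a distal compartment so that proximal/distal conductance
# densities (mS/cm^2) can differ.  Geometry in um, cm in uF/cm^2, ra in
# Ohm-cm, reversals in mV.  PN_A and PN_C differ only in the I_sAHP density.
# The leak density follows the specific membrane resistance R_m = 55
# kOhm-cm^2 (1/R_m = 0.018182 mS/cm^2), which reproduces the reported
# passive properties (V_rest -70.3 mV, R_in ~140 MOhm, tau_m ~30 ms).
archetype: PN_A
passive:
  cm: 2.4
  ra: 150.0
  e_leak: -75.0
reversals:
  I_Na: 45.0
  I_DR: -80.0
  I_M: -80.0
  I_H: -45.0
  I_Ca: 120.0
  I_Nap: 45.0
  I_A: -80.0
  I_sAHP: -80.0
calcium:
  # pool driven by the somatic I_Ca density; influx scale k is a calibration
  # constant (dimensionless pool units per mA/cm^2 per ms)
  tau_ms: 1000.0
  influx_scale: 0.001
compartments:
  - name: soma
    diameter: 24.75
    length: 25.0
    parent: null
    g_leak: 0.018182
    channels: {I_Na: 45.0, I_DR: 2.0, I_M: 2.24, I_H: 0.015, I_Ca: 0.55,
               I_Nap: 0.559, I_A: 2.0, I_sAHP: 50.0}
  - name: p-dend-prox
    diameter: 5.0
    length: 277.5
    parent: soma
    g_leak: 0.018182
    channels: {I_Na: 45.0, I_DR: 2.0, I_M: 1.792, I_H: 0.015, I_Ca: 0.55,
               I_Nap: 0.447}
  - name: p-dend-dist
    diameter: 5.0
    length: 277.5
    parent: p-dend-prox
    g_leak: 0.018182
    channels: {I_Na: 45.0, I_DR: 2.0, I_H: 0.015, I_Ca: 0.55}
  - name: a-dend-prox
    diameter: 3.0
    length: 135.0
    parent: soma
    g_leak: 0.018182
    channels: {I_Na: 45.0, I_DR: 2.0, I_M: 2.24, I_H: 0.015, I_Ca: 0.55,
               I_Nap: 0.559, I_A: 2.0}
  - name: a-dend-dist
    diameter: 3.0
    length: 135.0
    parent: a-dend-prox
    g_leak: 0.018182
    channels: {I_Na: 45.0, I_DR: 2.0, I_H: 0.015, I_Ca: 0.55, I_A: 2.0}
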