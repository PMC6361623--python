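# Fast-spiking interneuron: soma + single dendrite, fast Na/K currents only.
# The fsi_* channel kinetics are a documented fast-spiking stand-in
# calibrated to the printed constraints (spike half-width < 1 ms,
# non-adapting repetitive firing).  e_leak is likewise a stand-in.
archetype: FSI
passive:
  cm: 1.0
  ra: 150.0
  e_leak: -70.0
reversals:
  I_Na_fsi: 55.0
  I_DR_fsi: -90.0
calcium: null
compartments:
  - name: soma
    diameter: 15.0
    length: 15.0
    parent: null
    g_leak: 0.05
    channels: {I_Na_fsi: 160.0, I_DR_fsi: 200.0}
  - name: fsi-dend
    diameter: 10.0
    length: 150.0
    parent: soma
    g_leak: 0.05
    channels: {I_Na_fsi: 160.0, I_DR_fsi: 200.0}
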