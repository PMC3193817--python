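# Rate constants of the P2X3 receptor kinetic model after cholesterol
# depletion with methyl-beta-cyclodextrin (MbCD): slower gating (k4),
# faster entry into desensitization (d5, n4) and faster agonist unbinding
# from desensitized states (n1-n3).
label: MbCD
rates:
  k1: {value: 24000.0, units: "mM^-1 s^-1"}
  l1: {value: 15.0, units: "s^-1"}
  k2: {value: 16000.0, units: "mM^-1 s^-1"}
  l2: {value: 30.0, units: "s^-1"}
  k3: {value: 8000.0, units: "mM^-1 s^-1"}
  l3: {value: 45.0, units: "s^-1"}
  k4: {value: 40.0, units: "s^-1"}
  l4: {value: 10.0, units: "s^-1"}
  m1: {value: 24000.0, units: "mM^-1 s^-1"}
  n1: {value: 0.019, units: "s^-1"}
  m2: {value: 16000.0, units: "mM^-1 s^-1"}
  n2: {value: 0.038, units: "s^-1"}
  m3: {value: 8000.0, units: "mM^-1 s^-1"}
  n3: {value: 0.057, units: "s^-1"}
  m4: {value: 0.001, units: "s^-1"}
  n4: {value: 0.68, units: "s^-1"}
  d1: {value: 0.00001, units: "s^-1"}
  r1: {value: 10.0, units: "s^-1"}
  d2: {value: 0.12, units: "s^-1"}
  r2: {value: 0.00001, units: "s^-1"}
  d3: {value: 0.00001, units: "s^-1"}
  r3: {value: 0.00001, units: "s^-1"}
  d4: {value: 0.00001, units: "s^-1"}
  r4: {value: 0.00001, units: "s^-1"}
  d5: {value: 13.0, units: "s^-1"}
  r5: {value: 1.1, units: "s^-1"}
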