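# Cyclic ten-state scheme of P2X3 receptor operation.
#
# Upper branch: sequential binding of up to three agonist molecules to the
# resting receptor (R -> AR -> A2R -> A3R) followed by gating of the fully
# occupied receptor into the open state A3Ro.  Lower branch: the matching
# desensitized states (D -> AD -> A2D -> A3D) plus the rapidly desensitizing
# state A3Df entered directly from the open state.  Vertical transitions
# connect each bound/resting state to its desensitized counterpart.
#
# ligand_order 1 marks binding steps whose propensity is multiplied by the
# agonist concentration (second-order constants, mM^-1 s^-1).
states: [R, AR, A2R, A3R, A3Ro, D, AD, A2D, A3D, A3Df]
transitions:
  - {source: R,    target: AR,   rate: k1, ligand_order: 1}
  - {source: AR,   target: R,    rate: l1, ligand_order: 0}
  - {source: AR,   target: A2R,  rate: k2, ligand_order: 1}
  - {source: A2R,  target: AR,   rate: l2, ligand_order: 0}
  - {source: A2R,  target: A3R,  rate: k3, ligand_order: 1}
  - {source: A3R,  target: A2R,  rate: l3, ligand_order: 0}
  - {source: A3R,  target: A3Ro, rate: k4, ligand_order: 0}
  - {source: A3Ro, target: A3R,  rate: l4, ligand_order: 0}
  - {source: D,    target: AD,   rate: m1, ligand_order: 1}
  - {source: AD,   target: D,    rate: n1, ligand_order: 0}
  - {source: AD,   target: A2D,  rate: m2, ligand_order: 1}
  - {source: A2D,  target: AD,   rate: n2, ligand_order: 0}
  - {source: A2D,  target: A3D,  rate: m3, ligand_order: 1}
  - {source: A3D,  target: A2D,  rate: n3, ligand_order: 0}
  - {source: A3D,  target: A3Df, rate: m4, ligand_order: 0}
  - {source: A3Df, target: A3D,  rate: n4, ligand_order: 0}
  - {source: R,    target: D,    rate: d1, ligand_order: 0}
  - {source: D,    target: R,    rate: r1, ligand_order: 0}
  - {source: AR,   target: AD,   rate: d2, ligand_order: 0}
  - {source: AD,   target: AR,   rate: r2, ligand_order: 0}
  - {source: A2R,  target: A2D,  rate: d3, ligand_order: 0}
  - {source: A2D,  target: A2R,  rate: r3, ligand_order: 0}
  - {source: A3R,  target: A3D,  rate: d4, ligand_order: 0}
  - {source: A3D,  target: A3R,  rate: r4, ligand_order: 0}
  - {source: A3Ro, target: A3Df, rate: d5, ligand_order: 0}
  - {source: A3Df, target: A3Ro, rate: r5, ligand_order: 0}
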