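# Building blocks for the core pentasaccharide.
#
# Chains are written directly in the pentasaccharide label space
# (M/_M, M′/_M′, M″/_M″, G′/′, G/unsuffixed).  Energy annotations (kJ/mol,
# relative) are nominal values used only for the ≤10 kJ/mol block selection:
# they order the blocks the way the external quantum-chemistry results order
# them, with the reported markers (20.1 at 0 K for the lowest-free-energy
# trimannose block; the ~0.4 near-degeneracy and 4.1 free-energy gap between
# the two trisaccharide blocks; 10.7 for the second one at 298 K).
name: pentasaccharide-blocks
trimannose:
  - id: tri-A1
    linkage_classes: {m13: cis, m16: cis}
    energy_0k: 0.0
    gibbs_298: 2.0
    chains:
      - "OH6_M″→OH4_M′→OH3_M′→OH2_M′"
      - "OH2_M″→OH3_M″→OH4_M″→OH6_M′→OH2_M→OM"
      - "OH4_M→OM′"
  - id: tri-G1
    linkage_classes: {m13: trans, m16: cis}
    energy_0k: 20.1
    gibbs_298: 0.0
    chains:
      - "OH4_M′→OH3_M′→OH2_M′→OM′"
      - "OH4_M″→OH3_M″→OH2_M″→OM″"
      - "OH4_M→OH6_M′→OH6_M″"
  - id: tri-J2
    linkage_classes: {m13: trans, m16: cis}
    energy_0k: 5.4
    gibbs_298: 8.0
    chains:
      - "OH2_M′→OH3_M′→OH4_M′"
      - "OH4_M″→OM′"
      - "OH3_M″→OH2_M″→OM″"
      - "OH4_M→OH6_M′→OH6_M″"
nag2man:
  - id: tris-F1
    linkage_classes: {junction: trans, nag: cis}
    energy_0k: 0.0
    gibbs_298: 6.6
    chains:
      - "OH3→OG′"
      - "OH6′→OM"
      - "OH6_M→OH4_M"
      - "OH4_M→OH3_M→OH2_M→OH3′"
      - "NHCO′→OH6→OG"
  - id: tris-R1
    linkage_classes: {junction: cis, nag: trans}
    energy_0k: 0.4
    gibbs_298: 10.7
    chains:
      - "OH6_M→OH3′→OM"
      - "NHCO′→OH3→NHCO→O1"
      - "OH4_M→OH3_M→OH2_M→O′"
      - "OH6′→OH6→OG"
glcnac2:
  - id: di-D1
    linkage_classes: {nag: trans}
    energy_0k: 0.0
    gibbs_298: 0.0
    chains:
      - "OH6→OG′"
      - "NHCO′→OH3→NHCO→O1"
  - id: di-D2
    linkage_classes: {nag: cis}
    energy_0k: 1.0
    gibbs_298: 1.5
    chains:
      - "OH6′→OH3→NHCO→O1"
strategy3:
  # the upper (1→6) and lower (1→3) mannoses each bond either to the
  # disaccharide unit or to the middle mannose: 2 x 2 combination groups
  upper_options:
    - {id: U-di, chains: ["OH4_M″→OH6′"]}
    - {id: U-mid, chains: ["OH6_M″→OH4_M"]}
  lower_options:
    - {id: L-di, chains: ["OH4_M′→OH3′"]}
    - {id: L-mid, chains: ["OH6_M′→OH2_M→OM"]}
  linkage_classes: {m13: cis, m16: cis, junction: trans}
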