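# Motif catalog: Man-GlcNAc-GlcNAc trisaccharide, cis/cis1 linkage classes.
# Groups K-N carry one reversible upper chain plus two reversible lower
# chains (eight variants each); in group O the upper part pins OH6_M onto
# OH4_M, which removes the clockwise direction of the lower M-ring chain.
# The upper chains of groups L-N are depicted only graphically in the source
# material; they are encoded here as distinct reversible upper chains with
# the same structure as group K.
name: nag2man-cis-cis1
molecule: nag2man
linkage_classes: {man: cis, nag: cis}
groups:
  - label: K
    chains:
      - {steps: "OH6_M→OH3′→NHCO′→OH6→OG", region: upper, reversible: true}
      - {steps: "OH4_M→OH3_M→OH2_M→O′", region: lower, reversible: true}
      - {steps: "OH6′→OH3→NHCO→O1", region: lower, reversible: true}
  - label: L
    chains:
      - {steps: "OH6_M→OH3′→OH6→OG", region: upper, reversible: true}
      - {steps: "OH4_M→OH3_M→OH2_M→O′", region: lower, reversible: true}
      - {steps: "OH6′→OH3→NHCO→O1", region: lower, reversible: true}
  - label: M
    chains:
      - {steps: "OH6_M→NHCO′→OH6→OG", region: upper, reversible: true}
      - {steps: "OH4_M→OH3_M→OH2_M→O′", region: lower, reversible: true}
      - {steps: "OH6′→OH3→NHCO→O1", region: lower, reversible: true}
  - label: N
    chains:
      - {steps: "OH6_M→OH3′→OG′", region: upper, reversible: true}
      - {steps: "OH4_M→OH3_M→OH2_M→O′", region: lower, reversible: true}
      - {steps: "OH6′→OH3→NHCO→O1", region: lower, reversible: true}
  - label: O
    chains:
      - {steps: "OH6_M→OH4_M", region: upper}
      - {steps: "OH3′→NHCO′→OH6→OG", region: upper, reversible: true}
      - {steps: "OH4_M→OH3_M→OH2_M→O′", region: lower, reversible: true}
      - {steps: "OH6′→OH3→NHCO→O1", region: lower, reversible: true}
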