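# Motif catalog: Man-GlcNAc-GlcNAc trisaccharide, trans/trans1 linkage classes.
# Groups differ in their inter-ring hydrogen-bond skeleton; reversible chains
# contribute a clockwise and a counterclockwise variant each.  The "excluded"
# entries remove direction combinations rejected because two hydroxyls would
# point at each other; further combinations are pruned automatically by the
# conflict rules.
name: nag2man-trans-trans1
molecule: nag2man
linkage_classes: {man: trans, nag: trans}
groups:
  - label: A
    chains:
      - {steps: "OH6_M→OH6′→OH6→OG", region: upper, reversible: true}
      - {steps: "OH4_M→OH3_M→OH2_M→OH3′", region: lower, reversible: true}
      - {steps: "NHCO′→OH3→NHCO→O1", region: lower}
    excluded:
      # upper counterclockwise + lower clockwise: OH6_M and OH4_M would both
      # terminally accept and point at each other
      - [rev, rev, fwd]
  - label: B
    chains:
      - {steps: "OH6→OG′", region: upper}
      - {steps: "OH6′→OM", region: upper}
      - {steps: "OH6_M→OH4_M", region: upper}
      - {steps: "OH4_M→OH3_M→OH2_M→OH3′", region: lower, reversible: true}
      - {steps: "NHCO′→OH3→NHCO→O1", region: lower}
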