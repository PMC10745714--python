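# Motif catalog: Man-GlcNAc-GlcNAc trisaccharide, trans/cis1 linkage classes.
# Eight groups distinguished by the upper hydrogen bonds; the lower part is a
# cooperative chain whose clockwise variant survives only when the upper part
# does not pin OH6_M onto OH4_M.
name: nag2man-trans-cis1
molecule: nag2man
linkage_classes: {man: trans, nag: cis}
groups:
  - label: C
    chains:
      - {steps: "OH3→OH6′", region: upper}
      - {steps: "OH6_M→OH4_M", region: upper}
      - {steps: "OH4_M→OH3_M→OH2_M→OH3′", region: lower, reversible: true}
      - {steps: "NHCO′→OH6→OG", region: lower}
  - label: D
    chains:
      - {steps: "OH6′→OH3→OG′", region: upper}
      - {steps: "OH6_M→OH4_M", region: upper}
      - {steps: "OH4_M→OH3_M→OH2_M→OH3′", region: lower, reversible: true}
      - {steps: "NHCO′→OH6→OG", region: lower}
  - label: E
    chains:
      - {steps: "OH3→OH6′→NHCO→O1", region: upper}
      - {steps: "OH6_M→OH4_M", region: upper}
      - {steps: "OH4_M→OH3_M→OH2_M→OH3′", region: lower, reversible: true}
      - {steps: "NHCO′→OH6→OG", region: lower}
  - label: F
    chains:
      - {steps: "OH3→OG′", region: upper}
      - {steps: "OH6′→OM", region: upper}
      - {steps: "OH6_M→OH4_M", region: upper}
      - {steps: "OH4_M→OH3_M→OH2_M→OH3′", region: lower, reversible: true}
      - {steps: "NHCO′→OH6→OG", region: lower}
  - label: G
    chains:
      - {steps: "OH3→OH6′", region: upper}
      - {steps: "OH6_M→OM", region: upper}
      - {steps: "OH4_M→OH3_M→OH2_M→OH3′", region: lower, reversible: true}
      - {steps: "NHCO′→OH6→OG", region: lower}
  - label: H
    chains:
      - {steps: "OH6′→OH3→OG′", region: upper}
      - {steps: "OH6_M→OM", region: upper}
      - {steps: "OH4_M→OH3_M→OH2_M→OH3′", region: lower, reversible: true}
      - {steps: "NHCO′→OH6→OG", region: lower}
  - label: I
    chains:
      - {steps: "OH3→OH6′→NHCO→O1", region: upper}
      - {steps: "OH6_M→OM", region: upper}
      - {steps: "OH4_M→OH3_M→OH2_M→OH3′", region: lower, reversible: true}
      - {steps: "NHCO′→OH6→OG", region: lower}
  - label: J
    chains:
      - {steps: "OH3→OG′", region: upper}
      - {steps: "OH6_M→OH6′→OG′", region: upper}
      - {steps: "OH4_M→OH3_M→OH2_M→OH3′", region: lower, reversible: true}
      - {steps: "NHCO′→OH6→OG", region: lower}
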