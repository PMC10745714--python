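# Motif catalog: Man-GlcNAc-GlcNAc trisaccharide, cis/trans1 linkage classes.
# All groups share the lower chains OH4_M→OH3_M→OH2_M→O′ (reversible) and
# OH6′→OH6→OG; they differ in the upper hydrogen bonds.  In group T the
# OH6_M→OH4_M upper bond removes the clockwise lower direction.
name: nag2man-cis-trans1
molecule: nag2man
linkage_classes: {man: cis, nag: trans}
groups:
  - label: P
    chains:
      - {steps: "OH6_M→OH3′→NHCO′→OH3→NHCO→O1", region: upper}
      - {steps: "OH4_M→OH3_M→OH2_M→O′", region: lower, reversible: true}
      - {steps: "OH6′→OH6→OG", region: lower}
  - label: Q
    chains:
      - {steps: "OH3′→OH6_M", region: upper}
      - {steps: "NHCO′→OH3→NHCO→O1", region: upper}
      - {steps: "OH4_M→OH3_M→OH2_M→O′", region: lower, reversible: true}
      - {steps: "OH6′→OH6→OG", region: lower}
  - label: R
    chains:
      - {steps: "OH6_M→OH3′→OM", region: upper}
      - {steps: "NHCO′→OH3→NHCO→O1", region: upper}
      - {steps: "OH4_M→OH3_M→OH2_M→O′", region: lower, reversible: true}
      - {steps: "OH6′→OH6→OG", region: lower}
  - label: S
    chains:
      - {steps: "OH3′→OH6_M→NHCO′", region: upper}
      - {steps: "OH3→OG′", region: upper}
      - {steps: "OH4_M→OH3_M→OH2_M→O′", region: lower, reversible: true}
      - {steps: "OH6′→OH6→OG", region: lower}
  - label: T
    chains:
      - {steps: "OH6_M→OH4_M", region: upper}
      - {steps: "OH3′→OM", region: upper}
      - {steps: "NHCO′→OH3→NHCO→O1", region: upper}
      - {steps: "OH4_M→OH3_M→OH2_M→O′", region: lower, reversible: true}
      - {steps: "OH6′→OH6→OG", region: lower}
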