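# Motif catalog: trimannose (M core, M′ 1→3, M″ 1→6).
# Linkage classes vary per group: A-D cis/cis, E-F cis/trans, G-K trans/cis,
# L-M trans/trans (first class = 1→3 bond, second = 1→6 bond).  Groups C and
# D carry a fragility warning: their inter-ring bonds join two plain
# hydroxyls, whose narrow adjustable range tends to break on optimization.
# Group B's long chain is irreversible because its counterclockwise mirror
# coincides with group A; groups D and F differ from C and E only in the
# hydroxymethyl rotamer on the M″ ring.  Chain sets for groups H, I and
# parts of J-M are figure-derived reconstructions.
name: trimannose
molecule: trimannose
linkage_classes: {m13: cis, m16: cis}
groups:
  - label: A
    chains:
      - {steps: "OH6″→OH4′→OH3′→OH2′", reversible: true}
      - {steps: "OH2″→OH3″→OH4″→OH6′→OH2→O", reversible: true}
      - {steps: "OH4→O′"}
  - label: B
    chains:
      - {steps: "OH2′→OH3′→OH4′→OH6″→OM″"}
      - {steps: "OH2″→OH3″→OH4″→OH6′→OH2→O", reversible: true}
      - {steps: "OH4→O′"}
  - label: C
    warning: inter-ring bonds between plain hydroxyls; equilibrium hard to reach
    chains:
      - {steps: "OH4″→OH4′→OH3′→OH2′", reversible: true}
      - {steps: "OH2″→OH3″→OH6′→OH2→OM", reversible: true}
      - {steps: "OH4→O′"}
  - label: D
    warning: inter-ring bonds between plain hydroxyls; equilibrium hard to reach
    hydroxymethyl: {"M″": gt}
    chains:
      - {steps: "OH4″→OH4′→OH3′→OH2′", reversible: true}
      - {steps: "OH2″→OH3″→OH6′→OH2→OM", reversible: true}
      - {steps: "OH4→O′"}
  - label: E
    linkage_classes: {m13: cis, m16: trans}
    chains:
      - {steps: "OH4″→OH3″→OH2″→OH6′→OH2→OM", reversible: true}
      - {steps: "OH4′→OH3′→OH2′"}
  - label: F
    linkage_classes: {m13: cis, m16: trans}
    hydroxymethyl: {"M″": gt}
    chains:
      - {steps: "OH4″→OH3″→OH2″→OH6′→OH2→OM", reversible: true}
      - {steps: "OH4′→OH3′→OH2′"}
  - label: G
    linkage_classes: {m13: trans, m16: cis}
    chains:
      - {steps: "OH4′→OH3′→OH2′→OM′"}
      - {steps: "OH4″→OH3″→OH2″→OM″"}
      - {steps: "OH4→OH6′→OH6″"}
  - label: H
    linkage_classes: {m13: trans, m16: cis}
    chains:
      - {steps: "OH4′→OH3′→OH2′→OM′"}
      - {steps: "OH4″→OH3″→OH2″→OM″"}
      - {steps: "OH4→OH6′→OH6″→OM″"}
  - label: I
    linkage_classes: {m13: trans, m16: cis}
    chains:
      - {steps: "OH4′→OH3′→OH2′→OM′"}
      - {steps: "OH3″→OH2″→OM″"}
      - {steps: "OH4→OH6′→OH4″→OH6″"}
  - label: J
    linkage_classes: {m13: trans, m16: cis}
    chains:
      - {steps: "OH4′→OH3′→OH2′→OM′", reversible: true}
      - {steps: "OH4″→OM′"}
      - {steps: "OH3″→OH2″→OM″"}
      - {steps: "OH4→OH6′→OH6″"}
  - label: K
    linkage_classes: {m13: trans, m16: cis}
    chains:
      - {steps: "OH4′→OH3′→OH2′→OM′", reversible: true}
      - {steps: "OH4″→OM′"}
      - {steps: "OH3″→OH2″→OM″"}
      - {steps: "OH4→OH6′→OH6″→OM″"}
  - label: L
    linkage_classes: {m13: trans, m16: trans}
    chains:
      - {steps: "OH2→OH6″→OH4″"}
      - {steps: "OH4′→OH3′→OH2′→OM′"}
  - label: M
    linkage_classes: {m13: trans, m16: trans}
    chains:
      - {steps: "OH2→OH6″→OM″"}
      - {steps: "OH4′→OH3′→OH2′→OM′"}
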