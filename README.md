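# glycotree

Tree-based construction and enumeration of gas-phase oligosaccharide
conformers.  Conformers are organized along three axes: glycosidic-linkage
classes (`cis` ≈ Φ,Ψ = −80°,90°; `trans` ≈ 50°,120°), inter-ring
hydrogen-bond chain motifs written in arrow notation
(`OH6_M→OH6′→OH6→OG`), and the clockwise/counterclockwise direction of each
cooperative chain.  The engine builds idealized 3D structures (rigid
⁴C₁-chair pyranose templates joined at exact torsion presets), realizes the
hydrogen-bond chains by deterministic hydroxyl-rotamer solving, prunes
direction combinations that conflict (mutual pointing, double donation,
linkage-consumed sites), and emits structures, manifests and QM-ready input
decks.  Post-processing utilities handle harmonic-frequency scaling, IR
envelope broadening, Boltzmann population weights and 0 K vs 298.15 K
conformer ranking from externally computed energy tables.

Built-in catalogs cover three molecules:

* Manβ(1,4)GlcNAcβ(1,4)GlcNAc — four linkage-class catalogs
  (`nag2man-trans-trans1`, `-trans-cis1`, `-cis-cis1`, `-cis-trans1`)
* Manα(1,3)Manα(1,6)Man — `trimannose`
* the N-glycan core pentasaccharide — three block-combination strategies
  (`pentasaccharide-strategy1/2/3`)

Catalogs are data (`src/glycotree/data/catalogs/*.yaml`), not code; you can
define new molecules and motif inventories in the same format.  Residue
templates are versioned internal-coordinate tables
(`src/glycotree/data/templates/*.zmat`).

## CLI

```sh
# expand a catalog into structures + manifest.tsv
glycotree enumerate --catalog trisaccharide-trans-trans1 --out out/ --formats xyz,pdb,qm

# assemble a single skeleton at its linkage presets
glycotree build --molecule trimannose --classes m13=cis,m16=cis --out trimannose.xyz

# scale a frequency table (OH 0.9734 / NH 0.9600) and write the envelope
glycotree spectra --freqs freqs.txt --scale-set stretch --fwhm 15 --out envelope.tsv

# rank conformers by tabulated energies, reporting 0 K vs 298 K rank changes
glycotree rank --energies energies.txt --key gibbs298

glycotree validate-catalog my-catalog.yaml
glycotree catalogs
```

All commands are deterministic; reruns produce byte-identical outputs.

## Library sketch

```python
from glycotree.tree import builtin_catalog, enumerate_conformers

result = enumerate_conformers(builtin_catalog("nag2man-trans-cis1"))
result.total                      # 12
result.counts_per_group           # {'C': 1, ..., 'J': 2}
rec = result.conformers[0]
rec.realized_hbonds               # geometric H-bonds (< 2.8 Å, strict)
rec.infeasible                    # chain steps the rigid skeleton cannot satisfy
```

Note: structures are pre-optimization seeds for an external quantum-chemistry
engine (the package writes input decks and reads frequency/energy tables; it
never runs QM itself).  The dihedral sign convention is IUPAC
(clockwise-positive sighting along the central bond); the source notation
does not state one.

## Layout

```
src/glycotree/
  geom.py       Z-matrix/Cartesian kernel, measure/set dihedral
  templates.py  α-D-Man and β-D-GlcNAc chair templates + site definitions
  linkage.py    oligomer assembly, torsion presets, upper/lower partition
  hbonds.py     chain notation, rotamer solving, detection, conflict rules
  tree.py       catalogs, direction expansion, block combination
  spectra.py    scaling, broadening, Boltzmann weights, ranking
  io.py         XYZ/PDB/QM-deck writers, tables, manifests
  cli.py        command-line interface
  data/         residue templates (.zmat) and motif catalogs (.yaml)
scripts/
  acceptance.py         acceptance report
  generate_templates.py regenerates the template tables
tests/                  pytest suite (test_acceptance.py holds the criteria)
```
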