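"""Oligosaccharide skeleton assembly.

Joins residue templates through glycosidic linkages, applies the cis/trans
torsion presets, tracks which functional-group sites each bond consumes, and
computes the split-plane upper/lower partition of the remaining sites.

Linkage torsions follow the bridge-oxygen convention
Φ = ringO(child)-C1(child)-O(bridge)-Cx(parent) and
Ψ = C1(child)-O(bridge)-Cx(parent)-C(x-1)(parent); for 1→6 linkages the
extra exocyclic torsion ω = O6-C6-C5-O5 of the parent is set to the gg
staggered rotamer by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateFrameError, TopologyError
from .geom import MolecularStructure, measure_dihedral, set_dihedral
from .templates import FunctionalGroupSite, build_template

__all__ = [
    "LINK_CLASS_PRESETS",
    "GlycosidicLinkage",
    "ResidueSpec",
    "OligomerTopology",
    "AssembledOligomer",
    "assemble_oligomer",
    "set_linkage_conformation",
    "partition_upper_lower",
    "nag2man_topology",
    "trimannose_topology",
    "pentasaccharide_topology",
    "man_glcnac_topology",
    "glcnac2_topology",
]

#: (Φ, Ψ) presets per linkage class, degrees.
LINK_CLASS_PRESETS: dict[str, tuple[float, float]] = {
    "cis": (-80.0, 90.0),
    "trans": (50.0, 120.0),
}

#: Glycosidic C-O-C bond angle (degrees) and C1-O bridge bond length (Å).
GLYCOSIDIC_ANGLE = 117.0
GLYCOSIDIC_BOND = 1.43

#: Default exocyclic ω (O6-C6-C5-O5) for 1→6 linkages: the gg rotamer.
OMEGA_GG = -60.0


@dataclass
class GlycosidicLinkage:
    """``child`` C1 bonded through the parent's O{position}."""

    child: str
    parent: str
    position: int
    link_class: str = "trans"
    omega: float | None = None
    #: anomeric configuration of the bond; ``None`` keeps the child template's
    #: own configuration, ``"alpha"``/``"beta"`` forces it (a β-linked mannose
    #: attaches through the equatorial anomeric direction even though the
    #: free-residue template is the α anomer).
    anomeric: str | None = None

    def __post_init__(self) -> None:
        if self.link_class not in LINK_CLASS_PRESETS:
            raise TopologyError(
                f"unknown linkage class {self.link_class!r}; expected one of "
                f"{sorted(LINK_CLASS_PRESETS)}"
            )
        if self.position not in (2, 3, 4, 6):
            raise TopologyError(f"unsupported attachment position {self.position}")

    @property
    def preset(self) -> tuple[float, float]:
        return LINK_CLASS_PRESETS[self.link_class]


@dataclass
class ResidueSpec:
    """A residue instance in a topology.

    ``site_suffix`` decorates per-residue site labels (e.g. ``_M`` giving
    ``OH6_M``); ``ring_labels`` are the accepted names of the ring oxygen
    (first entry is canonical, e.g. ``OM`` with synonym ``O``).
    """

    tag: str
    template: str
    site_suffix: str = ""
    ring_labels: tuple[str, ...] = ()


@dataclass
class OligomerTopology:
    name: str
    residues: list[ResidueSpec]
    linkages: list[GlycosidicLinkage]

    def residue(self, tag: str) -> ResidueSpec:
        for r in self.residues:
            if r.tag == tag:
                return r
        raise TopologyError(f"unknown residue tag {tag!r}")

    def validate(self) -> str:
        """Check the linkage graph is a tree; return the root residue tag."""
        tags = [r.tag for r in self.residues]
        if len(set(tags)) != len(tags):
            raise TopologyError("duplicate residue tags")
        children = [l.child for l in self.linkages]
        if len(set(children)) != len(children):
            raise TopologyError("a residue is the child of two linkages")
        consumed: set[tuple[str, int]] = set()
        for l in self.linkages:
            if l.child not in tags or l.parent not in tags:
                raise TopologyError(f"linkage references unknown residue {l.child}->{l.parent}")
            key = (l.parent, l.position)
            if key in consumed:
                raise TopologyError(f"position {l.position} of {l.parent!r} already consumed")
            consumed.add(key)
        roots = [t for t in tags if t not in children]
        if len(roots) != 1:
            raise TopologyError(f"linkage graph is not a single tree (roots: {roots})")
        # cycle check: walk up from every residue
        parent_of = {l.child: l.parent for l in self.linkages}
        for t in tags:
            seen = set()
            cur = t
            while cur in parent_of:
                if cur in seen:
                    raise TopologyError("cyclic linkage graph")
                seen.add(cur)
                cur = parent_of[cur]
        return roots[0]


@dataclass
class SiteInstance:
    """A functional-group site bound to a specific residue of an oligomer."""

    residue: str
    site: FunctionalGroupSite
    label: str                      # canonical molecule-level label
    aliases: tuple[str, ...]
    consumed: bool = False

    def atom(self, oligomer: "AssembledOligomer", name: str) -> int:
        return oligomer.atom_index(self.residue, name)

    def donor_h(self, oligomer: "AssembledOligomer") -> int:
        return oligomer.atom_index(self.residue, self.site.donor_atoms[0])

    def acceptor_atom(self, oligomer: "AssembledOligomer") -> int:
        return oligomer.atom_index(self.residue, self.site.acceptor_atoms[0])

    def heavy_atom(self, oligomer: "AssembledOligomer") -> int:
        """The site's attachment heavy atom (O of a hydroxyl, N of the amide)."""
        if self.site.label == "NHCO":
            return oligomer.atom_index(self.residue, "N2")
        return self.acceptor_atom(oligomer)


class AssembledOligomer:
    """A built oligosaccharide: structure + residue/site bookkeeping."""

    def __init__(self, topology: OligomerTopology):
        self.topology = topology
        self.structure: MolecularStructure | None = None
        self.atom_map: dict[str, dict[str, int]] = {}
        self.sites: list[SiteInstance] = []
        self._site_lookup: dict[str, SiteInstance] = {}

    def atom_index(self, residue: str, name: str) -> int:
        return self.atom_map[residue][name]

    def site(self, label: str) -> SiteInstance:
        key = _normalize_label(label)
        try:
            return self._site_lookup[key]
        except KeyError:
            raise KeyError(f"no site {label!r} in {self.topology.name}") from None

    def has_site(self, label: str) -> bool:
        return _normalize_label(label) in self._site_lookup

    def active_sites(self) -> list[SiteInstance]:
        return [s for s in self.sites if not s.consumed]

    def register_site(self, inst: SiteInstance) -> None:
        self.sites.append(inst)
        for alias in (inst.label, *inst.aliases):
            self._site_lookup[_normalize_label(alias)] = inst

    def copy_structure(self) -> "AssembledOligomer":
        out = AssembledOligomer(self.topology)
        out.structure = self.structure.copy()
        out.atom_map = {k: dict(v) for k, v in self.atom_map.items()}
        out.sites = self.sites
        out._site_lookup = self._site_lookup
        return out

    def linkage_torsion_atoms(self, linkage: GlycosidicLinkage):
        """Atom indices for (Φ, Ψ) of a linkage, as two quadruples."""
        child, parent = linkage.child, linkage.parent
        x = linkage.position
        bridge = self.atom_index(parent, f"O{x}")
        c1 = self.atom_index(child, "C1")
        o5c = self.atom_index(child, "O5")
        cx = self.atom_index(parent, f"C{x}")
        prev = self.atom_index(parent, f"C{x - 1}")
        phi = (o5c, c1, bridge, cx)
        psi = (c1, bridge, cx, prev)
        return phi, psi

    def measure_linkage(self, linkage: GlycosidicLinkage) -> tuple[float, float]:
        phi_atoms, psi_atoms = self.linkage_torsion_atoms(linkage)
        return (
            measure_dihedral(self.structure, *phi_atoms),
            measure_dihedral(self.structure, *psi_atoms),
        )


def _normalize_label(label: str) -> str:
    return (
        label.strip()
        .replace("->", "→")
        .replace("'", "′")
        .replace("’", "′")
        .replace("''", "″")
        .replace("′′", "″")
    )


def _align_vectors(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping unit vector a onto unit vector b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # opposite: rotate 180 degrees about any perpendicular axis
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-6:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        from .geom import _rotation_matrix

        return _rotation_matrix(axis, np.pi)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def assemble_oligomer(topology: OligomerTopology) -> AssembledOligomer:
    """Build the 3D skeleton of an oligomer with all linkage torsions at their
    class presets.  Atom count is Σ residue atoms − 3 per linkage."""
    root = topology.validate()
    out = AssembledOligomer(topology)
    templates = {r.tag: build_template(r.template) for r in topology.residues}

    consumed: dict[str, set[str]] = {r.tag: set() for r in topology.residues}
    for l in topology.linkages:
        # the child's anomeric hydroxyl and the parent site at the attachment
        # position are lost to the condensation
        consumed[l.child].add("OH1")
        parent_site = "NHCO" if l.position == 2 else f"OH{l.position}"
        consumed[l.parent].add(parent_site)

    def residue_atoms(tag: str, drop: set[str]) -> tuple[list, list, dict[str, int]]:
        tpl = templates[tag]
        keep = [a for a in tpl.structure.atoms if a.name not in drop]
        index_map = {}
        atoms = []
        for a in keep:
            index_map[a.name] = len(atoms)
            atoms.append(a)
        bonds = []
        old_new = {a.index: index_map[a.name] for a in keep}
        for b in tpl.structure.bonds:
            i, j = sorted(b)
            if i in old_new and j in old_new:
                bonds.append((old_new[i], old_new[j]))
        return atoms, bonds, index_map

    # place the root residue as-is
    structure = MolecularStructure([], [])
    atom_map: dict[str, dict[str, int]] = {}

    def append_residue(tag: str, atoms, bonds) -> None:
        offset = len(structure.atoms)
        from dataclasses import replace

        for a in atoms:
            structure.atoms.append(
                replace(a, residue_id=tag, position=a.position.copy())
            )
        structure.reindex()
        for i, j in bonds:
            structure.add_bond(offset + i, offset + j)
        atom_map[tag] = {a.name: offset + k for k, a in enumerate(atoms)}

    root_atoms, root_bonds, _ = residue_atoms(root, set())
    append_residue(root, root_atoms, root_bonds)

    # BFS attach children
    by_parent: dict[str, list[GlycosidicLinkage]] = {}
    for l in topology.linkages:
        by_parent.setdefault(l.parent, []).append(l)
    queue = [root]
    while queue:
        parent = queue.pop(0)
        for l in by_parent.get(parent, []):
            child = l.child
            tpl = templates[child]
            x = l.position
            phi, psi = l.preset
            bridge = atom_map[parent][f"O{x}"]
            cx = atom_map[parent][f"C{x}"]
            prev = atom_map[parent][f"C{x - 1}"]
            # remove the parent hydroxyl hydrogen at the attachment position
            h_name = f"HO{x}"
            if h_name in atom_map[parent]:
                _remove_atom(structure, atom_map, parent, h_name)
                bridge = atom_map[parent][f"O{x}"]
                cx = atom_map[parent][f"C{x}"]
                prev = atom_map[parent][f"C{x - 1}"]
            # position for the child's anomeric carbon: bond to the bridge O,
            # glycosidic angle at the bridge, torsion = Ψ
            from .geom import place_atom

            c1_target = place_atom(
                structure.atoms[bridge].position,
                structure.atoms[cx].position,
                structure.atoms[prev].position,
                GLYCOSIDIC_BOND,
                GLYCOSIDIC_ANGLE,
                psi,
            )
            # rigid-place the child: C1 at target, former C1->O1 axis onto C1->bridge
            child_struct = tpl.structure.copy()
            c1_local = child_struct.index_of("", "C1")
            o1_local = child_struct.index_of("", "O1")
            if l.anomeric is not None and l.anomeric != tpl.anomeric_config:
                # epimerize the anomeric centre: swap the O1 and H1 directions
                h1_local = child_struct.index_of("", "H1")
                c1p = child_struct.atoms[c1_local].position
                o1v = child_struct.atoms[o1_local].position - c1p
                h1v = child_struct.atoms[h1_local].position - c1p
                ho1_local = child_struct.index_of("", "HO1")
                ho1v = child_struct.atoms[ho1_local].position - child_struct.atoms[o1_local].position
                new_o1 = c1p + h1v / np.linalg.norm(h1v) * np.linalg.norm(o1v)
                new_h1 = c1p + o1v / np.linalg.norm(o1v) * np.linalg.norm(h1v)
                child_struct.atoms[o1_local].position = new_o1
                child_struct.atoms[h1_local].position = new_h1
                child_struct.atoms[ho1_local].position = new_o1 + ho1v
            a_dir = child_struct.atoms[o1_local].position - child_struct.atoms[c1_local].position
            b_dir = structure.atoms[bridge].position - c1_target
            rot = _align_vectors(a_dir, b_dir)
            origin = child_struct.atoms[c1_local].position.copy()
            for a in child_struct.atoms:
                a.position = rot @ (a.position - origin) + c1_target
            # strip the anomeric hydroxyl, then merge
            drop = {"O1", "HO1"}
            keep = [a for a in child_struct.atoms if a.name not in drop]
            index_map = {a.index: k for k, a in enumerate(keep)}
            bonds = [
                (index_map[i], index_map[j])
                for b in child_struct.bonds
                for i, j in [sorted(b)]
                if i in index_map and j in index_map
            ]
            append_residue(child, keep, bonds)
            structure.add_bond(atom_map[child]["C1"], bridge)
            # spin about the new glycosidic bond to set Φ
            out.structure = structure
            out.atom_map = atom_map
            set_dihedral(
                structure,
                atom_map[parent][f"C{x}"],
                bridge,
                atom_map[child]["C1"],
                atom_map[child]["O5"],
                phi,
                in_place=True,
            )
            if x == 6:
                omega = l.omega if l.omega is not None else OMEGA_GG
                set_dihedral(
                    structure,
                    atom_map[parent]["O5"],
                    atom_map[parent]["C5"],
                    atom_map[parent]["C6"],
                    atom_map[parent]["O6"],
                    omega,
                    in_place=True,
                )
            queue.append(child)

    out.structure = structure
    out.atom_map = atom_map

    # register molecule-level sites
    for spec in topology.residues:
        tpl = templates[spec.tag]
        for site in tpl.sites:
            if site.label == "O":
                labels = spec.ring_labels or (f"O{spec.site_suffix}",)
                label, aliases = labels[0], tuple(labels[1:])
            else:
                label = site.label + spec.site_suffix
                aliases = ()
            inst = SiteInstance(
                spec.tag, site, label, aliases, consumed=site.label in consumed[spec.tag]
            )
            out.register_site(inst)
        # the reducing end keeps its anomeric hydroxyl; expose its oxygen as
        # the acceptor-only label "O1"
        if "OH1" not in consumed[spec.tag]:
            o1_site = FunctionalGroupSite("O1", (), ("O1",), position=1)
            out.register_site(SiteInstance(spec.tag, o1_site, "O1" + spec.site_suffix, ()))

    expected = sum(len(templates[r.tag].structure.atoms) for r in topology.residues) - 3 * len(
        topology.linkages
    )
    if len(structure.atoms) != expected:
        raise TopologyError(
            f"atom bookkeeping violated: {len(structure.atoms)} atoms, expected {expected}"
        )
    return out


def _remove_atom(structure: MolecularStructure, atom_map, residue: str, name: str) -> None:
    idx = atom_map[residue][name]
    del structure.atoms[idx]
    new_bonds = set()
    for b in structure.bonds:
        if idx in b:
            continue
        new_bonds.add(frozenset(i - 1 if i > idx else i for i in b))
    structure.bonds = new_bonds
    structure.reindex()
    for res, names in atom_map.items():
        for n, i in list(names.items()):
            if i == idx and res == residue and n == name:
                del names[n]
            elif i > idx:
                names[n] = i - 1


def set_linkage_conformation(
    oligomer: AssembledOligomer, linkage: GlycosidicLinkage, link_class: str
) -> AssembledOligomer:
    """Set a linkage's (Φ, Ψ) to the preset of ``link_class`` (exact)."""
    if link_class not in LINK_CLASS_PRESETS:
        raise TopologyError(f"unknown linkage class {link_class!r}")
    phi, psi = LINK_CLASS_PRESETS[link_class]
    phi_atoms, psi_atoms = oligomer.linkage_torsion_atoms(linkage)
    o5c, c1, bridge, cx = phi_atoms
    _, _, _, prev = psi_atoms
    s = oligomer.structure
    set_dihedral(s, prev, cx, bridge, c1, psi, in_place=True)
    set_dihedral(s, cx, bridge, c1, o5c, phi, in_place=True)
    return oligomer


def partition_upper_lower(
    oligomer: AssembledOligomer, split_ring_oxygens: list[int]
) -> dict[str, str]:
    """Assign every active site to the upper or lower part.

    The split plane is the least-squares plane through the given ring-oxygen
    atoms, oriented so that the majority of exocyclic C6 atoms lie on the
    positive (upper) side.  Sites are classified by their attachment heavy
    atom.
    """
    if len(split_ring_oxygens) < 3:
        raise DegenerateFrameError("need at least three ring oxygens for the split plane")
    pts = oligomer.structure.positions[split_ring_oxygens]
    centroid = pts.mean(axis=0)
    _, sv, vt = np.linalg.svd(pts - centroid)
    if sv[1] < 1e-8:
        raise DegenerateFrameError("split-plane atoms are collinear")
    normal = vt[2]
    c6 = [
        oligomer.atom_index(r.tag, "C6")
        for r in oligomer.topology.residues
        if "C6" in oligomer.atom_map[r.tag]
    ]
    side = sum(np.sign(np.dot(oligomer.structure.atoms[i].position - centroid, normal)) for i in c6)
    if side < 0:
        normal = -normal
    out: dict[str, str] = {}
    for inst in oligomer.active_sites():
        p = oligomer.structure.atoms[inst.heavy_atom(oligomer)].position
        # atoms on the plane itself (the defining ring oxygens) count as upper
        out[inst.label] = "upper" if np.dot(p - centroid, normal) >= -1e-6 else "lower"
    return out


# ---------------------------------------------------------------------------
# built-in topologies
# ---------------------------------------------------------------------------


def nag2man_topology(class_man: str = "trans", class_nag: str = "trans") -> OligomerTopology:
    """Manβ(1,4)GlcNAcβ(1,4)GlcNAc: rings M, G′, G (G is the reducing end).

    ``class_man`` is the Man→GlcNAc′ linkage class (Φ, Ψ); ``class_nag`` the
    GlcNAc′→GlcNAc one (Φ₁, Ψ₁).
    """
    return OligomerTopology(
        name="Man-GlcNAc-GlcNAc",
        residues=[
            ResidueSpec("G", "beta-D-GlcNAc", "", ("OG",)),
            ResidueSpec("G′", "beta-D-GlcNAc", "′", ("OG′", "O′")),
            ResidueSpec("M", "alpha-D-Man", "_M", ("OM", "O_M")),
        ],
        linkages=[
            GlycosidicLinkage("G′", "G", 4, class_nag),
            GlycosidicLinkage("M", "G′", 4, class_man, anomeric="beta"),
        ],
    )


def trimannose_topology(class_13: str = "cis", class_16: str = "cis") -> OligomerTopology:
    """Manα(1,3)Manα(1,6)Man: M is the reducing core, M′ 1→3, M″ 1→6."""
    return OligomerTopology(
        name="trimannose",
        residues=[
            ResidueSpec("M", "alpha-D-Man", "", ("O", "OM")),
            ResidueSpec("M′", "alpha-D-Man", "′", ("O′", "OM′")),
            ResidueSpec("M″", "alpha-D-Man", "″", ("O″", "OM″")),
        ],
        linkages=[
            GlycosidicLinkage("M′", "M", 3, class_13),
            GlycosidicLinkage("M″", "M", 6, class_16),
        ],
    )


def pentasaccharide_topology(
    class_13: str = "cis",
    class_16: str = "cis",
    class_junction: str = "trans",
    class_nag: str = "trans",
) -> OligomerTopology:
    """The core pentasaccharide Manα(1,3)[Manα(1,6)]Manβ(1,4)GlcNAcβ(1,4)GlcNAc."""
    return OligomerTopology(
        name="core-pentasaccharide",
        residues=[
            ResidueSpec("G", "beta-D-GlcNAc", "", ("OG",)),
            ResidueSpec("G′", "beta-D-GlcNAc", "′", ("OG′", "O′")),
            ResidueSpec("M", "alpha-D-Man", "_M", ("OM", "O_M")),
            ResidueSpec("M′", "alpha-D-Man", "_M′", ("OM′",)),
            ResidueSpec("M″", "alpha-D-Man", "_M″", ("OM″",)),
        ],
        linkages=[
            GlycosidicLinkage("G′", "G", 4, class_nag),
            GlycosidicLinkage("M", "G′", 4, class_junction, anomeric="beta"),
            GlycosidicLinkage("M′", "M", 3, class_13),
            GlycosidicLinkage("M″", "M", 6, class_16),
        ],
    )


def man_glcnac_topology(link_class: str = "trans") -> OligomerTopology:
    """The Manβ(1,4)GlcNAc disaccharide (rings M over G′)."""
    return OligomerTopology(
        name="Man-GlcNAc",
        residues=[
            ResidueSpec("G′", "beta-D-GlcNAc", "′", ("OG′", "O′")),
            ResidueSpec("M", "alpha-D-Man", "_M", ("OM",)),
        ],
        linkages=[GlycosidicLinkage("M", "G′", 4, link_class, anomeric="beta")],
    )


def glcnac2_topology(link_class: str = "trans") -> OligomerTopology:
    """The GlcNAcβ(1,4)GlcNAc disaccharide (rings G′ over G)."""
    return OligomerTopology(
        name="GlcNAc-GlcNAc",
        residues=[
            ResidueSpec("G", "beta-D-GlcNAc", "", ("OG",)),
            ResidueSpec("G′", "beta-D-GlcNAc", "′", ("OG′", "O′")),
        ],
        linkages=[GlycosidicLinkage("G′", "G", 4, link_class)],
    )
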