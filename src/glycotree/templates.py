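"""Built-in idealized pyranose residue templates.

Residues are rigid :sup:`4`\\ C\\ :sub:`1` chairs with idealized bond lengths
(C-C 1.53 Å, C-O 1.43 Å, O-H 0.96 Å, N-H 1.01 Å, C=O 1.22 Å, C-H 1.09 Å) and
tetrahedral centres.  Each template exposes labeled functional-group sites
(hydroxyls, the acetamido group, the ring oxygen) with their donor/acceptor
atoms and the exocyclic torsion that orients the site's hydrogen.

Geometry is stored as versioned internal-coordinate tables under
``data/templates`` (see the file headers for the column format); the builder
here reconstructs Cartesian coordinates from those tables.  The tables
themselves are produced by ``scripts/generate_templates.py`` from the
programmatic construction in this module.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.optimize import least_squares

from .errors import BuildError, CatalogError
from .geom import (
    AtomRecord,
    InternalCoordinateRow,
    MolecularStructure,
    measure_distance,
    place_atom,
    zmatrix_to_cartesian,
)

__all__ = [
    "FunctionalGroupSite",
    "MonosaccharideTemplate",
    "build_template",
    "list_sites",
    "KNOWN_RESIDUES",
]

KNOWN_RESIDUES = ("alpha-D-Man", "beta-D-GlcNAc")

# Idealized geometry (Å / degrees)
CC = 1.53
CO = 1.43
OH = 0.96
NH = 1.01
CN = 1.47
CN_AMIDE = 1.35
C_DOUBLE_O = 1.22
CH = 1.09
TET = 109.47
SP2 = 120.0
RING_TORSION = 55.0

RING_ATOMS = ("O5", "C1", "C2", "C3", "C4", "C5")


@dataclass
class FunctionalGroupSite:
    """A labeled hydrogen-bonding site on a residue.

    ``h_torsion`` is the four-atom tuple (by atom name) whose last atom is the
    donor hydrogen; setting that dihedral re-orients the hydrogen.
    ``heavy_torsion`` additionally positions the site's heavy atom (only the
    hydroxymethyl site has one: the exocyclic C5-C6 rotation).
    """

    label: str
    donor_atoms: tuple[str, ...]
    acceptor_atoms: tuple[str, ...]
    h_torsion: tuple[str, str, str, str] | None = None
    heavy_torsion: tuple[str, str, str, str] | None = None
    position: int | None = None
    axial: bool | None = None

    @property
    def is_donor(self) -> bool:
        return bool(self.donor_atoms)


@dataclass
class MonosaccharideTemplate:
    name: str
    anomeric_config: str
    structure: MolecularStructure
    sites: list[FunctionalGroupSite]

    @property
    def atom_names(self) -> list[str]:
        return [a.name for a in self.structure.atoms]

    def site(self, label: str) -> FunctionalGroupSite:
        for s in self.sites:
            if s.label == label:
                return s
        raise KeyError(label)

    def ring_closure_gap(self) -> float:
        s = self.structure
        c5 = next(a.index for a in s.atoms if a.name == "C5")
        o5 = next(a.index for a in s.atoms if a.name == "O5")
        return abs(measure_distance(s, c5, o5) - CO)


# ---------------------------------------------------------------------------
# ring construction: solve a 4C1 chair with mixed C-C/C-O bond lengths
# ---------------------------------------------------------------------------


def _solve_chair_ring() -> np.ndarray:
    """Positions of O5,C1..C5 for a closed chair with alternating ±55° torsions.

    Bond lengths are fixed (C-O for the two ring-oxygen bonds, C-C elsewhere);
    four angles and three torsions are adjusted by least squares so the ring
    closes (residual gap well below 1e-3 Å).
    """
    lengths = [CO, CC, CC, CC, CC]  # O5-C1, C1-C2, C2-C3, C3-C4, C4-C5

    def build(x):
        a1, a2, a3, a4, t1, t2, t3 = x
        p = [np.zeros(3), np.array([lengths[0], 0.0, 0.0])]
        ang = np.radians(a1)
        p.append(p[1] + lengths[1] * np.array([-np.cos(ang), np.sin(ang), 0.0]))
        p.append(place_atom(p[2], p[1], p[0], lengths[2], a2, t1))
        p.append(place_atom(p[3], p[2], p[1], lengths[3], a3, t2))
        p.append(place_atom(p[4], p[3], p[2], lengths[4], a4, t3))
        return np.array(p)

    def _dihedral(p, i, j, k, l):
        from .geom import _dihedral_from_points

        return _dihedral_from_points(p[i], p[j], p[k], p[l])

    def _angle(p, i, j, k):
        u = p[i] - p[j]
        v = p[k] - p[j]
        c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        return np.degrees(np.arccos(np.clip(c, -1, 1)))

    # targets: alternating ring torsions, tetrahedral-ish angles, closed ring
    def residuals(x):
        p = build(x)
        r = [
            (np.linalg.norm(p[5] - p[0]) - CO) * 1e4,            # C5-O5 closure
            (_angle(p, 4, 5, 0) - TET) * 1.0,                    # C4-C5-O5
            (_angle(p, 5, 0, 1) - TET) * 1.0,                    # C5-O5-C1
            (_dihedral(p, 2, 3, 4, 5) - RING_TORSION) * 1.0,     # C2-C3-C4-C5
            (_dihedral(p, 3, 4, 5, 0) + RING_TORSION) * 1.0,     # C3-C4-C5-O5
            (_dihedral(p, 4, 5, 0, 1) - RING_TORSION) * 1.0,     # C4-C5-O5-C1
            (x[0] - TET) * 0.1,
            (x[1] - TET) * 0.1,
            (x[2] - TET) * 0.1,
            (x[3] - TET) * 0.1,
            (_dihedral(p, 0, 1, 2, 3) - RING_TORSION) * 0.3,     # O5-C1-C2-C3
            (_dihedral(p, 1, 2, 3, 4) + RING_TORSION) * 0.3,     # C1-C2-C3-C4
        ]
        return np.array(r)

    x0 = np.array([TET, TET, TET, TET, RING_TORSION, -RING_TORSION, RING_TORSION])
    sol = least_squares(residuals, x0, xtol=1e-14, ftol=1e-14, gtol=1e-14)
    pts = build(sol.x)
    gap = abs(np.linalg.norm(pts[5] - pts[0]) - CO)
    if gap > 1e-4:
        raise BuildError(f"chair ring failed to close (gap {gap:.2e} Å)")
    return pts


def _tetrahedral_lobes(center, n1, n2):
    """The two free tetrahedral directions at ``center`` given two bonded
    neighbour positions; returns unit vectors (d_plus, d_minus)."""
    u = n1 - center
    u /= np.linalg.norm(u)
    v = n2 - center
    v /= np.linalg.norm(v)
    s = u + v
    ns = np.linalg.norm(s)
    if ns < 1e-8:
        raise BuildError("degenerate lobe frame")
    b = -s / ns
    n = np.cross(u, v)
    n /= np.linalg.norm(n)
    cos_t = np.cos(np.radians(TET))
    cos_phi = cos_t / np.dot(b, u)
    cos_phi = np.clip(cos_phi, -1.0, 1.0)
    sin_phi = np.sqrt(1.0 - cos_phi**2)
    return cos_phi * b + sin_phi * n, cos_phi * b - sin_phi * n


def _ring_normal(points: np.ndarray) -> np.ndarray:
    """Newell normal of the ordered ring O5->C1->...->C5."""
    n = np.zeros(3)
    for i in range(6):
        p, q = points[i], points[(i + 1) % 6]
        n += np.cross(p, q)
    return n / np.linalg.norm(n)


class _Builder:
    """Accumulates atoms/bonds while constructing a template."""

    def __init__(self):
        self.atoms: list[AtomRecord] = []
        self.bonds: list[tuple[int, int]] = []
        self.by_name: dict[str, int] = {}

    def add(self, name, element, position, bond_to=None):
        i = len(self.atoms)
        self.atoms.append(AtomRecord(i, element, name, "", np.asarray(position, float)))
        self.by_name[name] = i
        if bond_to is not None:
            self.bonds.append((i, self.by_name[bond_to]))
        return i

    def pos(self, name):
        return self.atoms[self.by_name[name]].position

    def place(self, name, element, bond_to, angle_to, torsion_to, length, angle, torsion):
        p = place_atom(
            self.pos(bond_to), self.pos(angle_to), self.pos(torsion_to), length, angle, torsion
        )
        return self.add(name, element, p, bond_to=bond_to)

    def finish(self) -> MolecularStructure:
        return MolecularStructure(self.atoms, self.bonds)


def _attach_pair(b: _Builder, ring: np.ndarray, normal, carbon, heavy, elem, length, heavy_axial):
    """Attach the heavy substituent and the ring hydrogen at a ring carbon,
    assigning the axial and equatorial lobes geometrically."""
    idx = RING_ATOMS.index(carbon)
    prev_name = RING_ATOMS[idx - 1]
    next_name = RING_ATOMS[(idx + 1) % 6]
    c = b.pos(carbon)
    d1, d2 = _tetrahedral_lobes(c, b.pos(prev_name), b.pos(next_name))
    # axial = lobe more aligned with the ring normal
    ax, eq = (d1, d2) if abs(np.dot(d1, normal)) >= abs(np.dot(d2, normal)) else (d2, d1)
    hvy_dir, h_dir = (ax, eq) if heavy_axial else (eq, ax)
    b.add(heavy, elem, c + length * hvy_dir, bond_to=carbon)
    b.add("H" + carbon[1:], "H", c + CH * h_dir, bond_to=carbon)


def _build_pyranose_core(b: _Builder, anomeric_axial: bool, c2_substituent: str, c2_elem: str,
                         c2_len: float, c2_axial: bool):
    ring = _solve_chair_ring()
    for name, p in zip(RING_ATOMS, ring):
        b.add(name, name[0], p)
    for i in range(6):
        b.bonds.append((i, (i + 1) % 6))
    normal = _ring_normal(ring)
    _attach_pair(b, ring, normal, "C1", "O1", "O", CO, anomeric_axial)
    _attach_pair(b, ring, normal, "C2", c2_substituent, c2_elem, c2_len, c2_axial)
    _attach_pair(b, ring, normal, "C3", "O3", "O", CO, False)
    _attach_pair(b, ring, normal, "C4", "O4", "O", CO, False)
    _attach_pair(b, ring, normal, "C5", "C6", "C", CC, False)
    # hydroxymethyl: O6 at the gg rotamer (omega = O6-C6-C5-O5 = -60), then H6A/B
    b.place("O6", "O", "C6", "C5", "O5", CO, TET, -60.0)
    c6 = b.pos("C6")
    dA, dB = _tetrahedral_lobes(c6, b.pos("C5"), b.pos("O6"))
    b.add("H6A", "H", c6 + CH * dA, bond_to="C6")
    b.add("H6B", "H", c6 + CH * dB, bond_to="C6")
    # hydroxyl hydrogens, default anti to the lower-numbered ring neighbour
    b.place("HO1", "H", "O1", "C1", "C2", OH, TET, 180.0)
    b.place("HO3", "H", "O3", "C3", "C2", OH, TET, 180.0)
    b.place("HO4", "H", "O4", "C4", "C3", OH, TET, 180.0)
    b.place("HO6", "H", "O6", "C6", "C5", OH, TET, 180.0)


def _build_mannose() -> MolecularStructure:
    b = _Builder()
    # alpha-D-Man in 4C1: O1 and O2 axial, O3/O4 equatorial, C6 equatorial
    _build_pyranose_core(b, anomeric_axial=True, c2_substituent="O2", c2_elem="O",
                         c2_len=CO, c2_axial=True)
    b.place("HO2", "H", "O2", "C2", "C1", OH, TET, 180.0)
    return b.finish()


def _build_glcnac() -> MolecularStructure:
    b = _Builder()
    # beta-D-GlcNAc in 4C1: everything equatorial; acetamido on C2
    _build_pyranose_core(b, anomeric_axial=False, c2_substituent="N2", c2_elem="N",
                         c2_len=CN, c2_axial=False)
    # planar trans-amide: C7 and HN2 opposite across the N, O7 anti to HN2
    b.place("C7", "C", "N2", "C2", "C1", CN_AMIDE, SP2, 120.0)
    b.place("HN2", "H", "N2", "C2", "C1", NH, SP2, -60.0)
    b.place("O7", "O", "C7", "N2", "HN2", C_DOUBLE_O, SP2, 180.0)
    b.place("C8", "C", "C7", "N2", "HN2", CC, SP2, 0.0)
    b.place("H81", "H", "C8", "C7", "N2", CH, TET, 60.0)
    b.place("H82", "H", "C8", "C7", "N2", CH, TET, 180.0)
    b.place("H83", "H", "C8", "C7", "N2", CH, TET, -60.0)
    return b.finish()


def _mannose_sites() -> list[FunctionalGroupSite]:
    return [
        FunctionalGroupSite("OH1", ("HO1",), ("O1",), ("C2", "C1", "O1", "HO1"),
                            position=1, axial=True),
        FunctionalGroupSite("OH2", ("HO2",), ("O2",), ("C1", "C2", "O2", "HO2"),
                            position=2, axial=True),
        FunctionalGroupSite("OH3", ("HO3",), ("O3",), ("C2", "C3", "O3", "HO3"),
                            position=3, axial=False),
        FunctionalGroupSite("OH4", ("HO4",), ("O4",), ("C3", "C4", "O4", "HO4"),
                            position=4, axial=False),
        FunctionalGroupSite("OH6", ("HO6",), ("O6",), ("C5", "C6", "O6", "HO6"),
                            heavy_torsion=("O5", "C5", "C6", "O6"), position=6, axial=False),
        FunctionalGroupSite("O", (), ("O5",), position=None),
    ]


def _glcnac_sites() -> list[FunctionalGroupSite]:
    return [
        FunctionalGroupSite("OH1", ("HO1",), ("O1",), ("C2", "C1", "O1", "HO1"),
                            position=1, axial=False),
        FunctionalGroupSite("NHCO", ("HN2",), ("O7",), ("C1", "C2", "N2", "HN2"),
                            position=2, axial=False),
        FunctionalGroupSite("OH3", ("HO3",), ("O3",), ("C2", "C3", "O3", "HO3"),
                            position=3, axial=False),
        FunctionalGroupSite("OH4", ("HO4",), ("O4",), ("C3", "C4", "O4", "HO4"),
                            position=4, axial=False),
        FunctionalGroupSite("OH6", ("HO6",), ("O6",), ("C5", "C6", "O6", "HO6"),
                            heavy_torsion=("O5", "C5", "C6", "O6"), position=6, axial=False),
        FunctionalGroupSite("O", (), ("O5",), position=None),
    ]


_SITE_FACTORIES = {
    "alpha-D-Man": _mannose_sites,
    "beta-D-GlcNAc": _glcnac_sites,
}
_GEOMETRY_BUILDERS = {
    "alpha-D-Man": _build_mannose,
    "beta-D-GlcNAc": _build_glcnac,
}
_ANOMERIC = {"alpha-D-Man": "alpha", "beta-D-GlcNAc": "beta"}


def build_template_from_scratch(name: str) -> MonosaccharideTemplate:
    """Construct a template programmatically (used to generate the data files)."""
    if name not in KNOWN_RESIDUES:
        raise CatalogError(f"unknown residue {name!r}; known: {KNOWN_RESIDUES}")
    structure = _GEOMETRY_BUILDERS[name]()
    return MonosaccharideTemplate(name, _ANOMERIC[name], structure, _SITE_FACTORIES[name]())


# ---------------------------------------------------------------------------
# internal-coordinate data files
# ---------------------------------------------------------------------------


def _template_text(name: str) -> str:
    path = resources.files("glycotree").joinpath(f"data/templates/{name}.zmat")
    return path.read_text()


def parse_template_table(text: str) -> tuple[list[InternalCoordinateRow], list[tuple[str, str]], dict]:
    """Parse the internal-coordinate table format.

    Lines: ``name element bond_ref length angle_ref angle torsion_ref torsion``
    with ``-`` for unused fields and references by atom name.  ``# closure:``
    comment lines list extra (ring-closing) bonds.
    """
    rows: list[InternalCoordinateRow] = []
    closures: list[tuple[str, str]] = []
    meta: dict[str, str] = {}
    names: dict[str, int] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("closure:"):
                a, _, bpart = body[len("closure:"):].strip().partition("-")
                closures.append((a.strip(), bpart.strip()))
            elif ":" in body:
                k, _, v = body.partition(":")
                meta[k.strip()] = v.strip()
            continue
        parts = line.split()
        if len(parts) != 8:
            raise BuildError(f"template table line {lineno}: expected 8 fields")
        name, element, bref, length, aref, angle, tref, torsion = parts

        def ref(tok):
            if tok == "-":
                return None
            if tok not in names:
                raise BuildError(f"template table line {lineno}: unknown reference {tok!r}")
            return names[tok]

        def val(tok):
            return None if tok == "-" else float(tok)

        rows.append(
            InternalCoordinateRow(
                element, name,
                bond_ref=ref(bref), length=val(length),
                angle_ref=ref(aref), angle=val(angle),
                torsion_ref=ref(tref), torsion=val(torsion),
            )
        )
        names[name] = len(rows) - 1
    return rows, closures, meta


def build_template(name: str) -> MonosaccharideTemplate:
    """Load a built-in residue template from its internal-coordinate table."""
    if name not in KNOWN_RESIDUES:
        raise CatalogError(f"unknown residue {name!r}; known: {KNOWN_RESIDUES}")
    rows, closures, _meta = parse_template_table(_template_text(name))
    structure = zmatrix_to_cartesian(rows)
    by_name = {a.name: a.index for a in structure.atoms}
    for a, bpart in closures:
        structure.add_bond(by_name[a], by_name[bpart])
    return MonosaccharideTemplate(name, _ANOMERIC[name], structure, _SITE_FACTORIES[name]())


def list_sites(template: MonosaccharideTemplate, role: str) -> list[str]:
    """Site labels that can act as hydrogen-bond ``donor`` or ``acceptor``."""
    if role == "donor":
        return [s.label for s in template.sites if s.donor_atoms]
    if role == "acceptor":
        return [s.label for s in template.sites if s.acceptor_atoms]
    raise ValueError(f"role must be 'donor' or 'acceptor', got {role!r}")
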