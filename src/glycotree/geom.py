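"""Cartesian/internal-coordinate geometry kernel.

Builds molecular structures from internal-coordinate (Z-matrix) rows and
measures or sets bond torsions on the resulting Cartesian geometry.  All
angles are in degrees; torsions are reported in the half-open interval
(-180, 180] following the IUPAC sign convention (positive = clockwise when
sighting from the second to the third frame atom).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import BuildError, DegenerateFrameError, NotRotatableError

__all__ = [
    "AtomRecord",
    "InternalCoordinateRow",
    "MolecularStructure",
    "zmatrix_to_cartesian",
    "cartesian_to_zmatrix",
    "measure_distance",
    "measure_angle",
    "measure_dihedral",
    "set_dihedral",
    "place_atom",
]

#: Heavy-atom contact below which a build warning is issued (Å).
CLASH_THRESHOLD = 1.8


@dataclass
class AtomRecord:
    """One atom: element, residue-local name, residue tag and position (Å)."""

    index: int
    element: str
    name: str
    residue_id: str
    position: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise BuildError(f"atom {self.name}: position must be a finite 3-vector")

    @property
    def key(self) -> tuple[str, str]:
        """(residue_id, name) pair, unique within a structure."""
        return (self.residue_id, self.name)


@dataclass(frozen=True)
class InternalCoordinateRow:
    """One Z-matrix row.

    References are indices of previously placed atoms.  The first row uses no
    references, the second only ``bond_ref``, the third ``bond_ref`` and
    ``angle_ref``.
    """

    element: str
    name: str
    residue_id: str = ""
    bond_ref: int | None = None
    length: float | None = None
    angle_ref: int | None = None
    angle: float | None = None
    torsion_ref: int | None = None
    torsion: float | None = None


class MolecularStructure:
    """An ordered atom list plus a bond graph, grouped into residues."""

    def __init__(self, atoms: list[AtomRecord], bonds: list[tuple[int, int]] | None = None):
        self.atoms = list(atoms)
        self.bonds: set[frozenset[int]] = set()
        for i, j in bonds or []:
            self.add_bond(i, j)

    # -- basic container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self.atoms)

    def __getitem__(self, index: int) -> AtomRecord:
        return self.atoms[index]

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    @positions.setter
    def positions(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        for atom, row in zip(self.atoms, xyz):
            atom.position = row.copy()

    @property
    def residues(self) -> list[str]:
        seen: list[str] = []
        for a in self.atoms:
            if a.residue_id not in seen:
                seen.append(a.residue_id)
        return seen

    def add_bond(self, i: int, j: int) -> None:
        n = len(self.atoms)
        if not (0 <= i < n and 0 <= j < n) or i == j:
            raise BuildError(f"invalid bond ({i}, {j})")
        self.bonds.add(frozenset((i, j)))

    def bonded(self, i: int, j: int) -> bool:
        return frozenset((i, j)) in self.bonds

    def neighbors(self, i: int) -> list[int]:
        out = sorted(j for b in self.bonds if i in b for j in b if j != i)
        return out

    def index_of(self, residue_id: str, name: str) -> int:
        for a in self.atoms:
            if a.residue_id == residue_id and a.name == name:
                return a.index
        raise KeyError(f"no atom {name} in residue {residue_id!r}")

    def copy(self) -> "MolecularStructure":
        atoms = [replace(a, position=a.position.copy()) for a in self.atoms]
        out = MolecularStructure(atoms)
        out.bonds = set(self.bonds)
        return out

    def reindex(self) -> None:
        for i, a in enumerate(self.atoms):
            a.index = i

    # -- graph utilities ----------------------------------------------------------

    def component_from(self, start: int, severed: frozenset[int]) -> set[int]:
        """Atoms reachable from ``start`` when the bond ``severed`` is cut."""
        seen = {start}
        stack = [start]
        while stack:
            i = stack.pop()
            for b in self.bonds:
                if i in b and b != severed:
                    (j,) = b - {i}
                    if j not in seen:
                        seen.add(j)
                        stack.append(j)
        return seen

    def clashes(self, threshold: float = CLASH_THRESHOLD) -> list[tuple[int, int, float]]:
        """Non-bonded heavy-atom pairs closer than ``threshold`` Å."""
        heavy = [a.index for a in self.atoms if a.element != "H"]
        pos = self.positions
        out = []
        for ii, i in enumerate(heavy):
            for j in heavy[ii + 1:]:
                if self.bonded(i, j):
                    continue
                d = float(np.linalg.norm(pos[i] - pos[j]))
                if d < threshold:
                    out.append((i, j, d))
        return out


# -- elementary measurements -----------------------------------------------------


def measure_distance(structure: MolecularStructure, a: int, b: int) -> float:
    return float(np.linalg.norm(structure.atoms[a].position - structure.atoms[b].position))


def measure_angle(structure: MolecularStructure, a: int, b: int, c: int) -> float:
    """Angle a-b-c in degrees."""
    p = structure.positions
    u = p[a] - p[b]
    v = p[c] - p[b]
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise DegenerateFrameError("coincident atoms in angle measurement")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def _dihedral_from_points(p0, p1, p2, p3) -> float:
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    nb1 = np.linalg.norm(b1)
    if nb1 == 0.0:
        raise DegenerateFrameError("coincident central atoms")
    b1u = b1 / nb1
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    if np.linalg.norm(v) < 1e-10 or np.linalg.norm(w) < 1e-10:
        raise DegenerateFrameError("collinear atoms in dihedral frame")
    x = np.dot(v, w)
    y = np.dot(np.cross(b1u, v), w)
    ang = float(np.degrees(np.arctan2(y, x)))
    if ang <= -180.0:
        ang += 360.0
    return ang


def measure_dihedral(structure: MolecularStructure, a: int, b: int, c: int, d: int) -> float:
    """Torsion a-b-c-d in degrees, in (-180, 180], IUPAC sign convention."""
    if len({a, b, c, d}) != 4:
        raise DegenerateFrameError("dihedral requires four distinct atoms")
    p = structure.positions
    return _dihedral_from_points(p[a], p[b], p[c], p[d])


def set_dihedral(
    structure: MolecularStructure,
    a: int,
    b: int,
    c: int,
    d: int,
    target: float,
    in_place: bool = False,
) -> MolecularStructure:
    """Rotate the d-side of the b-c bond so that torsion a-b-c-d equals ``target``.

    The b-c bond must be a bridge of the bond graph: only atoms on d's side of
    the cut move, so every bond length and bond angle is preserved.
    """
    out = structure if in_place else structure.copy()
    severed = frozenset((b, c))
    if severed not in out.bonds:
        raise NotRotatableError(f"atoms {b} and {c} are not bonded")
    moving = out.component_from(c, severed)
    if b in moving:
        raise NotRotatableError(f"bond {b}-{c} lies in a ring; cut does not separate the graph")
    current = measure_dihedral(out, a, b, c, d)
    delta = np.radians(target - current)
    axis_origin = out.atoms[b].position
    axis = out.atoms[c].position - axis_origin
    axis = axis / np.linalg.norm(axis)
    rot = _rotation_matrix(axis, delta)
    for i in moving:
        p = out.atoms[i].position - axis_origin
        out.atoms[i].position = rot @ p + axis_origin
    return out


def _rotation_matrix(axis: np.ndarray, theta: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis, angle in radians."""
    k = np.asarray(axis, dtype=float)
    kx, ky, kz = k
    kmat = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
    return np.eye(3) + np.sin(theta) * kmat + (1 - np.cos(theta)) * (kmat @ kmat)


# -- Z-matrix construction -------------------------------------------------------


def place_atom(
    p_bond: np.ndarray,
    p_angle: np.ndarray,
    p_torsion: np.ndarray,
    length: float,
    angle: float,
    torsion: float,
) -> np.ndarray:
    """NeRF placement: position of a new atom at (length, angle, torsion) from
    three reference points, such that torsion(new, p_bond, p_angle, p_torsion)
    equals ``torsion``."""
    if length <= 0:
        raise BuildError("bond length must be positive")
    if not (0.0 < angle < 180.0):
        raise DegenerateFrameError(f"bond angle {angle} outside (0, 180)")
    bc = p_bond - p_angle
    nbc = np.linalg.norm(bc)
    if nbc < 1e-10:
        raise DegenerateFrameError("coincident bond/angle references")
    bc = bc / nbc
    ab = p_angle - p_torsion
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise DegenerateFrameError("collinear torsion reference frame")
    n = n / nn
    m = np.cross(n, bc)
    ang = np.radians(angle)
    tor = np.radians(torsion)
    d = np.array(
        [
            -length * np.cos(ang),
            length * np.sin(ang) * np.cos(tor),
            length * np.sin(ang) * np.sin(tor),
        ]
    )
    frame = np.column_stack([bc, m, n])
    return p_bond + frame @ d


def zmatrix_to_cartesian(rows: list[InternalCoordinateRow]) -> MolecularStructure:
    """Build Cartesian coordinates from topologically ordered Z-matrix rows.

    The first atom is placed at the origin, the second on +x, the third in the
    xy-plane.  Later rows require all three references.
    """
    atoms: list[AtomRecord] = []
    bonds: list[tuple[int, int]] = []
    for i, row in enumerate(rows):
        refs = [row.bond_ref, row.angle_ref, row.torsion_ref]
        needed = min(i, 3)
        for r in refs[:needed]:
            if r is None:
                raise BuildError(f"row {i} ({row.name}): missing reference")
            if not (0 <= r < i):
                raise BuildError(f"row {i} ({row.name}): dangling reference {r}")
        if i == 0:
            pos = np.zeros(3)
        elif i == 1:
            if row.length is None or row.length <= 0:
                raise BuildError(f"row {i}: invalid bond length")
            pos = atoms[row.bond_ref].position + np.array([row.length, 0.0, 0.0])
        elif i == 2:
            if row.angle is None or not (0.0 < row.angle < 180.0):
                raise DegenerateFrameError(f"row {i}: bond angle outside (0, 180)")
            b = atoms[row.bond_ref].position
            aref = atoms[row.angle_ref].position
            u = aref - b
            u = u / np.linalg.norm(u)
            ang = np.radians(row.angle)
            # rotate u by the bond angle within the xy-plane
            perp = np.array([-u[1], u[0], 0.0])
            if np.linalg.norm(perp) < 1e-10:
                perp = np.array([0.0, 1.0, 0.0])
            else:
                perp = perp / np.linalg.norm(perp)
            pos = b + row.length * (np.cos(ang) * u + np.sin(ang) * perp)
        else:
            if row.torsion is None:
                raise BuildError(f"row {i} ({row.name}): missing torsion")
            pos = place_atom(
                atoms[row.bond_ref].position,
                atoms[row.angle_ref].position,
                atoms[row.torsion_ref].position,
                row.length,
                row.angle,
                row.torsion,
            )
        atoms.append(AtomRecord(i, row.element, row.name, row.residue_id, pos))
        if i > 0:
            bonds.append((i, row.bond_ref))
    return MolecularStructure(atoms, bonds)


def cartesian_to_zmatrix(
    structure: MolecularStructure, order: list[int] | None = None
) -> list[InternalCoordinateRow]:
    """Express a structure as Z-matrix rows over a construction order.

    ``order`` defaults to the existing atom order; each atom after the first
    must have a bonded neighbour earlier in the order (its bond reference).
    Angle/torsion references are taken as the reference's own references,
    falling back to any earlier atoms when the chain is too short.
    """
    n = len(structure.atoms)
    order = list(order) if order is not None else list(range(n))
    pos_in_order = {atom: k for k, atom in enumerate(order)}
    refs: dict[int, tuple[int | None, int | None, int | None]] = {}
    rows: list[InternalCoordinateRow] = []
    for k, i in enumerate(order):
        atom = structure.atoms[i]
        if k == 0:
            refs[i] = (None, None, None)
            rows.append(InternalCoordinateRow(atom.element, atom.name, atom.residue_id))
            continue
        earlier = [j for j in structure.neighbors(i) if pos_in_order.get(j, n) < k]
        if not earlier:
            raise BuildError(f"atom {atom.name} has no earlier bonded neighbour")
        b = min(earlier, key=lambda j: pos_in_order[j])
        a_ref, t_ref = None, None
        chain = refs[b]
        if chain[0] is not None:
            a_ref = chain[0]
            t_ref = chain[1]
        if a_ref is None:
            a_ref = next((order[m] for m in range(k) if order[m] not in (i, b)), None)
        if t_ref is None and k >= 3:
            t_ref = next(
                (order[m] for m in range(k) if order[m] not in (i, b, a_ref)), None
            )
        refs[i] = (b, a_ref, t_ref)
        length = measure_distance(structure, i, b)
        angle = measure_angle(structure, i, b, a_ref) if a_ref is not None else None
        torsion = (
            measure_dihedral(structure, i, b, a_ref, t_ref) if t_ref is not None else None
        )
        rows.append(
            InternalCoordinateRow(
                atom.element,
                atom.name,
                atom.residue_id,
                bond_ref=pos_in_order[b],
                length=length,
                angle_ref=pos_in_order[a_ref] if a_ref is not None else None,
                angle=angle,
                torsion_ref=pos_in_order[t_ref] if t_ref is not None else None,
                torsion=torsion,
            )
        )
    return rows
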