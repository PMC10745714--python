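"""Cooperative hydrogen-bond chains: notation, rotamer solving, detection,
conflict rules.

A chain is written head-to-tail in arrow notation, ``OH6_M→OH6′→OH6→OG``:
every token but the last donates its hydrogen to the next token, and the last
token may be an acceptor-only site (a ring oxygen, a bridge oxygen or the
reducing-end ``O1``).  Chains flagged reversible have a distinct mirror
variant obtained by reversing the hydroxyl backbone (acceptor-only terminals
are dropped on reversal).

The default detection criterion is a strict heavy-atom distance cut-off of
2.8 Å between donor and acceptor heavy atoms; an optional D-H···A angle
filter is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import (
    ChainNotationError,
    ChainRoleError,
    ChainVocabularyError,
    DoubleDonationError,
    ReversalError,
)
from .geom import measure_angle, measure_distance, set_dihedral
from .linkage import AssembledOligomer, SiteInstance, _normalize_label

__all__ = [
    "HBondCriteria",
    "HBondChain",
    "HBondObservation",
    "ConflictHit",
    "RotamerResult",
    "parse_chain_notation",
    "reverse_chain",
    "solve_rotamers",
    "detect_hbonds",
    "check_conflicts",
]

STAGGERED = (-60.0, 60.0, 180.0)


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric acceptance criterion for a hydrogen bond."""

    max_distance: float = 2.8
    min_dha_angle: float | None = None

    def __post_init__(self) -> None:
        if self.max_distance <= 0:
            raise ValueError("max_distance must be positive")


@dataclass(frozen=True)
class HBondChain:
    """An ordered donor→acceptor chain over molecule-level site labels."""

    tokens: tuple[str, ...]
    region: str | None = None
    reversible: bool = False

    @property
    def steps(self) -> tuple[tuple[str, str], ...]:
        return tuple(zip(self.tokens, self.tokens[1:]))

    @property
    def donors(self) -> tuple[str, ...]:
        return self.tokens[:-1]

    @property
    def terminal_acceptor(self) -> str:
        return self.tokens[-1]

    def notation(self) -> str:
        return "→".join(self.tokens)

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.notation()


@dataclass
class HBondObservation:
    """A realized hydrogen bond (heavy-atom distance below the cut-off)."""

    donor: str
    acceptor: str
    h_atom: int
    distance: float
    dha_angle: float


@dataclass
class ConflictHit:
    kind: str  # mutual-pointing | double-donation | orientation-clash
    sites: tuple[str, ...]
    message: str


@dataclass
class RotamerResult:
    oligomer: AssembledOligomer
    realized: list[HBondObservation]
    infeasible: list[tuple[str, str, str]]  # (donor, acceptor, reason)

    @property
    def satisfied_steps(self) -> set[tuple[str, str]]:
        return {(o.donor, o.acceptor) for o in self.realized}


def _is_donor_capable(label: str) -> bool:
    lab = _normalize_label(label)
    return lab.startswith("OH") or lab.startswith("NHCO")


def parse_chain_notation(
    text: str,
    region: str | None = None,
    reversible: bool = False,
    oligomer: AssembledOligomer | None = None,
) -> HBondChain:
    """Parse arrow notation into an :class:`HBondChain`.

    Accepts the UTF-8 arrow ``→`` or ASCII ``->``, and apostrophes in place of
    prime marks.  When an oligomer is supplied, every token is checked against
    its site vocabulary.
    """
    if not isinstance(text, str) or not text.strip():
        raise ChainNotationError("empty chain notation")
    norm = _normalize_label(text)
    tokens = tuple(t.strip() for t in norm.split("→"))
    if any(not t for t in tokens):
        raise ChainNotationError(f"empty token in chain {text!r}")
    if len(tokens) < 2:
        raise ChainNotationError(f"chain needs at least two sites: {text!r}")
    for t in tokens[:-1]:
        if not _is_donor_capable(t):
            raise ChainRoleError(f"acceptor-only site {t!r} cannot donate in {text!r}")
    if oligomer is not None:
        for t in tokens:
            if not oligomer.has_site(t):
                raise ChainVocabularyError(
                    f"unknown site label {t!r} for {oligomer.topology.name}"
                )
    return HBondChain(tokens=tokens, region=region, reversible=reversible)


def reverse_chain(chain: HBondChain) -> HBondChain:
    """The clockwise/counterclockwise mirror of a reversible chain.

    Trailing acceptor-only sites are dropped; the hydroxyl backbone is
    reversed, so reversing twice is the identity on the backbone.
    """
    if not chain.reversible:
        raise ReversalError(f"chain {chain.notation()!r} is not reversible")
    backbone = list(chain.tokens)
    while backbone and not _is_donor_capable(backbone[-1]):
        backbone.pop()
    if len(backbone) < 2:
        raise ReversalError(f"chain {chain.notation()!r} has no reversible backbone")
    return replace(chain, tokens=tuple(reversed(backbone)))


# ---------------------------------------------------------------------------
# rotamer solving
# ---------------------------------------------------------------------------


def _set_site_torsion(olig: AssembledOligomer, inst: SiteInstance, quad, value: float) -> None:
    a, b, c, d = (olig.atom_index(inst.residue, n) for n in quad)
    set_dihedral(olig.structure, a, b, c, d, value, in_place=True)


def _solve_h_torsion(olig, inst, target_atom: int) -> float:
    """Orient a site's donor hydrogen toward an acceptor atom: 5° grid scan of
    the H torsion followed by bounded golden-section refinement of the
    H···acceptor distance; ties break toward the smaller absolute torsion."""
    h = inst.donor_h(olig)

    def dist_at(t: float) -> float:
        _set_site_torsion(olig, inst, inst.site.h_torsion, t)
        return measure_distance(olig.structure, h, target_atom)

    grid = [g - 180.0 + 2.5 for g in range(0, 360, 5)]
    grid.sort(key=abs)  # stable tie-break toward small |torsion|
    best_t = min(grid, key=lambda t: (round(dist_at(t), 12), abs(t)))
    res = minimize_scalar(
        dist_at, bounds=(best_t - 5.0, best_t + 5.0), method="bounded",
        options={"xatol": 1e-6},
    )
    t = float(res.x)
    if dist_at(best_t) < res.fun:
        t = best_t
    _set_site_torsion(olig, inst, inst.site.h_torsion, t)
    return t


def _best_staggered(olig, inst, quad, score) -> float:
    best = None
    for t in STAGGERED:
        _set_site_torsion(olig, inst, quad, t)
        s = score()
        if best is None or s < best[0] - 1e-12:
            best = (s, t)
    _set_site_torsion(olig, inst, quad, best[1])
    return best[1]


def solve_rotamers(
    oligomer: AssembledOligomer,
    chains: list[HBondChain],
    criteria: HBondCriteria = HBondCriteria(),
    preset_heavy: dict[str, float] | None = None,
) -> RotamerResult:
    """Realize hydrogen-bond chains by rotating exocyclic torsions.

    Chains are processed in order and each chain sequentially from its first
    donor.  A hydroxymethyl donor (or acceptor) that is not yet constrained
    first has its C5-C6 torsion chosen among the three staggered rotamers to
    bring the heavy atoms closest; the donor hydrogen is then aimed by grid
    search with golden-section refinement.  Steps whose heavy-atom distance
    still fails the criterion are reported as infeasible, not fatal.
    Remaining unconstrained hydroxyl/hydroxymethyl torsions are set to the
    staggered rotamer with the most open nearest contact.
    """
    donors_seen: dict[str, int] = {}
    for ci, chain in enumerate(chains):
        for d in chain.donors:
            key = _normalize_label(d)
            if key in donors_seen and donors_seen[key] != ci:
                raise DoubleDonationError(
                    f"site {d!r} donates in two chains ({donors_seen[key]} and {ci})"
                )
            donors_seen.setdefault(key, ci)

    olig = oligomer.copy_structure()
    placed: set[str] = set()    # sites whose heavy atom is frozen
    oriented: set[str] = set()  # sites whose hydrogen is frozen
    for label, value in (preset_heavy or {}).items():
        inst = olig.site(label)
        if inst.site.heavy_torsion:
            _set_site_torsion(olig, inst, inst.site.heavy_torsion, value)
            placed.add(inst.label)
    realized: list[HBondObservation] = []
    infeasible: list[tuple[str, str, str]] = []

    for chain in chains:
        for donor, acceptor in chain.steps:
            dsite = olig.site(donor)
            asite = olig.site(acceptor)
            if dsite.consumed:
                infeasible.append((donor, acceptor, f"donor {donor!r} consumed by a linkage"))
                continue
            if asite.consumed:
                infeasible.append((acceptor, donor, f"acceptor {acceptor!r} consumed by a linkage"))
                continue
            a_atom = asite.acceptor_atom(olig)
            d_heavy = dsite.heavy_atom(olig)
            if dsite.site.heavy_torsion and dsite.label not in placed:
                _best_staggered(
                    olig, dsite, dsite.site.heavy_torsion,
                    lambda: measure_distance(olig.structure, dsite.heavy_atom(olig), a_atom),
                )
            placed.add(dsite.label)
            if asite.site.heavy_torsion and asite.label not in placed and asite.label not in oriented:
                _best_staggered(
                    olig, asite, asite.site.heavy_torsion,
                    lambda: measure_distance(olig.structure, asite.acceptor_atom(olig),
                                             dsite.heavy_atom(olig)),
                )
                placed.add(asite.label)
            a_atom = asite.acceptor_atom(olig)
            d_heavy = dsite.heavy_atom(olig)
            _solve_h_torsion(olig, dsite, a_atom)
            oriented.add(dsite.label)
            dist = measure_distance(olig.structure, d_heavy, a_atom)
            h = dsite.donor_h(olig)
            angle = measure_angle(olig.structure, d_heavy, h, a_atom)
            ok = dist < criteria.max_distance
            if ok and criteria.min_dha_angle is not None:
                ok = angle >= criteria.min_dha_angle
            if ok:
                realized.append(HBondObservation(dsite.label, asite.label, h, dist, angle))
            else:
                infeasible.append(
                    (donor, acceptor, f"heavy-atom distance {dist:.2f} Å ≥ {criteria.max_distance} Å")
                )

    _relax_free_torsions(olig, placed, oriented)
    return RotamerResult(olig, realized, infeasible)


def _relax_free_torsions(olig: AssembledOligomer, placed: set[str], oriented: set[str]) -> None:
    """Put unconstrained OH/CH2OH torsions into the most open staggered rotamer."""
    pos = None

    def open_score(moving_atoms: list[int]) -> float:
        p = olig.structure.positions
        score = 0.0
        for i in moving_atoms:
            d = np.linalg.norm(p - p[i], axis=1)
            d[i] = np.inf
            for j in olig.structure.neighbors(i):
                d[j] = np.inf
            score -= float(d.min())  # lower score = more open
        return score

    for inst in olig.active_sites():
        if not inst.site.donor_atoms:
            continue
        if inst.site.heavy_torsion and inst.label not in placed:
            heavy = inst.heavy_atom(olig)
            _best_staggered(olig, inst, inst.site.heavy_torsion, lambda: open_score([heavy]))
        if inst.site.h_torsion and inst.label not in oriented:
            h = inst.donor_h(olig)
            _best_staggered(olig, inst, inst.site.h_torsion, lambda: open_score([h]))


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------


def _graph_distance_le(structure, i: int, j: int, cutoff: int) -> bool:
    """True if i and j are within ``cutoff`` bonds of each other."""
    frontier = {i}
    seen = {i}
    for _ in range(cutoff):
        nxt = set()
        for k in frontier:
            for n in structure.neighbors(k):
                if n == j:
                    return True
                if n not in seen:
                    seen.add(n)
                    nxt.add(n)
        frontier = nxt
    return False


def detect_hbonds(
    oligomer: AssembledOligomer, criteria: HBondCriteria = HBondCriteria()
) -> list[HBondObservation]:
    """All hydrogen bonds satisfying the criterion on the current geometry.

    Donors are the active donor sites; acceptors are all oxygen atoms more
    than two bonds away from the donor heavy atom.  Each donor hydrogen is
    reported at most once, paired with its nearest eligible acceptor.
    """
    s = oligomer.structure
    acceptor_label: dict[int, str] = {}
    for inst in oligomer.sites:
        for name in inst.site.acceptor_atoms:
            try:
                idx = oligomer.atom_index(inst.residue, name)
            except KeyError:
                continue  # atom lost to a glycosidic condensation
            acceptor_label.setdefault(idx, inst.label)
    oxygens = [a.index for a in s.atoms if a.element == "O"]
    out: list[HBondObservation] = []
    for inst in oligomer.active_sites():
        if not inst.site.donor_atoms:
            continue
        d_heavy = inst.heavy_atom(oligomer)
        h = inst.donor_h(oligomer)
        best = None
        for o in oxygens:
            if o == d_heavy or _graph_distance_le(s, d_heavy, o, 2):
                continue
            dist = measure_distance(s, d_heavy, o)
            if dist >= criteria.max_distance:
                continue
            angle = measure_angle(s, d_heavy, h, o)
            if criteria.min_dha_angle is not None and angle < criteria.min_dha_angle:
                continue
            if best is None or dist < best[0]:
                best = (dist, o, angle)
        if best is not None:
            dist, o, angle = best
            label = acceptor_label.get(o, f"{s.atoms[o].residue_id}:{s.atoms[o].name}")
            out.append(HBondObservation(inst.label, label, h, dist, angle))
    return out


def collinear_probe(separation: float) -> AssembledOligomer:
    """A minimal collinear O-H···O probe at the given heavy-atom separation
    (Å), with one hydroxyl donor site and one acceptor-only site.  Used to
    exercise the detector boundary."""
    from .geom import AtomRecord, MolecularStructure
    from .linkage import OligomerTopology, ResidueSpec, SiteInstance
    from .templates import FunctionalGroupSite

    atoms = [
        AtomRecord(0, "O", "O1", "X", np.array([0.0, 0.0, 0.0])),
        AtomRecord(1, "H", "HO1", "X", np.array([0.96, 0.0, 0.0])),
        AtomRecord(2, "O", "O2", "X", np.array([separation, 0.0, 0.0])),
    ]
    structure = MolecularStructure(atoms, [(0, 1)])
    topo = OligomerTopology("probe", [ResidueSpec("X", "alpha-D-Man")], [])
    olig = AssembledOligomer(topo)
    olig.structure = structure
    olig.atom_map = {"X": {"O1": 0, "HO1": 1, "O2": 2}}
    olig.register_site(
        SiteInstance("X", FunctionalGroupSite("OH1", ("HO1",), ("O1",)), "OH1", ())
    )
    olig.register_site(
        SiteInstance("X", FunctionalGroupSite("O", (), ("O2",)), "OX", ())
    )
    return olig


# ---------------------------------------------------------------------------
# conflict rules
# ---------------------------------------------------------------------------


def _neighbor_pair(olig: AssembledOligomer, lab1: str, lab2: str) -> bool:
    """Same-residue sites on ring-adjacent positions (4 and 6 share C5)."""
    try:
        s1, s2 = olig.site(lab1), olig.site(lab2)
    except KeyError:
        return False
    if s1.residue != s2.residue:
        return False
    p1, p2 = s1.site.position, s2.site.position
    if p1 is None or p2 is None:
        return False
    return abs(p1 - p2) == 1 or {p1, p2} == {4, 6}


def check_conflicts(
    chains: list[HBondChain], oligomer: AssembledOligomer
) -> list[ConflictHit]:
    """Topological conflict screening of a chain set.

    * mutual-pointing: the terminal donors of two chains target each other, or
      one chain donates into a site that is simultaneously the terminal
      acceptor of another chain while being the donor's geometric neighbour
      (ring-adjacent position on the same residue);
    * double-donation: one site donates in two chains;
    * orientation-clash: a chain references a site consumed by a glycosidic
      linkage.
    """
    hits: list[ConflictHit] = []
    donors_by_chain = [set(map(_normalize_label, c.donors)) for c in chains]
    for i in range(len(chains)):
        for j in range(i + 1, len(chains)):
            shared = donors_by_chain[i] & donors_by_chain[j]
            for s in sorted(shared):
                hits.append(
                    ConflictHit("double-donation", (s,), f"site {s!r} donates in chains {i} and {j}")
                )
    for ci, chain in enumerate(chains):
        for t in chain.tokens:
            try:
                inst = oligomer.site(t)
            except KeyError:
                continue
            if inst.consumed:
                hits.append(
                    ConflictHit(
                        "orientation-clash", (t,),
                        f"chain {ci} requires {t!r}, consumed by a glycosidic linkage",
                    )
                )
    # mutual pointing, clause 1: terminal donors target each other's site
    for i in range(len(chains)):
        for j in range(i + 1, len(chains)):
            ci, cj = chains[i], chains[j]
            di, ai = ci.steps[-1]
            dj, aj = cj.steps[-1]
            if _normalize_label(ai) == _normalize_label(dj) and _normalize_label(
                aj
            ) == _normalize_label(di):
                hits.append(
                    ConflictHit("mutual-pointing", (di, dj), "terminal donors target each other")
                )
    # clause 2: a donation X→Y between ring neighbours while Y terminally
    # accepts another chain (its free hydrogen is forced back toward X)
    for i, chain in enumerate(chains):
        for x, y in chain.steps:
            if not _neighbor_pair(oligomer, x, y):
                continue
            for j, other in enumerate(chains):
                if j == i:
                    continue
                if _normalize_label(other.terminal_acceptor) == _normalize_label(y):
                    hits.append(
                        ConflictHit(
                            "mutual-pointing", (x, y),
                            f"{x!r} points at {y!r}, which terminally accepts chain {j}",
                        )
                    )
    return hits
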